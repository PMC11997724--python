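"""Independent brute-force oracles for geometry and FDR kernels.

Everything here is written with scalar Python loops and its own arithmetic so
it shares no code path with the package implementation it is checking.
"""

import math

import numpy as np


def round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def resample_scalar(points, step):
    """Per-segment subdivision with endpoints kept; scalar arithmetic."""
    out = [tuple(points[0])]
    for a, b in zip(points[:-1], points[1:]):
        length = math.dist(a, b)
        k = max(int(math.ceil(length / step)), 1)
        for i in range(1, k + 1):
            t = i / k
            out.append(tuple(a[j] + t * (b[j] - a[j]) for j in range(3)))
    return out


def voxelize_bruteforce(streamlines, affine, shape, step):
    """Set of in-grid voxel index tuples, via per-point solve + scalar rounding."""
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    hit = set()
    for sl in streamlines:
        for p in resample_scalar(np.asarray(sl, dtype=float), step):
            q = inv @ np.array([p[0], p[1], p[2], 1.0])
            idx = tuple(round_half_away(q[i]) for i in range(3))
            if all(0 <= idx[i] < shape[i] for i in range(3)):
                hit.add(idx)
    return hit


def voxel_membership_scan(sample_world, affine, shape):
    """All-voxel scan: the voxels a single world point belongs to.

    Checks every voxel of the grid against the sample by reconstructing the
    voxel-assignment rule per voxel (nearest center, halves away from zero).
    Returns a set with zero or one index tuples.
    """
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    q = inv @ np.array([*sample_world, 1.0])
    members = set()
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if (round_half_away(q[0]), round_half_away(q[1]), round_half_away(q[2])) == (i, j, k):
                    members.add((i, j, k))
    return members


def injured_bruteforce(streamlines, mask_grid, affine, step):
    """Indices of streamlines with any sample in a lesion voxel (scalar loops)."""
    shape = mask_grid.shape
    injured = []
    for n, sl in enumerate(streamlines):
        vox = voxelize_bruteforce([sl], affine, shape, step)
        if any(mask_grid[v] == 1 for v in vox):
            injured.append(n)
    return injured


def burden_bruteforce(left, right, mask_grid, affine, step):
    """Burden via explicit per-voxel sets, averaging hemispheres."""
    shape = mask_grid.shape
    inj_l = set()
    inj_r = set()
    can_l = set()
    can_r = set()
    for target_inj, target_can, side in ((inj_l, can_l, left), (inj_r, can_r, right)):
        for sl in side:
            vs = voxelize_bruteforce([sl], affine, shape, step)
            target_can |= vs
            if any(mask_grid[v] == 1 for v in vs):
                target_inj |= vs
    return (len(inj_l) + len(inj_r)) / (len(can_l) + len(can_r))


def bh_adjust_bruteforce(p):
    """BH adjusted p by definition: smallest q at which each test is rejected.

    The rejection set at level q is the largest k with p_(k) <= k q / m; the
    adjusted p of a test is the minimum q over a dense candidate set at which
    it falls in the rejection set.
    """
    p = list(map(float, p))
    m = len(p)
    candidates = sorted({min(1.0, pj * m / j) for pj in p for j in range(1, m + 1)})

    def rejected_at(q):
        order = sorted(range(m), key=lambda i: p[i])
        kmax = 0
        for rank, i in enumerate(order, start=1):
            if p[i] <= rank * q / m + 1e-9:  # fp slack: q candidates round-trip
                kmax = rank
        return set(order[:kmax])

    adj = [1.0] * m
    for q in candidates:
        rej = rejected_at(q)
        for i in rej:
            adj[i] = min(adj[i], q)
    return adj
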