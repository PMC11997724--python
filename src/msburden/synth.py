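"""Synthetic cohorts: EMR records, toy tract bundles, planted lesion masks.

No patient data ship with the package; every downstream stage (phenotyping,
burden scoring, statistics) is exercised on cohorts generated here. The
generator emulates the structure the analysis assumes:

* a three-group anxiety phenotype (no/mild/severe) with EMR fields written so
  the rule-based phenotyper recovers the latent group: no-anxiety patients are
  psychiatrically clean with a confirming PHQ of 0; mild patients carry exactly
  one of {anxiety diagnosis code, anxiolytic order}; severe patients carry both;
* a planted positive burden-severity gradient in a toy uncinate-fasciculus
  (UF) analog, a severity-independent overlap in a fornix analog, and a
  general-psychopathology gradient in total (background) lesion volume;
* PROMIS emotional functioning decreasing with anxiety severity (physical at
  half the slope).

Toy tracts are parametric circular arcs (hook-shaped for the UF analog,
arch-shaped for the fornix analog) jittered per streamline, mirror-symmetric
about the mid-sagittal plane, and placed so UF and fornix voxelizations are
disjoint — which guarantees lesions planted on one tract never injure the
other.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .burden import LesionMask, TractBundle, VoxelGrid, _voxel_set
from .phenotype import EMOTIONAL_DOMAINS, PHYSICAL_DOMAINS, PatientRecord

__all__ = [
    "SynthConfig",
    "GridTooSmallError",
    "BurdenGranularityError",
    "make_toy_bundles",
    "TractGeometry",
    "plant_lesion_mask",
    "make_cohort",
    "Cohort",
]

_EPOCH = dt.date(2014, 1, 1)

ANXIETY_CODES = ("F41.1", "F40.01", "F41.0", "F40.10")
DEPRESSION_CODES = ("F32.9", "F33.1", "F32.1")
ANXIOLYTICS = ("lorazepam", "clonazepam", "buspirone", "hydroxyzine")
ANTIDEPRESSANTS = ("sertraline", "fluoxetine", "escitalopram", "venlafaxine")

RACE_LEVELS = ("White", "Black or African American", "Asian", "Other", "Unknown")
RACE_PROPS = (0.715, 0.205, 0.005, 0.05, 0.025)


class GridTooSmallError(ValueError):
    """Grid cannot contain spatially disjoint UF and fornix analogs."""


class BurdenGranularityError(ValueError):
    """Requested burden is not reachable at the tract's voxel granularity."""


@dataclass(frozen=True)
class SynthConfig:
    """Cohort generation parameters.

    Defaults mirror the study conditions the analysis targets: a 372-patient
    cohort split ~27/67/6% into no/mild/severe anxiety; group mean UF burden
    fractions (0.02, 0.05, 0.10); a severity-independent fornix overlap; and
    background lesion volume increasing with psychiatric severity.
    """

    n_patients: int = 372
    group_props: tuple[float, float, float] = (99 / 372, 249 / 372, 24 / 372)
    burden_means: tuple[float, float, float] = (0.02, 0.05, 0.10)
    burden_noise_sd: float = 0.02
    fornix_burden_mean: float = 0.04
    #: per-group additive background lesion volume, mm^3
    total_lesion_extra: tuple[float, float, float] = (4000.0, 7000.0, 10000.0)
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 1.0
    seed: int = 0
    #: PROMIS emotional T-score decrease per anxiety severity level
    promis_effect: float = 4.0
    phq_missing_rate: float = 0.1
    n_streamlines_per_side: int = 50
    #: probability that a mild/severe-anxiety patient also carries depression
    depression_rate: float = 0.8
    #: fraction of patients with PROMIS observations
    promis_rate: float = 0.7
    #: mean PHQ-2 for mild and severe groups (truncated-Poisson on 0..6)
    phq2_means: tuple[float, float] = (0.57, 1.16)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.group_props) - 1.0) > 1e-9:
            raise ValueError("group_props must sum to 1")
        for b in (*self.burden_means, self.fornix_burden_mean):
            if not 0.0 <= b <= 1.0:
                raise ValueError("burden means must lie in [0, 1]")
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 16")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if not 0.0 <= self.phq_missing_rate <= 1.0:
            raise ValueError("phq_missing_rate must be a probability")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            m = yaml.safe_load(fh) or {}
        for key in ("group_props", "burden_means", "total_lesion_extra",
                    "grid_shape", "phq2_means"):
            if key in m:
                m[key] = tuple(m[key])
        return cls(**m)

    def to_yaml(self, path) -> None:
        m = dataclasses.asdict(self)
        for k, v in m.items():
            if isinstance(v, tuple):
                m[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(m, fh, sort_keys=False)


# ------------------------------------------------------------- toy bundles


def _arc(x0, yc, zc, radius, theta0, theta1, n_points=41):
    theta = np.linspace(theta0, theta1, n_points)
    return np.column_stack(
        [np.full_like(theta, x0), yc + radius * np.cos(theta), zc + radius * np.sin(theta)]
    )


def make_toy_bundles(
    grid_shape=(48, 48, 48),
    voxel_size_mm: float = 1.0,
    n_streamlines_per_side: int = 50,
    seed: int = 0,
) -> list[TractBundle]:
    """Four toy bundles: UF_left, UF_right, fornix_left, fornix_right.

    UF analogs are hook-shaped arcs low/anterior in the volume; fornix analogs
    are arch-shaped arcs high/posterior. Right bundles are exact mirror images
    of the left about the mid-sagittal plane. The two tracts' voxelizations
    are verified disjoint on the requested grid; a grid too small to hold them
    apart raises :class:`GridTooSmallError`.
    """
    if n_streamlines_per_side < 1:
        raise ValueError("n_streamlines_per_side must be >= 1")
    shape = tuple(int(s) for s in grid_shape)
    v = float(voxel_size_mm)
    extent = np.asarray(shape, dtype=float) * v
    m = float(extent.min())
    if min(shape) < 16:
        raise GridTooSmallError(
            f"grid {shape} too small: need >= 16 voxels per axis for disjoint bundles"
        )
    jitter = min(1.5, 0.02 * m)
    rng = np.random.default_rng(seed)

    def jittered_arcs(x0, yc, zc, radius, th0, th1):
        arcs = []
        for _ in range(n_streamlines_per_side):
            dx, dy, dz = np.clip(rng.normal(0.0, jitter, 3), -1.5 * jitter, 1.5 * jitter)
            dr = float(np.clip(rng.normal(0.0, jitter / 2), -jitter, jitter))
            arc = _arc(x0 + dx, yc + dy, zc + dz, radius + dr, th0, th1)
            arcs.append(np.clip(arc, 0.6 * v, extent - 1.6 * v))
        return arcs

    # UF analog: hook opening posteriorly, low in z
    uf_left = jittered_arcs(
        0.28 * extent[0], 0.30 * extent[1], 0.40 * extent[2],
        0.14 * m, np.deg2rad(-100), np.deg2rad(100),
    )
    # fornix analog: arch, posterior and superior
    fx_left = jittered_arcs(
        0.44 * extent[0], 0.75 * extent[1], 0.60 * extent[2],
        0.11 * m, np.deg2rad(20), np.deg2rad(160),
    )

    def mirror(arcs):
        out = []
        for a in arcs:
            b = a.copy()
            b[:, 0] = extent[0] - b[:, 0]
            out.append(b)
        return out

    bundles = [
        TractBundle("UF_left", uf_left),
        TractBundle("UF_right", mirror(uf_left)),
        TractBundle("fornix_left", fx_left),
        TractBundle("fornix_right", mirror(fx_left)),
    ]

    grid = VoxelGrid(shape=shape, affine=np.diag([v, v, v, 1.0]))
    uf_vox = _voxel_set(bundles[0].streamlines + bundles[1].streamlines, grid)
    fx_vox = _voxel_set(bundles[2].streamlines + bundles[3].streamlines, grid)
    if uf_vox & fx_vox:
        raise GridTooSmallError(
            f"grid {shape} at {v} mm too small: UF and fornix analogs share "
            f"{len(uf_vox & fx_vox)} voxels; increase grid extent"
        )
    return bundles


# --------------------------------------------------------- lesion planting


class TractGeometry:
    """Precomputed voxel geometry of a bilateral bundle pair on a grid.

    Caches per-streamline voxel sets and the deterministic greedy planting
    trajectory: tract voxels sorted by how many streamlines traverse them
    (fewest first, ties by voxel index) with the burden value reached after
    each prefix. Burden grows in the finest increments the tract offers and
    is monotone along the trajectory, so planting a target burden reduces to
    a prefix lookup, and the value recomputed by streamline filtering on the
    planted mask equals the trajectory value by construction.
    """

    def __init__(self, left: TractBundle, right: TractBundle, grid: VoxelGrid):
        self.grid = grid
        self.sl_vox: dict[str, list[frozenset[int]]] = {}
        for side, bundle in (("left", left), ("right", right)):
            self.sl_vox[side] = [
                frozenset(_voxel_set([sl], grid)) for sl in bundle.streamlines
            ]
        self.canonical = {
            side: frozenset().union(*sets) for side, sets in self.sl_vox.items()
        }
        self.all_voxels: frozenset[int] = self.canonical["left"] | self.canonical["right"]

        traversals: dict[int, list[tuple[str, int]]] = defaultdict(list)
        for side, sets in self.sl_vox.items():
            for i, s in enumerate(sets):
                for vox in s:
                    traversals[vox].append((side, i))
        self.order: list[int] = sorted(
            traversals, key=lambda vx: (len(traversals[vx]), vx)
        )

        denom = len(self.canonical["left"]) + len(self.canonical["right"])
        injured = {s: [False] * len(self.sl_vox[s]) for s in ("left", "right")}
        inj_vox = {"left": set(), "right": set()}
        traj = []
        for vox in self.order:
            for side, i in traversals[vox]:
                if not injured[side][i]:
                    injured[side][i] = True
                    inj_vox[side] |= self.sl_vox[side][i]
            traj.append((len(inj_vox["left"]) + len(inj_vox["right"])) / denom)
        self.trajectory = np.asarray(traj)

    def prefix_for_target(self, target: float, tol: float = 0.05) -> tuple[int, float]:
        """Smallest greedy prefix whose burden best approximates ``target``.

        Returns ``(n_voxels, achieved_burden)``; raises
        :class:`BurdenGranularityError` when no prefix lands within ``tol``.
        """
        if not 0.0 <= target <= 1.0:
            raise ValueError("target burden must lie in [0, 1]")
        if target == 0.0:
            return 0, 0.0
        if target == 1.0:  # cover every voxel traversed by any streamline
            return len(self.order), 1.0
        k = int(np.searchsorted(self.trajectory, target))
        if k >= len(self.trajectory):  # trajectory tops out at 1.0
            k = len(self.trajectory) - 1
        after = float(self.trajectory[k])
        before = float(self.trajectory[k - 1]) if k > 0 else 0.0
        # prefix of length k (value `before`, possibly the empty mask) vs k+1
        if abs(before - target) < abs(after - target):
            k, achieved = k - 1, before
        else:
            achieved = after
        if abs(achieved - target) > tol:
            raise BurdenGranularityError(
                f"target burden {target:.3f} unreachable: nearest achievable values "
                f"are {before:.3f} and {after:.3f} (granularity ~{after - before:.3f})"
            )
        return k + 1, achieved

    def mask_voxels(self, n_prefix: int) -> set[int]:
        return set(self.order[:n_prefix])


def _compose_mask(grid: VoxelGrid, voxels: set[int]) -> LesionMask:
    arr = np.zeros(grid.shape, dtype=np.uint8)
    if voxels:
        arr[np.unravel_index(np.fromiter(voxels, dtype=np.int64), grid.shape)] = 1
    return LesionMask(grid=arr, affine=grid.affine)


def plant_lesion_mask(
    left: TractBundle,
    right: TractBundle,
    target_burden: float,
    grid: VoxelGrid,
    rng: np.random.Generator | None = None,
    tol: float = 0.05,
    n_background_voxels: int = 0,
    avoid_voxels: set[int] | None = None,
    geometry: TractGeometry | None = None,
) -> LesionMask:
    """Plant a lesion mask so the recomputed tract burden hits ``target_burden``.

    On-tract voxels follow the greedy trajectory of :class:`TractGeometry`
    (within ``tol`` absolute). Optional background voxels are drawn uniformly
    outside the tract (and outside ``avoid_voxels``) and cannot injure the
    bundle. Deterministic given ``rng``.
    """
    geom = geometry or TractGeometry(left, right, grid)
    k, _achieved = geom.prefix_for_target(target_burden, tol=tol)
    voxels = geom.mask_voxels(k)
    if n_background_voxels > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        forbidden = geom.all_voxels | (avoid_voxels or set())
        complement = np.setdiff1d(
            np.arange(grid.n_voxels(), dtype=np.int64),
            np.fromiter(forbidden, dtype=np.int64),
            assume_unique=False,
        )
        take = min(n_background_voxels, complement.size)
        voxels |= set(rng.choice(complement, size=take, replace=False).tolist())
    return _compose_mask(grid, voxels)


# ----------------------------------------------------------------- cohort


@dataclass
class Cohort:
    """A generated cohort: EMR records, imaging, and latent ground truth."""

    config: SynthConfig
    records: list[PatientRecord]
    bundles: list[TractBundle]
    grid: VoxelGrid
    masks: dict[str, LesionMask]  # empty when generated without imaging
    truth: "object"  # pandas DataFrame: latent groups and planted burdens

    def burden_table(self):
        """Per-patient burden columns (planted/achieved values) as a DataFrame."""
        cols = ["patient_id", "uf_burden", "fornix_burden", "total_lesion_volume"]
        return self.truth[cols].copy()

    def analysis_table(self, dicts=None):
        """Phenotype the records and merge burden columns; drops excluded rows."""
        from .phenotype import classify_table

        tab = classify_table(self.records, dicts)
        merged = tab.merge(self.burden_table(), on="patient_id")
        return merged[merged["stratum"] != "excluded"].reset_index(drop=True)

    def write(self, out_dir) -> None:
        """Write EMR CSV, covariates CSV, NIfTI masks, TRK+TCK bundles, truth."""
        from . import io as mio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_emr_csv(self.records, out / "emr.csv")
        mio.write_covariates_csv(self.records, out / "covariates.csv")
        self.config.to_yaml(out / "synth_config.yaml")
        self.truth.to_csv(out / "latent_truth.csv", index=False)
        bdir = out / "bundles"
        bdir.mkdir(exist_ok=True)
        for b in self.bundles:
            mio.save_bundle(b, bdir / f"{b.name}.trk", grid=self.grid)
            mio.save_bundle(b, bdir / f"{b.name}.tck")
        if self.masks:
            mdir = out / "masks"
            mdir.mkdir(exist_ok=True)
            for pid, mask in self.masks.items():
                mio.save_mask(mask, mdir / f"{pid}.nii.gz")


def _truncated_poisson(rng, lam, high, size=None):
    x = rng.poisson(lam, size=size)
    return np.minimum(x, high)


def make_cohort(config: SynthConfig, with_imaging: bool = True) -> Cohort:
    """Generate a full synthetic cohort under ``config``.

    Each patient gets a latent anxiety group; EMR fields are written so the
    phenotyping rules recover it (subject to ``phq_missing_rate``, which
    silently drops the confirming PHQ of some no-anxiety patients, excluding
    them downstream). With imaging enabled, each patient receives a lesion
    mask planted at the group's UF burden mean plus noise, a severity-
    independent fornix overlap, and background lesions scaled by group.
    Reproducible given ``config.seed``.
    """
    import pandas as pd

    master = np.random.default_rng(config.seed)
    r_group, r_cov, r_emr, r_burden, r_mask = master.spawn(5)
    n = config.n_patients

    groups = r_group.choice(3, size=n, p=np.asarray(config.group_props))
    age = np.clip(r_cov.normal(47.7, 11.4, n), 18.0, 90.0)
    sex = np.where(r_cov.random(n) < 0.80, "F", "M")
    race = r_cov.choice(RACE_LEVELS, size=n, p=np.asarray(RACE_PROPS))
    tbv = r_cov.normal(1.15e6, 1.1e5, n)

    means = np.asarray(config.burden_means)
    uf_target = np.clip(
        r_burden.normal(means[groups], config.burden_noise_sd), 0.0, 1.0
    )
    fornix_target = np.clip(
        r_burden.normal(config.fornix_burden_mean, config.burden_noise_sd, n), 0.0, 1.0
    )
    extra = np.asarray(config.total_lesion_extra)
    background_mm3 = np.maximum(r_burden.normal(extra[groups], 1500.0), 0.0)
    depressed = (groups > 0) & (r_emr.random(n) < config.depression_rate)

    grid = VoxelGrid(
        shape=config.grid_shape,
        affine=np.diag([config.voxel_size_mm] * 3 + [1.0]),
    )
    bundles: list[TractBundle] = []
    masks: dict[str, LesionMask] = {}
    uf_geom = fx_geom = None
    if with_imaging:
        bundles = make_toy_bundles(
            config.grid_shape,
            config.voxel_size_mm,
            config.n_streamlines_per_side,
            seed=int(master.integers(2**31)),
        )
        uf_geom = TractGeometry(bundles[0], bundles[1], grid)
        fx_geom = TractGeometry(bundles[2], bundles[3], grid)
    else:
        bundles = []

    records: list[PatientRecord] = []
    truth_rows = []
    vox_vol = grid.voxel_volume_mm3
    bg_pool = np.empty(0, dtype=np.int64)
    if with_imaging:
        all_tract_vox = uf_geom.all_voxels | fx_geom.all_voxels
        bg_pool = np.setdiff1d(
            np.arange(grid.n_voxels(), dtype=np.int64),
            np.fromiter(all_tract_vox, dtype=np.int64),
        )

    for i in range(n):
        pid = f"P{i:04d}"
        g = int(groups[i])
        mri_date = _EPOCH + dt.timedelta(days=int(r_emr.integers(0, 1461)))
        rec = PatientRecord(
            patient_id=pid,
            icd10_codes={"G35"},
            mri_dates=[mri_date],
            age=float(age[i]),
            sex=str(sex[i]),
            race=str(race[i]),
            total_brain_volume=float(tbv[i]),
        )

        if g == 0:
            if r_emr.random() >= config.phq_missing_rate:
                d = mri_date + dt.timedelta(days=int(r_emr.integers(-180, 181)))
                rec.phq_obs.append(("PHQ2", 0, d))
                if r_emr.random() < 0.5:
                    rec.phq_obs.append(("PHQ9", 0, d))
        else:
            if g == 2:
                rec.icd10_codes.add(str(r_emr.choice(ANXIETY_CODES)))
                rec.medications.add(str(r_emr.choice(ANXIOLYTICS)))
            elif r_emr.random() < 0.5:
                rec.icd10_codes.add(str(r_emr.choice(ANXIETY_CODES)))
            else:
                rec.medications.add(str(r_emr.choice(ANXIOLYTICS)))
            lam = config.phq2_means[g - 1]
            for _ in range(int(r_emr.integers(1, 3))):
                d = mri_date + dt.timedelta(days=int(r_emr.integers(-180, 181)))
                rec.phq_obs.append(
                    ("PHQ2", int(_truncated_poisson(r_emr, lam, 6)), d)
                )
            if depressed[i]:
                u = r_emr.random()
                if u < 0.4:
                    rec.icd10_codes.add(str(r_emr.choice(DEPRESSION_CODES)))
                elif u < 0.7:
                    rec.medications.add(str(r_emr.choice(ANTIDEPRESSANTS)))
                else:
                    rec.icd10_codes.add(str(r_emr.choice(DEPRESSION_CODES)))
                    rec.medications.add(str(r_emr.choice(ANTIDEPRESSANTS)))

        if r_emr.random() < config.promis_rate:
            d = mri_date + dt.timedelta(days=int(r_emr.integers(-90, 91)))
            for dom in EMOTIONAL_DOMAINS:
                val = r_emr.normal(50.0 - config.promis_effect * g, 8.0)
                rec.promis_obs.append((dom, float(val), d))
            for dom in PHYSICAL_DOMAINS:
                val = r_emr.normal(50.0 - 0.5 * config.promis_effect * g, 8.0)
                rec.promis_obs.append((dom, float(val), d))

        records.append(rec)

        row = {
            "patient_id": pid,
            "group": g,
            "depressed": bool(depressed[i]),
            "uf_target": float(uf_target[i]),
            "fornix_target": float(fornix_target[i]),
        }
        if with_imaging:
            k_uf, uf_achieved = uf_geom.prefix_for_target(float(uf_target[i]))
            k_fx, fx_achieved = fx_geom.prefix_for_target(float(fornix_target[i]))
            n_bg = int(round(background_mm3[i] / vox_vol))
            voxels = uf_geom.mask_voxels(k_uf) | fx_geom.mask_voxels(k_fx)
            if n_bg > 0:
                take = min(n_bg, bg_pool.size)
                voxels |= set(
                    r_mask.choice(bg_pool, size=take, replace=False).tolist()
                )
            mask = _compose_mask(grid, voxels)
            masks[pid] = mask
            row.update(
                uf_burden=uf_achieved,
                fornix_burden=fx_achieved,
                total_lesion_volume=float(mask.grid.sum()) * vox_vol,
            )
        else:
            row.update(
                uf_burden=float(uf_target[i]),
                fornix_burden=float(fornix_target[i]),
                total_lesion_volume=float(background_mm3[i]),
            )
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    return Cohort(
        config=config,
        records=records,
        bundles=bundles,
        grid=grid,
        masks=masks,
        truth=truth,
    )
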