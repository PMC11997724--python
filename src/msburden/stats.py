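"""Statistical layer: burden GAMs, effect sizes, group tests, FDR control.

The central model is a Gaussian generalized additive model

    outcome ~ predictor + sex + total_brain_volume + s(age)

with a penalized cubic B-spline of age (basis dimension 4; smoothing weight
chosen by AIC), fitted with statsmodels' GLMGam. The predictor is either the
binary anxiety diagnosis contrast (severe vs none), the ordinal anxiety
severity code (0/1/2 entered as a single parametric slope), or the binary
depression contrast. The reported T is the Wald statistic of the parametric
predictor term; effect size is Cohen's f-squared comparing the full model to
the same model with the predictor dropped, with a percentile bootstrap CI over
patients.

Group-level tests (ANOVA / chi-squared / Shapiro-Wilk / paired and unpaired t)
and the Benjamini-Hochberg step-up are thin, exactly specified kernels; the
BH step-up is written out rather than delegated so its contract is testable
against brute-force enumeration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "ModelResult",
    "fit_burden_gam",
    "cohens_f2",
    "cohens_d",
    "bh_fdr",
    "demographic_battery",
    "promis_comparisons",
    "sensitivity_suite",
    "rejection_rate",
]

PREDICTORS = ("diagnosis_binary", "severity_ordinal", "depression_binary")


@dataclass
class ModelResult:
    """Fitted-model summary for one hypothesis."""

    term: str
    estimate: float
    T: float
    p: float
    cohens_f2: float
    f2_ci: tuple[float, float] | None
    n: int
    formula_descriptor: str
    r2_full: float
    r2_reduced: float


def cohens_f2(r2_full: float, r2_reduced: float) -> float:
    """f^2 = (R2_full - R2_reduced) / (1 - R2_full)."""
    if not 0.0 <= r2_reduced <= r2_full:
        raise ValueError("need 0 <= R2_reduced <= R2_full")
    if r2_full >= 1.0:
        raise ValueError("R2_full must be < 1")
    return (r2_full - r2_reduced) / (1.0 - r2_full)


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean(a) - mean(b)) / pooled SD (n-1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        raise ValueError("pooled SD is zero; d undefined")
    return float((a.mean() - b.mean()) / pooled)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejected at level q).

    adjusted p_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj <= q


# ------------------------------------------------------------------- GAM


def _design(table: pd.DataFrame, outcome: str, predictor: str):
    """Subset rows, build (y, exog, age, n) for one hypothesis."""
    t = table.copy()
    if predictor == "diagnosis_binary":
        t = t[t["stratum"].isin(["none", "severe"])]
        x = (t["stratum"] == "severe").astype(float)
        groups = t["stratum"]
    elif predictor == "severity_ordinal":
        t = t[t["stratum"].isin(["none", "mild", "severe"])]
        x = t["anxiety_severity_code"].astype(float)
        groups = t["stratum"]
    elif predictor == "depression_binary":
        t = t[t["depression"].isin(["no_depression", "depression"])]
        x = (t["depression"] == "depression").astype(float)
        groups = t["depression"]
    else:
        raise ValueError(f"unknown predictor {predictor!r}; expected one of {PREDICTORS}")

    needed = [outcome, "age", "sex", "total_brain_volume"]
    keep = t[needed].notna().all(axis=1)
    t, x, groups = t[keep], x[keep], groups[keep]

    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError(f"{predictor}: fewer than 2 groups present")
    if counts.min() < 10:
        raise ValueError(
            f"{predictor}: smallest group has {counts.min()} rows (< 10): "
            f"{counts.to_dict()}"
        )

    y = t[outcome].to_numpy(dtype=float)
    sex_male = (t["sex"].astype(str).str.upper().str.startswith("M")).astype(float)
    tbv = t["total_brain_volume"].to_numpy(dtype=float)
    tbv = (tbv - tbv.mean()) / tbv.std()  # conditioning only; T is invariant
    exog = np.column_stack([np.ones(len(t)), x.to_numpy(dtype=float), sex_male, tbv])
    age = t["age"].to_numpy(dtype=float)
    return y, exog, age


def _fit(y, exog, age, age_spline, spline_df, alpha):
    """Fit the GAM (or its forced-linear-age reduction); returns (result, alpha)."""
    if age_spline == "linear":
        # an unpenalized spline of dimension 2 is exactly a linear age term
        X = np.column_stack([exog, age])
        res = sm.GLM(y, X, family=sm.families.Gaussian()).fit()
        return res, None
    bs = BSplines(age[:, None], df=[spline_df], degree=[3], include_intercept=False)
    if alpha is None:
        gam = GLMGam(y, exog=exog, smoother=bs, alpha=[1.0])
        try:
            alpha = list(gam.select_penweight()[0])
        except Exception:
            alpha = [1.0]
    res = GLMGam(y, exog=exog, smoother=bs, alpha=alpha).fit()
    return res, alpha


def _r2(y, fitted) -> float:
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - rss / tss if tss > 0 else 0.0


def fit_burden_gam(
    table: pd.DataFrame,
    outcome: str,
    predictor: str = "severity_ordinal",
    age_spline: str = "cubic",
    spline_df: int = 4,
    alpha=None,
    f2_bootstrap: int = 0,
    seed: int = 0,
) -> ModelResult:
    """Fit outcome ~ predictor + sex + total_brain_volume + s(age).

    Returns the parametric predictor term's estimate, Wald T, two-sided p,
    and Cohen's f-squared against the predictor-dropped reduced model. With
    ``f2_bootstrap`` = B > 0, a percentile bootstrap over patients (B
    resamples, smoothing weight held at the full-fit value) gives the f2 CI.
    """
    y, exog, age = _design(table, outcome, predictor)
    res, alpha_used = _fit(y, exog, age, age_spline, spline_df, alpha)
    r2_full = _r2(y, np.asarray(res.fittedvalues))
    res_red, _ = _fit(y, np.delete(exog, 1, axis=1), age, age_spline, spline_df, alpha_used)
    r2_red = _r2(y, np.asarray(res_red.fittedvalues))
    f2 = cohens_f2(r2_full, min(r2_red, r2_full))

    ci = None
    if f2_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = len(y)
        vals = np.empty(f2_bootstrap)
        for b in range(f2_bootstrap):
            idx = rng.integers(0, n, n)
            rb, _ = _fit(y[idx], exog[idx], age[idx], age_spline, spline_df, alpha_used)
            rrb, _ = _fit(
                y[idx], np.delete(exog[idx], 1, axis=1), age[idx],
                age_spline, spline_df, alpha_used,
            )
            r2f = _r2(y[idx], np.asarray(rb.fittedvalues))
            r2r = min(_r2(y[idx], np.asarray(rrb.fittedvalues)), r2f)
            vals[b] = cohens_f2(r2f, r2r) if r2f < 1.0 else np.nan
        vals = vals[np.isfinite(vals)]
        ci = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))

    spline_desc = "s(age)" if age_spline == "cubic" else "age"
    return ModelResult(
        term=predictor,
        estimate=float(res.params[1]),
        T=float(res.tvalues[1]),
        p=float(res.pvalues[1]),
        cohens_f2=float(f2),
        f2_ci=ci,
        n=len(y),
        formula_descriptor=f"{outcome} ~ {predictor} + sex + total_brain_volume + {spline_desc}",
        r2_full=float(r2_full),
        r2_reduced=float(r2_red),
    )


# --------------------------------------------------------------- batteries


def demographic_battery(table: pd.DataFrame) -> pd.DataFrame:
    """ANOVA for continuous and chi-squared for categorical demographics.

    Each variable is tested under two contrasts: anxiety diagnosis (none vs
    severe) and anxiety severity (all three groups). Returns a tidy frame
    with columns variable, contrast, test, statistic, p.
    """
    t = table[table["stratum"].isin(["none", "mild", "severe"])]
    contrasts = {
        "diagnosis": ["none", "severe"],
        "severity": ["none", "mild", "severe"],
    }
    rows = []
    for contrast, levels in contrasts.items():
        sub = t[t["stratum"].isin(levels)]
        for var in ("age", "phq2_mean"):
            samples = [
                sub.loc[sub["stratum"] == lv, var].dropna().to_numpy() for lv in levels
            ]
            samples = [s for s in samples if len(s) >= 2]
            if len(samples) < 2:
                continue
            if all(np.var(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
                stat, p = 0.0, 1.0  # identical constant groups
            else:
                stat, p = sps.f_oneway(*samples)
            rows.append((var, contrast, "anova", float(stat), float(p)))
        for var in ("sex", "race"):
            ct = pd.crosstab(sub["stratum"], sub[var])
            ct = ct.loc[:, ct.sum(axis=0) > 0]
            if ct.shape[0] < 2 or ct.shape[1] < 2:
                continue
            stat, p, _dof, _exp = sps.chi2_contingency(ct)
            rows.append((var, contrast, "chi2", float(stat), float(p)))
    return pd.DataFrame(rows, columns=["variable", "contrast", "test", "statistic", "p"])


def promis_comparisons(table: pd.DataFrame, q: float = 0.05) -> dict:
    """PROMIS summary-score comparisons across anxiety strata.

    Shapiro-Wilk normality per group x measure; unpaired t (severe vs none)
    per summary; paired t (emotional vs physical) within each group, each
    with Cohen's d; BH-FDR over the five-contrast family.
    """
    t = table[table["stratum"].isin(["none", "mild", "severe"])]
    t = t.dropna(subset=["promis_physical", "promis_emotional"])

    shapiro_rows = []
    for stratum, g in t.groupby("stratum"):
        for measure in ("promis_physical", "promis_emotional"):
            x = g[measure].to_numpy()
            if len(x) >= 3:
                w, p = sps.shapiro(x)
                shapiro_rows.append((stratum, measure, float(w), float(p)))

    contrast_rows = []
    none_g = t[t["stratum"] == "none"]
    severe_g = t[t["stratum"] == "severe"]
    for measure in ("promis_emotional", "promis_physical"):
        a, b = severe_g[measure].to_numpy(), none_g[measure].to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            stat, p = sps.ttest_ind(a, b)
            contrast_rows.append(
                {
                    "contrast": f"severe_vs_none:{measure}",
                    "test": "unpaired_t",
                    "statistic": float(stat),
                    "p": float(p),
                    "cohens_d": cohens_d(a, b),
                }
            )
    for stratum in ("none", "mild", "severe"):
        g = t[t["stratum"] == stratum]
        if len(g) < 2:
            continue
        emo = g["promis_emotional"].to_numpy()
        phy = g["promis_physical"].to_numpy()
        diff = emo - phy
        if diff.std(ddof=1) == 0:
            # identical summaries per patient: no paired difference to test
            stat, p, d = (0.0, 1.0, 0.0) if diff.mean() == 0 else (np.inf, 0.0, np.inf)
        else:
            stat, p = sps.ttest_rel(emo, phy)
            d = float(diff.mean() / diff.std(ddof=1))
        contrast_rows.append(
            {
                "contrast": f"{stratum}:emotional_vs_physical",
                "test": "paired_t",
                "statistic": float(stat),
                "p": float(p),
                "cohens_d": d,
            }
        )

    contrasts = pd.DataFrame(contrast_rows)
    if not contrasts.empty:
        adj, rej = bh_fdr(contrasts["p"].to_numpy(), q=q)
        contrasts["p_fdr"] = adj
        contrasts["significant"] = rej
    shapiro = pd.DataFrame(
        shapiro_rows, columns=["stratum", "measure", "W", "p"]
    )
    return {"shapiro": shapiro, "contrasts": contrasts}


SENSITIVITY_MODELS = (
    ("fornix_burden", "diagnosis_binary"),
    ("fornix_burden", "severity_ordinal"),
    ("uf_burden", "depression_binary"),
    ("total_lesion_volume", "diagnosis_binary"),
    ("total_lesion_volume", "severity_ordinal"),
    ("total_lesion_volume", "depression_binary"),
)


def sensitivity_suite(table: pd.DataFrame, q: float = 0.05, **gam_kwargs) -> pd.DataFrame:
    """Specificity models with BH-FDR applied within the suite.

    Fornix burden vs anxiety (control tract), UF burden vs depression
    (control phenotype), and total lesion volume vs anxiety diagnosis,
    anxiety severity, and depression (general psychopathology).
    """
    rows = []
    for outcome, predictor in SENSITIVITY_MODELS:
        res = fit_burden_gam(table, outcome, predictor, **gam_kwargs)
        rows.append(
            {
                "outcome": outcome,
                "predictor": predictor,
                "estimate": res.estimate,
                "T": res.T,
                "p": res.p,
                "cohens_f2": res.cohens_f2,
                "n": res.n,
            }
        )
    report = pd.DataFrame(rows)
    adj, rej = bh_fdr(report["p"].to_numpy(), q=q)
    report["p_fdr"] = adj
    report["significant"] = rej
    return report


# -------------------------------------------------------------- simulation


def rejection_rate(
    config,
    n_seeds: int,
    outcome: str = "uf_burden",
    predictor: str = "severity_ordinal",
    alpha_level: float = 0.05,
    base_seed: int = 0,
    require_positive_T: bool = False,
) -> float:
    """Monte-Carlo rejection rate of the burden GAM over regenerated cohorts.

    With a planted effect this estimates power; with equal group means it
    estimates the empirical type-I error. Cohorts are generated at the table
    level (no voxel planting) so the statistic under test is the GAM itself.
    A rare cohort draw that cannot satisfy the model's minimum group size is
    skipped and replaced by the next seed, so the rate is always over
    ``n_seeds`` fitted replicates; the seed sequence is deterministic.
    """
    from .synth import make_cohort

    hits = 0
    fitted = 0
    offset = 0
    while fitted < n_seeds:
        cfg = dataclasses.replace(config, seed=base_seed + offset)
        offset += 1
        coh = make_cohort(cfg, with_imaging=False)
        try:
            res = fit_burden_gam(coh.analysis_table(), outcome, predictor)
        except ValueError:  # group too small in this draw
            continue
        fitted += 1
        ok = res.p < alpha_level
        if require_positive_T:
            ok = ok and res.T > 0
        hits += ok
    return hits / n_seeds
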