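"""End-to-end orchestration: synth -> phenotype -> burden -> stats.

A run is a pure function of (inputs, config, seed): every stage writes its
intermediate CSV, the stats stage writes a JSON and a text report, and a
manifest records package/library versions, the seed, and a hash of the
resolved configuration so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as mio
from .burden import tract_burden, total_lesion_volume
from .phenotype import CodeDictionaries, classify_table
from .stats import fit_burden_gam, demographic_battery, promis_comparisons, sensitivity_suite
from .synth import SynthConfig, make_cohort

log = logging.getLogger("msburden")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    Either ``synth`` is set (the cohort is generated) or the four input paths
    are set (EMR CSV, covariates CSV, masks directory, bundle paths keyed by
    name UF_left/UF_right/fornix_left/fornix_right) — not neither.
    """

    out_dir: str
    seed: int = 0
    synth: SynthConfig | None = None
    emr: str | None = None
    covariates: str | None = None
    masks_dir: str | None = None
    bundles: dict[str, str] = field(default_factory=dict)
    dictionaries: str | None = None
    stats_bootstrap: int = 1000
    alpha: float = 0.05
    q: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.synth is None and self.emr is None:
            raise ValueError("config needs either a synth block or real input paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            m = yaml.safe_load(fh) or {}
        synth = m.pop("synth", None)
        if synth is not None:
            for key in ("group_props", "burden_means", "total_lesion_extra",
                        "grid_shape", "phq2_means"):
                if key in synth:
                    synth[key] = tuple(synth[key])
            seed = m.get("seed", 0)
            synth.setdefault("seed", seed)
            synth = SynthConfig(**synth)
        stats_block = m.pop("stats", {}) or {}
        return cls(
            out_dir=m["out_dir"],
            seed=int(m.get("seed", 0)),
            synth=synth,
            emr=m.get("emr"),
            covariates=m.get("covariates"),
            masks_dir=m.get("masks_dir"),
            bundles=m.get("bundles", {}) or {},
            dictionaries=m.get("dictionaries"),
            stats_bootstrap=int(stats_block.get("bootstrap", 1000)),
            alpha=float(stats_block.get("alpha", 0.05)),
            q=float(stats_block.get("q", 0.05)),
            log_level=m.get("log_level", "INFO"),
        )

    def config_hash(self) -> str:
        m = dataclasses.asdict(self)
        blob = json.dumps(m, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_inputs(config: RunConfig) -> list[str]:
    """Non-mutating diagnostics: file existence, header sanity, EMR schema."""
    diags: list[str] = []
    if config.synth is not None:
        return diags
    for label, path in (("emr", config.emr), ("covariates", config.covariates)):
        if path is None or not Path(path).exists():
            diags.append(f"{label}: missing file {path}")
    if config.emr and Path(config.emr).exists():
        try:
            df = pd.read_csv(config.emr, keep_default_na=False)
            diags.extend(mio.validate_emr_frame(df))
        except Exception as exc:  # malformed CSV
            diags.append(f"emr: unreadable ({exc})")
    if config.masks_dir is None or not Path(config.masks_dir).is_dir():
        diags.append(f"masks_dir: missing directory {config.masks_dir}")
    for name in ("UF_left", "UF_right", "fornix_left", "fornix_right"):
        path = config.bundles.get(name)
        if path is None or not Path(path).exists():
            diags.append(f"bundles: missing {name} ({path})")
            continue
        try:
            mio.load_bundle(path, name=name)
        except Exception as exc:
            diags.append(f"bundles: {name} unreadable ({exc})")
    if config.masks_dir and Path(config.masks_dir).is_dir():
        for f in sorted(Path(config.masks_dir).glob("*.nii*")):
            try:
                mio.load_mask(f)
            except Exception as exc:
                diags.append(f"masks: {f.name} unreadable ({exc})")
    return diags


def _burden_frame(masks, uf_pair, fx_pair, grid) -> pd.DataFrame:
    """Score every patient's mask against both tracts (long + wide outputs)."""
    long_rows = []
    wide_rows = []
    for pid in sorted(masks):
        mask = masks[pid]
        tlv = total_lesion_volume(mask)
        wide = {"patient_id": pid, "total_lesion_volume": tlv}
        for tract, (left, right) in (("UF", uf_pair), ("fornix", fx_pair)):
            res = tract_burden(left, right, mask, grid, tract_name=tract)
            long_rows.append(
                {
                    "patient_id": pid,
                    "tract": tract,
                    "injured_vol_l": res.injured_volume_left,
                    "injured_vol_r": res.injured_volume_right,
                    "canonical_vol_l": res.canonical_volume_left,
                    "canonical_vol_r": res.canonical_volume_right,
                    "burden": res.burden,
                    "total_lesion_volume": tlv,
                }
            )
            wide[f"{tract.lower()}_burden"] = res.burden
        wide_rows.append(wide)
    return pd.DataFrame(long_rows), pd.DataFrame(wide_rows)


def run_all(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict and writes everything."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dicts = (
        CodeDictionaries.from_yaml(config.dictionaries)
        if config.dictionaries
        else CodeDictionaries.default()
    )

    # ---- stage: synth / inputs
    try:
        if config.synth is not None:
            log.info("stage synth: generating cohort n=%d", config.synth.n_patients)
            cohort = make_cohort(config.synth, with_imaging=True)
            records = cohort.records
            masks = cohort.masks
            bundles = {b.name: b for b in cohort.bundles}
            grid = cohort.grid
            mio.write_emr_csv(records, out / "emr.csv")
            mio.write_covariates_csv(records, out / "covariates.csv")
        else:
            log.info("stage inputs: reading EMR %s", config.emr)
            records = mio.read_emr_csv(config.emr, config.covariates)
            bundles = None  # loaded in the burden stage
            masks = None
            grid = None
    except StageError:
        raise
    except Exception as exc:
        raise StageError("synth" if config.synth is not None else "inputs", str(exc))

    # ---- stage: phenotype
    try:
        pheno = classify_table(records, dicts)
        pheno.to_csv(out / "strata.csv", index=False)
        log.info(
            "stage phenotype: %d records -> %s",
            len(pheno),
            pheno["stratum"].value_counts().to_dict(),
        )
    except Exception as exc:
        raise StageError("phenotype", str(exc))

    # ---- stage: burden
    try:
        if bundles is None:
            bundles = {}
            for name in ("UF_left", "UF_right", "fornix_left", "fornix_right"):
                path = config.bundles.get(name)
                if path is None or not Path(path).exists():
                    raise ValueError(f"missing bundle path for {name}: {path}")
                bundles[name] = mio.load_bundle(path, name=name)
            if config.masks_dir is None or not Path(config.masks_dir).is_dir():
                raise ValueError(f"missing masks directory: {config.masks_dir}")
            masks = {}
            for f in sorted(Path(config.masks_dir).glob("*.nii*")):
                masks[f.name.split(".")[0]] = mio.load_mask(f)
            if not masks:
                raise ValueError(f"no NIfTI masks found in {config.masks_dir}")
            grid = next(iter(masks.values())).voxel_grid()
        missing = [n for n in ("UF_left", "UF_right", "fornix_left", "fornix_right")
                   if n not in bundles]
        if missing:
            raise ValueError(f"missing bundles: {missing}")
        uf_pair = (bundles["UF_left"], bundles["UF_right"])
        fx_pair = (bundles["fornix_left"], bundles["fornix_right"])
        burden_long, burden_wide = _burden_frame(masks, uf_pair, fx_pair, grid)
        burden_long.to_csv(out / "burden.csv", index=False)
        log.info("stage burden: scored %d masks on %d voxels", len(masks),
                 int(np.prod(grid.shape)) if grid else 0)
    except Exception as exc:
        raise StageError("burden", str(exc))

    # ---- stage: stats
    try:
        table = pheno.merge(burden_wide, on="patient_id")
        table = table[table["stratum"] != "excluded"].reset_index(drop=True)
        table.to_csv(out / "analysis.csv", index=False)
        report = build_report(
            table,
            bootstrap=config.stats_bootstrap,
            q=config.q,
            seed=config.seed,
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("stats", str(exc))

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "report.txt", "w") as fh:
        fh.write(render_report(report))
    manifest = {
        "package": {"msburden": __version__},
        "python": platform.python_version(),
        "libraries": _library_versions(),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_records": len(records),
        "n_masks": len(masks),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", out)
    return report


def build_report(table: pd.DataFrame, bootstrap: int = 1000, q: float = 0.05,
                 seed: int = 0) -> dict:
    """The full statistical report on an assembled analysis table."""
    hypothesis = {}
    for label, predictor in (
        ("uf_vs_anxiety_diagnosis", "diagnosis_binary"),
        ("uf_vs_anxiety_severity", "severity_ordinal"),
    ):
        res = fit_burden_gam(
            table, "uf_burden", predictor, f2_bootstrap=bootstrap, seed=seed
        )
        hypothesis[label] = _model_dict(res)

    sens = sensitivity_suite(table, q=q)
    promis = promis_comparisons(table, q=q)
    demo = demographic_battery(table)
    strata_counts = table["stratum"].value_counts().to_dict()
    phq2 = (
        table.groupby("stratum")["phq2_mean"].mean().dropna().round(6).to_dict()
    )
    return {
        "group_counts": {k: int(v) for k, v in strata_counts.items()},
        "phq2_mean_by_stratum": phq2,
        "hypothesis_models": hypothesis,
        "sensitivity_models": sens.to_dict(orient="records"),
        "promis": {
            "shapiro": promis["shapiro"].to_dict(orient="records"),
            "contrasts": promis["contrasts"].to_dict(orient="records"),
        },
        "demographics": demo.to_dict(orient="records"),
    }


def _model_dict(res) -> dict:
    return {
        "term": res.term,
        "estimate": res.estimate,
        "T": res.T,
        "p": res.p,
        "cohens_f2": res.cohens_f2,
        "f2_ci": list(res.f2_ci) if res.f2_ci else None,
        "n": res.n,
        "formula": res.formula_descriptor,
    }


def render_report(report: dict) -> str:
    lines = ["MS white-matter lesion burden report", "=" * 38, ""]
    lines.append("Anxiety strata: " + json.dumps(report["group_counts"], sort_keys=True))
    lines.append(
        "Mean PHQ-2 by stratum: "
        + json.dumps(report["phq2_mean_by_stratum"], sort_keys=True)
    )
    lines.append("")
    lines.append("Hypothesis models (unadjusted alpha = .05)")
    for name, m in report["hypothesis_models"].items():
        ci = m["f2_ci"]
        ci_txt = f" [95% CI {ci[0]:.3f}-{ci[1]:.3f}]" if ci else ""
        lines.append(
            f"  {name}: T = {m['T']:.2f}, P = {m['p']:.3g}, "
            f"Cohen f2 = {m['cohens_f2']:.3f}{ci_txt}, n = {m['n']}"
        )
    lines.append("")
    lines.append("Sensitivity models (BH-FDR within suite)")
    for m in report["sensitivity_models"]:
        lines.append(
            f"  {m['outcome']} ~ {m['predictor']}: T = {m['T']:.2f}, "
            f"P(FDR) = {m['p_fdr']:.3g}, significant = {m['significant']}"
        )
    lines.append("")
    lines.append("PROMIS contrasts (BH-FDR within family)")
    for m in report["promis"]["contrasts"]:
        lines.append(
            f"  {m['contrast']} ({m['test']}): T = {m['statistic']:.2f}, "
            f"P(FDR) = {m.get('p_fdr', float('nan')):.3g}, d = {m['cohens_d']:.2f}"
        )
    lines.append("")
    lines.append("Demographics")
    for m in report["demographics"]:
        lines.append(
            f"  {m['variable']} [{m['contrast']}] ({m['test']}): "
            f"stat = {m['statistic']:.3f}, P = {m['p']:.3g}"
        )
    return "\n".join(lines) + "\n"


def _library_versions() -> dict:
    import nibabel
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "nibabel": nibabel.__version__,
    }
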