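"""Configuration-driven orchestration: reproduce the result tables from a
cohort file (real or synthetic) with deterministic seeding.

``run_all`` writes four CSVs — the correlation table, the cross-validated
prediction table, the Bayes-factor prior-robustness curves, and the
subsample-variability curves — plus a YAML run log recording the seed and
software versions.  Every stochastic stage draws from a named substream of
the master seed so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import TraitAssociation
from .prediction import CVConfig, TraitPredictivity
from .powercalc import subsample_variability
from .synthdata import ROIS, TRAITS

__all__ = ["RunConfig", "load_cohort", "run_table1", "run_table2", "run_all"]

logger = logging.getLogger(__name__)

#: substream offsets for the master seed, one per stochastic stage
_SEED_STREAMS = {"table2": 1000, "subsample": 2000}


@dataclass
class RunConfig:
    """Settings of a full analysis run."""

    cohort_path: str | Path | None = None
    traits: tuple[str, ...] = TRAITS
    rois: tuple[str, ...] = ROIS
    cv: CVConfig = field(default_factory=CVConfig)
    prior_width: float = 1.0
    robustness_widths: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)
    subsample_sizes: tuple[int, ...] = (15, 25, 50, 94)
    subsample_draws: int = 2000
    seed: int = 0
    out_dir: str | Path = "dopaproxy_out"
    published_rounding: bool = False
    column_map: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cv" in raw:
            raw["cv"] = CVConfig(**raw["cv"])
        for key in ("traits", "rois", "robustness_widths", "subsample_sizes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def load_cohort(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load and validate a cohort CSV (one row per participant).

    ``column_map`` renames file columns to the canonical names
    (digit_span, listening_span, bis11, sebr, bas, ki_<roi>).  k_i^cer
    columns must be numeric and positive where present.
    """
    table = pd.read_csv(path)
    if column_map:
        missing = [c for c in column_map if c not in table.columns]
        if missing:
            raise KeyError(
                f"mapped column(s) {missing} not in file; available: {list(table.columns)}"
            )
        table = table.rename(columns=column_map)
    ki_cols = [c for c in table.columns if c.startswith("ki_")]
    for col in ki_cols:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric k_i^cer value at row {row}, column {col!r}")
        if (vals.dropna() <= 0).any():
            raise ValueError(f"non-positive k_i^cer value in column {col!r}")
        table[col] = vals
    if "participant_id" in table.columns and table["participant_id"].duplicated().any():
        raise ValueError("participant_id values must be unique")
    # per-measure exclusion flags: exclude_<trait> == True blanks the trait
    for col in [c for c in table.columns if c.startswith("exclude_")]:
        trait = col[len("exclude_"):]
        if trait in table.columns:
            n_excl = int(table[col].astype(bool).sum())
            if n_excl:
                logger.info("excluding %d row(s) for %s via %s", n_excl, trait, col)
                table.loc[table[col].astype(bool), trait] = np.nan
    logger.info("cohort: %d rows, %d columns; missingness: %s",
                len(table), table.shape[1],
                {c: int(table[c].isna().sum()) for c in table.columns
                 if table[c].isna().any()})
    return table


def _round_table1(tbl: pd.DataFrame) -> pd.DataFrame:
    out = tbl.copy()
    out["r"] = out["r"].round(3)
    out["p_one_sided"] = out["p_one_sided"].round(3)
    out["p_adjusted"] = out["p_adjusted"].round(3)
    out["bf01_0_1"] = out["bf01_0_1"].round(2)
    out["bf01_m1_1"] = out["bf01_m1_1"].round(2)
    return out


def run_table1(cohort: pd.DataFrame, config: RunConfig):
    """Correlation table: 5 traits x 3 ROIs with r, one-sided p,
    Holm-adjusted p, BF01(0,1), BF01(-1,1)."""
    model = TraitAssociation(cohort, traits=config.traits, rois=config.rois,
                             prior_width=config.prior_width)
    results = model.fit()
    table = _round_table1(results.table) if config.published_rounding else results.table
    return results, table


def run_table2(cohort: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Cross-validated prediction table: per trait x ROI the R^2 and RMSE
    means, standard errors and permutation p-values."""
    rows = []
    base_seed = config.seed + _SEED_STREAMS["table2"]
    for i, trait in enumerate(config.traits):
        for j, roi in enumerate(config.rois):
            cfg = CVConfig(k=config.cv.k, repeats=config.cv.repeats,
                           n_permutations=config.cv.n_permutations,
                           seed=base_seed + 31 * i + j)
            col = f"ki_{roi}" if f"ki_{roi}" in cohort.columns else roi
            res = TraitPredictivity(cohort[trait], cohort[col], cfg).fit()
            rows.append({
                "trait": trait, "roi": roi,
                "r2_mean": res.cv.r2_mean, "r2_stderr": res.cv.r2_stderr,
                "perm_p_r2": res.perm.perm_p_r2 if res.perm else np.nan,
                "rmse_mean": res.cv.rmse_mean, "rmse_stderr": res.cv.rmse_stderr,
                "perm_p_rmse": res.perm.perm_p_rmse if res.perm else np.nan,
            })
    return pd.DataFrame(rows)


def run_all(config: RunConfig, cohort: pd.DataFrame | None = None) -> Path:
    """Run every stage and write the report directory.

    Per-trait failures are collected and re-raised at the end so one bad
    column does not abort the whole run.
    """
    if cohort is None:
        if config.cohort_path is None:
            raise ValueError("either a cohort table or config.cohort_path is required")
        cohort = load_cohort(config.cohort_path, config.column_map)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    errors: list[str] = []

    try:
        assoc_results, table1 = run_table1(cohort, config)
        table1.to_csv(out / "table1.csv", index=False)
        rob = assoc_results.robustness(widths=config.robustness_widths)
        rob.to_csv(out / "robustness_curves.csv", index=False)
    except Exception as exc:  # noqa: BLE001 - aggregated below
        errors.append(f"table1/robustness: {exc}")

    try:
        table2 = run_table2(cohort, config)
        table2.to_csv(out / "table2.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        errors.append(f"table2: {exc}")

    try:
        frames = []
        sub_seed = config.seed + _SEED_STREAMS["subsample"]
        for i, trait in enumerate(config.traits):
            for j, roi in enumerate(config.rois):
                col = f"ki_{roi}" if f"ki_{roi}" in cohort.columns else roi
                xy = cohort[[trait, col]].dropna()
                sizes = [s for s in config.subsample_sizes if s <= len(xy)] or [len(xy)]
                curve = subsample_variability(
                    xy[trait], xy[col], sizes,
                    n_draws=config.subsample_draws, seed=sub_seed + 31 * i + j)
                frames.append(pd.DataFrame({
                    "trait": trait, "roi": roi, "size": curve.sizes,
                    "ci_low": curve.ci_low, "ci_high": curve.ci_high,
                }))
        pd.concat(frames, ignore_index=True).to_csv(out / "subsample_curves.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        errors.append(f"subsample: {exc}")

    import scipy

    log = {
        "seed": config.seed,
        "traits": list(config.traits),
        "rois": list(config.rois),
        "cv": {"k": config.cv.k, "repeats": config.cv.repeats,
               "n_permutations": config.cv.n_permutations},
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
        "errors": errors,
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)

    if errors:
        raise RuntimeError("run completed with errors: " + "; ".join(errors))
    return out
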