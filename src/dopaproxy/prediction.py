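"""Out-of-sample predictive accuracy of a trait for k_i^cer.

Simple linear regression (ki ~ 1 + trait) evaluated by repeated k-fold
cross-validation: per repeat the data are freshly partitioned into k folds of
near-equal size; each fold is predicted from a model fitted on the other
k - 1 folds; the pooled out-of-fold predictions of the repeat give one R^2
and one RMSE.  Means and standard errors are taken across repeats
(std_err = SD / sqrt(repeats)).

The permutation null shuffles the outcome, reruns a single cross-validation
per permutation, and reports p as the literal proportion of permutations
whose accuracy is at least as good as the observed one (ties inclusive;
a (b+1)/(B+1) smoothed estimator is available via ``smoothed=True``).

Out-of-sample R^2 can be negative: a superfluous predictor reliably does
worse than predicting the grand mean, which is exactly the signature the
null cohorts reproduce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CVConfig",
    "CVResult",
    "PermutationResult",
    "r2_score",
    "rmse",
    "kfold_indices",
    "cross_validate",
    "permutation_test",
    "TraitPredictivity",
    "PredictivityResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and permutation settings (study: k=10, 100 repeats,
    5000 permutations)."""

    k: int = 10
    repeats: int = 100
    n_permutations: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")


def r2_score(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; negative when the
    predictions are worse than the mean of ``y_true``."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("y_true is constant; R^2 undefined")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def rmse(y_true, y_pred) -> float:
    """Root mean squared prediction error (units of y)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("inputs must have equal length >= 1")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def kfold_indices(n: int, k: int, seed: int | np.random.Generator) -> list[np.ndarray]:
    """Seeded random partition of range(n) into k folds with sizes differing
    by at most one (the first n % k folds get the extra element)."""
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [order[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def _cv_single(x: np.ndarray, y: np.ndarray, k: int, rng: np.random.Generator,
               collect_errors: bool = False):
    """One repeat: fresh partition, per-fold OLS fit, pooled predictions."""
    n = x.size
    folds = kfold_indices(n, k, rng)
    preds = np.empty(n)
    for val in folds:
        tr = np.ones(n, dtype=bool)
        tr[val] = False
        xt, yt = x[tr], y[tr]
        xm, ym = xt.mean(), yt.mean()
        sxx = float((xt - xm) @ (xt - xm))
        if sxx == 0.0:
            logger.info("constant predictor in a training split; intercept-only fold fit")
            preds[val] = ym
        else:
            slope = float((xt - xm) @ (yt - ym)) / sxx
            preds[val] = ym + slope * (x[val] - xm)
    errors = preds - y if collect_errors else None
    return r2_score(y, preds), rmse(y, preds), errors


@dataclass(frozen=True)
class CVResult:
    """Cross-validated accuracy summaries for one (trait, ROI) pair."""

    r2_mean: float
    r2_stderr: float
    rmse_mean: float
    rmse_stderr: float
    r2_per_repeat: np.ndarray = field(repr=False)
    rmse_per_repeat: np.ndarray = field(repr=False)
    per_repeat_errors: np.ndarray | None = field(repr=False, default=None)
    config: CVConfig | None = None


def cross_validate(x, y, cfg: CVConfig, collect_errors: bool = True) -> CVResult:
    """Repeated k-fold cross-validation of y ~ 1 + x.

    Rows with a missing value in either variable are dropped first (pairwise
    deletion).  ``per_repeat_errors`` holds the (repeats, n) matrix of
    out-of-fold prediction errors (prediction minus truth), the display data
    of per-participant error plots.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < cfg.k:
        raise ValueError(f"need at least k={cfg.k} complete pairs, have {x.size}")
    rng = np.random.default_rng(cfg.seed)
    r2s = np.empty(cfg.repeats)
    rmses = np.empty(cfg.repeats)
    errors = np.empty((cfg.repeats, x.size)) if collect_errors else None
    for rep in range(cfg.repeats):
        r2s[rep], rmses[rep], err = _cv_single(x, y, cfg.k, rng, collect_errors)
        if collect_errors:
            errors[rep] = err
    div = np.sqrt(cfg.repeats)
    return CVResult(
        r2_mean=float(r2s.mean()),
        r2_stderr=float(r2s.std(ddof=1) / div) if cfg.repeats > 1 else 0.0,
        rmse_mean=float(rmses.mean()),
        rmse_stderr=float(rmses.std(ddof=1) / div) if cfg.repeats > 1 else 0.0,
        r2_per_repeat=r2s,
        rmse_per_repeat=rmses,
        per_repeat_errors=errors,
        config=cfg,
    )


@dataclass(frozen=True)
class PermutationResult:
    perm_p_r2: float
    perm_p_rmse: float
    null_r2: np.ndarray = field(repr=False)
    null_rmse: np.ndarray = field(repr=False)
    observed: CVResult = None


def permutation_test(x, y, cfg: CVConfig, smoothed: bool = False,
                     observed: CVResult | None = None) -> PermutationResult:
    """Permutation null for the cross-validated accuracy.

    Each permutation shuffles y (breaking the participant-wise pairing),
    runs one cross-validation replicate, and records its pooled R^2 and
    RMSE.  p is the proportion of permutations at least as accurate as the
    observed summary (>= for R^2, <= for RMSE); ``smoothed`` switches to the
    (b+1)/(B+1) estimator.
    """
    if cfg.n_permutations < 1:
        raise ValueError("need at least one permutation")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if observed is None:
        observed = cross_validate(x, y, cfg, collect_errors=False)
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 1)
    null_r2 = np.empty(cfg.n_permutations)
    null_rmse = np.empty(cfg.n_permutations)
    for b in range(cfg.n_permutations):
        y_perm = rng.permutation(y)
        null_r2[b], null_rmse[b], _ = _cv_single(x, y_perm, cfg.k, rng)
    b_r2 = int(np.sum(null_r2 >= observed.r2_mean))
    b_rmse = int(np.sum(null_rmse <= observed.rmse_mean))
    B = cfg.n_permutations
    if smoothed:
        p_r2, p_rmse = (b_r2 + 1) / (B + 1), (b_rmse + 1) / (B + 1)
    else:
        p_r2, p_rmse = b_r2 / B, b_rmse / B
    return PermutationResult(perm_p_r2=p_r2, perm_p_rmse=p_rmse,
                             null_r2=null_r2, null_rmse=null_rmse, observed=observed)


class PredictivityResults:
    """Results wrapper pairing the CV summaries with the permutation null."""

    def __init__(self, cv: CVResult, perm: PermutationResult | None) -> None:
        self.cv = cv
        self.perm = perm

    def summary(self) -> str:
        lines = [
            "Cross-validated simple linear regression (ki ~ 1 + trait)",
            "---------------------------------------------------------",
            f"R^2  : mean {self.cv.r2_mean: .5f}  std_err {self.cv.r2_stderr: .6f}",
            f"RMSE : mean {self.cv.rmse_mean: .6f}  std_err {self.cv.rmse_stderr: .3g}",
        ]
        if self.perm is not None:
            lines.append(
                f"permutation p (B={self.perm.null_r2.size}): "
                f"R^2 {self.perm.perm_p_r2:.4f}, RMSE {self.perm.perm_p_rmse:.4f}"
            )
        return "\n".join(lines)


class TraitPredictivity:
    """Model object: can this trait predict k_i^cer out of sample?

    ``fit()`` runs the repeated cross-validation and (if
    ``cfg.n_permutations > 0``) the permutation test.
    """

    def __init__(self, x, y, cfg: CVConfig = CVConfig()) -> None:
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.cfg = cfg

    def fit(self) -> PredictivityResults:
        cv = cross_validate(self.x, self.y, self.cfg)
        perm = None
        if self.cfg.n_permutations > 0:
            perm = permutation_test(self.x, self.y, self.cfg, observed=cv)
        return PredictivityResults(cv, perm)
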