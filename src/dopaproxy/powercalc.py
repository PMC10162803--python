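"""Power analysis for one-sided Pearson correlation tests, effect-size
conversions, and subsample-variability curves.

Two power models are provided:

``method="nct"`` (default)
    Noncentral-t (point-biserial) formulation: the test statistic
    t = r*sqrt(n-2)/sqrt(1-r^2) is compared against the null t critical
    value, and under the alternative t is modelled as noncentral t with
    df = n - 2 and noncentrality delta = sqrt(n) * rho / sqrt(1 - rho^2)
    (equivalently delta = d/2 * sqrt(n) with Cohen's d = 2r/sqrt(1-r^2)).
    This is the computation behind the commonly used desk calculators and
    reproduces the study's printed sensitivity values (rho = 0.29 at power
    0.9 and 0.25 at power 0.8 for n = 94, alpha = .05 one-sided; required
    N = 614 / 850 for rho = 0.1 at power 0.8 / 0.9).

``method="exact"``
    Fully exact bivariate-normal computation: the critical r* is obtained
    from the null t distribution and the power is the upper-tail integral of
    the exact sampling density of r (Hotelling's form) above r*.  This is
    the distributionally exact answer — validated against Monte-Carlo
    rejection rates in the test suite — and differs from the noncentral-t
    model in the third decimal (e.g. detectable rho 0.296 rather than 0.291
    at n = 94, power 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.optimize import brentq

from .association import exact_r_density, pearson_r

__all__ = [
    "PowerQuery",
    "SubsampleCurve",
    "critical_r",
    "power_one_sided_r",
    "detectable_rho",
    "required_n",
    "r_to_d",
    "d_to_r",
    "subsample_variability",
]


@dataclass(frozen=True)
class PowerQuery:
    """Validated inputs of a power computation."""

    alpha: float = 0.05
    n: int = 94
    rho: float = 0.1
    power: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if not abs(self.rho) < 1.0:
            raise ValueError("|rho| must be < 1")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Critical sample correlation of the one-sided ("greater") test:
    r* = t*/sqrt(df + t*^2) with t* the upper-alpha quantile at df = n-2."""
    df = n - 2
    t_crit = stats.t.ppf(1.0 - alpha, df)
    return float(t_crit / np.sqrt(df + t_crit * t_crit))


def power_one_sided_r(rho: float, n: int, alpha: float = 0.05,
                      method: str = "nct") -> float:
    """Power of the one-sided (positive) Pearson correlation test."""
    PowerQuery(alpha=alpha, n=n, rho=rho, power=0.5)  # validate alpha/n/rho
    df = n - 2
    if method == "nct":
        t_crit = stats.t.ppf(1.0 - alpha, df)
        delta = np.sqrt(n) * rho / np.sqrt(1.0 - rho * rho)
        return float(stats.nct.sf(t_crit, df, delta))
    if method == "exact":
        if rho == 0.0:
            return alpha
        r_star = critical_r(n, alpha)
        # integrate the tail away from the density mode (~rho): the spike of
        # a near-unity rho would otherwise be missed by adaptive quadrature
        if rho > r_star:
            val, _ = integrate.quad(lambda r: exact_r_density(r, rho, n), -1.0, r_star,
                                    epsabs=1e-12, epsrel=1e-10, limit=200)
            val = 1.0 - val
        else:
            val, _ = integrate.quad(lambda r: exact_r_density(r, rho, n), r_star, 1.0,
                                    epsabs=1e-12, epsrel=1e-10, limit=200)
        if not np.isfinite(val):
            raise RuntimeError("power quadrature failed")
        return float(min(max(val, 0.0), 1.0))
    raise ValueError(f"unknown method {method!r}")


def detectable_rho(n: int, power: float, alpha: float = 0.05,
                   method: str = "nct") -> float:
    """Smallest positive rho detectable at the requested power (sensitivity
    analysis); solved by bracketed root-finding to 1e-6 in rho."""
    PowerQuery(alpha=alpha, n=n, rho=0.1, power=power)

    def gap(rho: float) -> float:
        return power_one_sided_r(rho, n, alpha, method=method) - power

    lo, hi = 1e-9, 1.0 - 1e-9
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("no detectable rho in (0, 1) for these settings")
    return float(brentq(gap, lo, hi, xtol=1e-6))


def required_n(rho: float, power: float, alpha: float = 0.05,
               method: str = "nct", n_max: int = 10_000_000) -> int:
    """Smallest integer n reaching the requested power at effect size rho."""
    PowerQuery(alpha=alpha, n=4, rho=rho, power=power)
    if rho <= 0:
        raise ValueError("required_n needs rho > 0")
    lo, hi = 4, 8
    while power_one_sided_r(rho, hi, alpha, method=method) < power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError("required n exceeds n_max")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_one_sided_r(rho, mid, alpha, method=method) >= power:
            hi = mid
        else:
            lo = mid
    return hi


def r_to_d(r: float) -> float:
    """Cohen's d equivalent of a correlation: d = 2r / sqrt(1 - r^2)."""
    if not abs(r) < 1.0:
        raise ValueError("|r| must be < 1")
    return 2.0 * r / np.sqrt(1.0 - r * r)


def d_to_r(d: float) -> float:
    """Inverse conversion: r = d / sqrt(4 + d^2)."""
    return d / np.sqrt(4.0 + d * d)


@dataclass(frozen=True)
class SubsampleCurve:
    """Percentile spread of the sample correlation by subsample size."""

    sizes: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_draws: int
    seed: int

    @property
    def widths(self) -> np.ndarray:
        return self.ci_high - self.ci_low


def subsample_variability(
    x,
    y,
    sizes,
    n_draws: int = 10_000,
    seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5),
    max_retries: int = 100,
) -> SubsampleCurve:
    """Sampling variability of r by subsample size.

    For each size, draws ``n_draws`` subsamples *with replacement* from the
    complete pairs, computes Pearson r for each, and reports the percentile
    interval.  Degenerate resamples (a constant column) are redrawn up to
    ``max_retries`` times.  Illustrates how small-N correlation estimates
    scatter: at N = 15 a true-null correlation spans roughly [-0.5, 0.5].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    sizes = np.asarray(sizes, dtype=int)
    if np.any(sizes < 4):
        raise ValueError("all subsample sizes must be >= 4")
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    rng = np.random.default_rng(seed)
    lo = np.empty(sizes.size)
    hi = np.empty(sizes.size)
    for i, m in enumerate(sizes):
        rs = np.empty(n_draws)
        for b in range(n_draws):
            for attempt in range(max_retries + 1):
                idx = rng.integers(0, x.size, size=m)
                xs, ys = x[idx], y[idx]
                if np.ptp(xs) > 0 and np.ptp(ys) > 0:
                    rs[b], _ = pearson_r(xs, ys)
                    break
            else:
                raise RuntimeError(f"degenerate resamples persisted at size {m}")
        lo[i], hi[i] = np.percentile(rs, ci)
    return SubsampleCurve(sizes=sizes, ci_low=lo, ci_high=hi,
                          n_draws=n_draws, seed=seed)
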