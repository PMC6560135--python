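"""Inhibition indices, the dose-response summary, and the statistical
tests for comparing strains.

Growth inhibition is quantified by the inhibition index

    i = (mu_control - mu_acetate) / mu_control,

which is 0 for no inhibition and 1 for complete growth arrest.  Because the
index is a ratio of normally distributed means, equality of two indices is
tested by a bootstrap: each replicate set of growth rates is resampled with
replacement, an index is computed per resample and per strain, and the
p-value is the upper-tail probability, under the recentred bootstrap
distribution of the index difference, of exceeding the observed difference
in magnitude.  Because the difference distribution is two-sided, a p-value
cutoff of 0.03 (0.005) corresponds to an overall significance level of
0.06 (0.01); significance calls use those printed thresholds.

Growth-rate (or yield) equality between strains is tested with Welch's t
test, the unequal-variance two-sample t test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ReplicateSet",
    "InhibitionResult",
    "DoseResponseFit",
    "TestResult",
    "StatsError",
    "inhibition_index",
    "bootstrap_index_test",
    "welch_test",
    "fit_dose_response",
    "SIGNIFICANCE_CUTOFFS",
]

# Two-sided p-value cutoffs and the significance levels they correspond to.
SIGNIFICANCE_CUTOFFS = {0.06: 0.03, 0.01: 0.005}


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


@dataclass
class ReplicateSet:
    """Replicate growth rates (1/h) for one strain x condition."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise StatsError(f"replicate set {self.label!r} is empty")
        if not np.all(np.isfinite(self.values)):
            raise StatsError(f"non-finite growth rate in {self.label!r}")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class InhibitionResult:
    """Inhibition index with its bootstrap mean and percentile interval."""

    i: float
    mu_control: float
    mu_acetate: float
    boot_mean: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan


@dataclass
class DoseResponseFit:
    """Exponential-with-baseline dose response mu(c) = b + a * exp(-k c)."""

    baseline_b: float
    amplitude: float
    decay_k: float
    rss: float


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float = math.nan
    n_boot: int = 0
    seed: Optional[int] = None


def inhibition_index(mu_control: float, mu_acetate: float) -> float:
    """Inhibition index i = (mu_control - mu_acetate) / mu_control."""
    if mu_control <= 0:
        raise StatsError("control growth rate must be positive")
    i = (mu_control - mu_acetate) / mu_control
    if not 0.0 <= i <= 1.0:
        warnings.warn(
            f"inhibition index {i:.3f} outside [0, 1] "
            f"(mu_control={mu_control}, mu_acetate={mu_acetate})",
            stacklevel=2,
        )
    return i


def _boot_means(rng: np.random.Generator, values: np.ndarray, n_boot: int) -> np.ndarray:
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    return values[idx].mean(axis=1)


def bootstrap_index_test(
    groupA_control: ReplicateSet,
    groupA_acetate: ReplicateSet,
    groupB_control: ReplicateSet,
    groupB_acetate: ReplicateSet,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[TestResult, InhibitionResult, InhibitionResult]:
    """Bootstrap equality test for the inhibition indices of two strains.

    All four replicate sets are resampled with replacement ``n_boot``
    times; an index per resample and strain gives bootstrap means and
    percentile 95% intervals, and the index-difference distribution,
    recentred at zero, gives the p-value as the probability of exceeding
    the observed difference in magnitude.  Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise StatsError("n_boot must be >= 1")
    for g in (groupA_control, groupA_acetate, groupB_control, groupB_acetate):
        if g.n < 2:
            raise StatsError(f"replicate set {g.label!r} needs >= 2 values")
    rng = np.random.default_rng(seed)
    mAc = _boot_means(rng, groupA_control.values, n_boot)
    mAa = _boot_means(rng, groupA_acetate.values, n_boot)
    mBc = _boot_means(rng, groupB_control.values, n_boot)
    mBa = _boot_means(rng, groupB_acetate.values, n_boot)
    iA = (mAc - mAa) / mAc
    iB = (mBc - mBa) / mBc

    def observed(ctrl: ReplicateSet, ace: ReplicateSet) -> float:
        return inhibition_index(float(ctrl.values.mean()), float(ace.values.mean()))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        i_obs_A = observed(groupA_control, groupA_acetate)
        i_obs_B = observed(groupB_control, groupB_acetate)
    d_obs = i_obs_A - i_obs_B
    d = iA - iB
    centred = d - d.mean()
    p = (np.count_nonzero(centred >= abs(d_obs)) + 1) / (n_boot + 1)

    def summarize(i_obs: float, boots: np.ndarray, ctrl, ace) -> InhibitionResult:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        return InhibitionResult(
            i=i_obs,
            mu_control=float(ctrl.values.mean()),
            mu_acetate=float(ace.values.mean()),
            boot_mean=float(boots.mean()),
            ci_low=float(lo),
            ci_high=float(hi),
        )

    test = TestResult(
        statistic=float(d_obs),
        p_value=float(p),
        method="bootstrap",
        n_boot=n_boot,
        seed=seed,
    )
    return (
        test,
        summarize(i_obs_A, iA, groupA_control, groupA_acetate),
        summarize(i_obs_B, iB, groupB_control, groupB_acetate),
    )


def welch_test(a: ReplicateSet, b: ReplicateSet) -> TestResult:
    """Welch's t test (unequal variances) for two replicate sets."""
    if a.n < 2 or b.n < 2:
        raise StatsError("Welch's test needs >= 2 values per group")
    va, vb = a.values.var(ddof=1), b.values.var(ddof=1)
    if va == 0 and vb == 0:
        raise StatsError("zero variance in both replicate sets")
    res = stats.ttest_ind(a.values, b.values, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="welch",
        df=float(res.df),
    )


def fit_dose_response(
    acetate_conc: Sequence[float],
    mu: Sequence[float],
) -> DoseResponseFit:
    """Least-squares fit of mu(c) = b + a * exp(-k * c) to dose-response data.

    ``b`` is the baseline growth rate at saturating acetate, ``a`` the
    inhibitable amplitude (so the fitted curve equals b + a at c = 0), and
    ``k`` the exponential decay constant per mM.
    """
    c = np.asarray(acetate_conc, dtype=float)
    y = np.asarray(mu, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise StatsError("concentration and growth-rate vectors must align")
    if c.size < 4:
        raise StatsError("need at least 4 (concentration, mu) pairs")
    if np.any(c < 0):
        raise StatsError("concentrations must be non-negative")
    if np.allclose(c, c[0]):
        raise StatsError("degenerate design: all concentrations equal")

    spread = float(y.max() - y.min())
    b0 = max(float(y.min()), 0.0)
    a0 = max(spread, 1e-6)
    cpos = c[c > 0]
    k0 = 1.0 / float(cpos.mean()) if cpos.size else 0.01

    def resid(p):
        b, a, k = p
        return y - (b + a * np.exp(-k * c))

    res = optimize.least_squares(
        resid,
        x0=[b0, a0, k0],
        bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    b, a, k = (float(v) for v in res.x)
    return DoseResponseFit(
        baseline_b=b, amplitude=a, decay_k=k, rss=float(np.sum(res.fun**2))
    )
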