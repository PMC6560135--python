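"""Simulation studies of estimator calibration.

These studies regenerate synthetic experiments under the study conditions
(four replicates, 3% replicate coefficient of variation) and quantify how
well the fitting and testing machinery recovers the generative truth:

* :func:`growth_recovery_study` -- bias and interval coverage of the
  fitted growth rate and biomass yield.  Coverage is reported at two
  levels: per-fit intervals (estimate +/- 2 standard errors from the
  nonlinear fit, the level at which the ~95% nominal coverage applies)
  and per-experiment intervals (replicate mean +/- 2 SEM, whose exact
  small-sample coverage with n replicates is P(|t_{n-1}| < 2), i.e. 86.1%
  at n = 4).
* :func:`bootstrap_calibration_study` -- type-I error of the bootstrap
  inhibition-index equality test at a given p-value cutoff, over many
  simulated null quadruples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .growth_kinetics import fit_uptake_secretion, mean_2sem
from .inhibition_stats import ReplicateSet, bootstrap_index_test
from .synthetic_data import SimulationConfig, simulate_growth_experiment

__all__ = [
    "RecoveryStudy",
    "CalibrationStudy",
    "growth_recovery_study",
    "bootstrap_calibration_study",
    "binomial_band",
]


def binomial_band(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Central 95% band for an empirical proportion around probability p."""
    half = z * math.sqrt(p * (1.0 - p) / n)
    return p - half, p + half


@dataclass
class RecoveryStudy:
    """Results of the parameter-recovery simulation study."""

    n_experiments: int
    n_fits: int
    mu_true: float
    yield_true: float
    mu_grand_mean: float
    mu_grand_2sem: float
    yield_grand_mean: float
    yield_grand_2sem: float
    mu_cover_fit: float       # per-fit mu_hat +/- 2 SE covering the replicate rate
    yield_cover_fit: float    # per-fit Y_hat +/- 2 SE covering the true yield
    mu_cover_2sem: float      # per-experiment mean +/- 2 SEM covering mu_true

    @property
    def mu_unbiased(self) -> bool:
        return abs(self.mu_grand_mean - self.mu_true) <= self.mu_grand_2sem

    @property
    def yield_unbiased(self) -> bool:
        return abs(self.yield_grand_mean - self.yield_true) <= self.yield_grand_2sem


def growth_recovery_study(
    n_experiments: int = 200,
    base_config: SimulationConfig | None = None,
    seed: int = 0,
) -> RecoveryStudy:
    """Repeat the simulate-then-fit cycle and measure bias and coverage.

    Each experiment simulates ``n_replicates`` flasks from ``base_config``
    (with a fresh child seed) and fits the joint growth + glucose model per
    replicate, yielding mu_hat and Y_hat with standard errors.
    """
    cfg = base_config or SimulationConfig()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_experiments)

    mu_means, y_means = [], []
    mu_fit_cover, y_fit_cover, mu_2sem_cover = [], [], []
    n_fits = 0
    for s in child_seeds:
        exp = simulate_growth_experiment(replace(cfg, seed=int(s)))
        mu_hats, y_hats = [], []
        for rep in exp.replicates:
            with warnings.catch_warnings():
                # curves are exponential by construction; the flag only
                # reacts to the relative OD noise at low densities
                warnings.simplefilter("ignore", UserWarning)
                fit = fit_uptake_secretion(
                    (rep.curve.times, rep.metabolites["glucose"]),
                    rep.curve,
                    mode="uptake",
                )
            n_fits += 1
            mu_hats.append(fit.mu_used)
            y_hats.append(fit.yield_Y)
            mu_fit_cover.append(abs(fit.mu_used - rep.mu_rep) <= 2.0 * fit.mu_se)
            y_fit_cover.append(abs(fit.yield_Y - cfg.yield_true) <= 2.0 * fit.yield_se)
        m, two_sem = mean_2sem(mu_hats)
        mu_means.append(m)
        y_means.append(mean_2sem(y_hats)[0])
        mu_2sem_cover.append(abs(m - cfg.mu_true) <= two_sem)

    mu_means = np.asarray(mu_means)
    y_means = np.asarray(y_means)
    return RecoveryStudy(
        n_experiments=n_experiments,
        n_fits=n_fits,
        mu_true=cfg.mu_true,
        yield_true=cfg.yield_true,
        mu_grand_mean=float(mu_means.mean()),
        mu_grand_2sem=mean_2sem(mu_means)[1],
        yield_grand_mean=float(y_means.mean()),
        yield_grand_2sem=mean_2sem(y_means)[1],
        mu_cover_fit=float(np.mean(mu_fit_cover)),
        yield_cover_fit=float(np.mean(y_fit_cover)),
        mu_cover_2sem=float(np.mean(mu_2sem_cover)),
    )


@dataclass
class CalibrationStudy:
    """Type-I error of the bootstrap index test under the null."""

    n_simulations: int
    p_cutoff: float
    nominal_level: float
    rejection_rate: float
    band_low: float
    band_high: float

    @property
    def within_band(self) -> bool:
        return self.band_low <= self.rejection_rate <= self.band_high


def bootstrap_calibration_study(
    n_simulations: int = 600,
    n_replicates: int = 4,
    cv: float = 0.03,
    mu_control: float = 0.70,
    mu_acetate: float = 0.35,
    n_boot: int = 2000,
    p_cutoff: float = 0.03,
    nominal_level: float = 0.06,
    seed: int = 0,
) -> CalibrationStudy:
    """Simulate null quadruples (both strains share the same true rates)
    and record how often the bootstrap test rejects at ``p_cutoff``."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for k in range(n_simulations):
        groups = []
        for label, mu in (
            ("A_control", mu_control), ("A_acetate", mu_acetate),
            ("B_control", mu_control), ("B_acetate", mu_acetate),
        ):
            vals = rng.normal(mu, cv * mu, size=n_replicates)
            groups.append(ReplicateSet(label, vals))
        test, _, _ = bootstrap_index_test(
            *groups, n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1))
        )
        rejections += test.p_value < p_cutoff
    lo, hi = binomial_band(nominal_level, n_simulations)
    return CalibrationStudy(
        n_simulations=n_simulations,
        p_cutoff=p_cutoff,
        nominal_level=nominal_level,
        rejection_rate=rejections / n_simulations,
        band_low=lo,
        band_high=hi,
    )
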