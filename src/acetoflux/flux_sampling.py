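"""Uniform sampling of the measurement-constrained flux polytope, flux
distribution modes, and the growth-rate-normalized cross-condition
comparison.

The feasible set {v : N v = 0, lb <= v <= ub} is reduced to a
full-dimensional polytope by the null-space parameterization v = v0 + K a,
where v0 is a feasible interior point and K a basis of the null space of N
(augmented with rows pinning fluxes whose bounds coincide).  Samples are
drawn by coordinate hit-and-run with rounding: a pilot chain estimates the
sample covariance of a, whose Cholesky factor whitens the polytope
(two rounds by default) so that chords along coordinate directions have
comparable lengths; the production chain then runs in the rounded space
with burn-in and thinning.  All randomness derives from the stated seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg
from scipy.optimize import linprog

from .flux_analysis import MetabolicModel, ModelError

__all__ = [
    "FluxPolytope",
    "FluxSampleSet",
    "ConditionComparison",
    "SamplingError",
    "build_polytope",
    "sample_flux_space",
    "estimate_flux_mode",
    "compare_conditions",
]


class SamplingError(ValueError):
    """Raised when the polytope is empty or the chain cannot move."""


@dataclass
class FluxPolytope:
    """Null-space parameterization of the feasible flux set.

    ``v = v0 + K @ (T @ beta)``; the inequalities lb <= v <= ub translate
    to row constraints on alpha = T beta.  ``T`` is the rounding transform
    (identity before rounding).
    """

    v0: np.ndarray
    K: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    reaction_ids: list[str]
    subsystem: list[str]
    rounding_transform: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rounding_transform is None:
            self.rounding_transform = np.eye(self.dimension)

    @property
    def dimension(self) -> int:
        return self.K.shape[1] if self.K.size else 0

    def map_to_fluxes(self, beta: np.ndarray) -> np.ndarray:
        if self.dimension == 0:
            return np.tile(self.v0, (np.atleast_2d(beta).shape[0], 1))
        return self.v0 + np.atleast_2d(beta) @ (self.K @ self.rounding_transform).T


def _interior_point(model: MetabolicModel, fixed: np.ndarray) -> np.ndarray:
    """Feasible point maximizing the smallest slack to the free bounds."""
    n = model.n_reactions
    free = ~fixed
    n_free = int(free.sum())
    # variables: [v, t]; maximize t subject to lb_i + t <= v_i <= ub_i - t
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_ub, b_ub = [], []
    for j in np.flatnonzero(free):
        row = np.zeros(n + 1)
        row[j], row[-1] = -1.0, 1.0
        A_ub.append(row)
        b_ub.append(-model.lb[j])
        row = np.zeros(n + 1)
        row[j], row[-1] = 1.0, 1.0
        A_ub.append(row)
        b_ub.append(model.ub[j])
    A_eq = np.hstack([model.S, np.zeros((model.n_metabolites, 1))])
    t_cap = 0.5 * min(
        (model.ub[j] - model.lb[j] for j in np.flatnonzero(free)), default=1.0
    )
    bounds = [(model.lb[j], model.ub[j]) for j in range(n)] + [(0.0, t_cap)]
    for j in np.flatnonzero(fixed):
        bounds[j] = (model.lb[j], model.lb[j])
    res = linprog(
        c,
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=A_eq,
        b_eq=np.zeros(model.n_metabolites),
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        raise SamplingError(f"no feasible interior point (LP status {res.status})")
    return res.x[:n]


def _chord_limits(y: np.ndarray, a: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Step range delta such that lo <= y + delta * a <= hi."""
    with np.errstate(divide="ignore", invalid="ignore"):
        upper = np.where(a > 0, (hi - y) / a, np.where(a < 0, (lo - y) / a, np.inf))
        lower = np.where(a > 0, (lo - y) / a, np.where(a < 0, (hi - y) / a, -np.inf))
    return float(np.max(lower)), float(np.min(upper))


def _run_chain(
    rng: np.random.Generator,
    A: np.ndarray,
    y0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    n_record: int,
    stride: int,
    burn_in: int,
    d: int,
):
    """Coordinate hit-and-run; returns recorded beta matrix (n_record x d)."""
    beta = np.zeros(d)
    y = y0.copy()
    out = np.empty((n_record, d))
    recorded = 0
    step = 0
    stuck = 0
    total_steps = burn_in + n_record * stride
    while recorded < n_record:
        k = int(rng.integers(d))
        a = A[:, k]
        dmin, dmax = _chord_limits(y, a, lo, hi)
        if not math.isfinite(dmin) or not math.isfinite(dmax):
            raise SamplingError("unbounded chord: polytope is not bounded")
        if dmax - dmin < 1e-13:
            stuck += 1
            if stuck > 100 * d:
                raise SamplingError("chain stuck: repeated zero-length chords")
            delta = 0.0
        else:
            stuck = 0
            delta = rng.uniform(dmin, dmax)
        beta[k] += delta
        y = y + delta * a
        step += 1
        if step % 1000 == 0:  # control floating-point drift of the cache
            y = A @ beta + y0
        if step > burn_in and (step - burn_in) % stride == 0:
            out[recorded] = beta
            recorded += 1
        if step > 10 * total_steps + 1000:  # pragma: no cover - safety valve
            raise SamplingError("chain failed to record enough samples")
    return out


def build_polytope(
    model: MetabolicModel,
    seed: int = 0,
    rounding_rounds: int = 2,
    pilot_steps: Optional[int] = None,
    fixed_tol: float = 1e-9,
) -> FluxPolytope:
    """Reduce a (constrained) model to a rounded sampling polytope.

    Fluxes whose bounds coincide (within ``fixed_tol``) are eliminated as
    equalities; the rounding transform is the Cholesky factor of the sample
    covariance of a pilot hit-and-run chain, iterated ``rounding_rounds``
    times.
    """
    model.validate()
    fixed = (model.ub - model.lb) <= fixed_tol
    v0 = _interior_point(model, fixed)
    aug = [model.S]
    for j in np.flatnonzero(fixed):
        row = np.zeros(model.n_reactions)
        row[j] = 1.0
        aug.append(row[None, :])
    K = linalg.null_space(np.vstack(aug))
    poly = FluxPolytope(
        v0=v0,
        K=K if K.size else np.zeros((model.n_reactions, 0)),
        lb=model.lb.copy(),
        ub=model.ub.copy(),
        reaction_ids=list(model.reaction_ids),
        subsystem=list(model.subsystem),
    )
    d = poly.dimension
    if d == 0:
        return poly
    rng = np.random.default_rng(seed)
    steps = pilot_steps if pilot_steps is not None else max(100 * d, 1000)
    # restrict chord tests to rows K can actually move
    active = np.any(np.abs(poly.K) > 1e-12, axis=1) & ~fixed
    lo, hi = poly.lb[active], poly.ub[active]
    T = np.eye(d)
    for _ in range(max(0, rounding_rounds)):
        A = (poly.K @ T)[active]
        betas = _run_chain(rng, A, v0[active], lo, hi,
                           n_record=steps, stride=1, burn_in=0, d=d)
        alphas = betas @ T.T
        cov = np.cov(alphas, rowvar=False)
        cov = np.atleast_2d(cov) + 1e-12 * np.eye(d)
        try:
            T = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:  # pragma: no cover - near-degenerate
            break
    poly.rounding_transform = T
    return poly


@dataclass
class FluxSampleSet:
    """Matrix of polytope samples (draws x reactions) with chain metadata."""

    samples: np.ndarray
    reaction_ids: list[str]
    subsystem: list[str]
    n_draws: int
    burn_in: int
    thinning: int
    seed: int

    def column(self, reaction_id: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(reaction_id)]


def sample_flux_space(
    polytope: FluxPolytope,
    n_draws: int = 10_000,
    burn_in: int = 1_000,
    thinning: int = 10,
    seed: int = 0,
) -> FluxSampleSet:
    """Coordinate hit-and-run samples of the rounded flux polytope."""
    if n_draws < 1:
        raise SamplingError("n_draws must be positive")
    d = polytope.dimension
    if d == 0:
        samples = np.tile(polytope.v0, (n_draws, 1))
        return FluxSampleSet(samples, list(polytope.reaction_ids),
                             list(polytope.subsystem), n_draws, burn_in, thinning, seed)
    rng = np.random.default_rng(seed)
    fixedish = (polytope.ub - polytope.lb) <= 1e-9
    active = np.any(np.abs(polytope.K) > 1e-12, axis=1) & ~fixedish
    A_full = polytope.K @ polytope.rounding_transform
    A = A_full[active]
    betas = _run_chain(
        rng, A, polytope.v0[active], polytope.lb[active], polytope.ub[active],
        n_record=n_draws, stride=max(1, thinning), burn_in=max(0, burn_in), d=d,
    )
    samples = polytope.v0 + betas @ A_full.T
    return FluxSampleSet(
        samples=samples,
        reaction_ids=list(polytope.reaction_ids),
        subsystem=list(polytope.subsystem),
        n_draws=n_draws,
        burn_in=burn_in,
        thinning=thinning,
        seed=seed,
    )


def estimate_flux_mode(samples: Sequence[float]) -> float:
    """Mode of a sampled flux distribution via a Freedman-Diaconis histogram.

    Returns the center of the highest-count bin; ties are broken toward the
    bin nearest the sample median.  Zero-variance samples return the
    constant value.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise SamplingError("empty sample")
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        return float(x[0])
    q25, q75 = np.percentile(x, [25, 75])
    h = 2.0 * (q75 - q25) * x.size ** (-1.0 / 3.0)
    if h <= 0:
        return float(np.median(x))
    nbins = max(1, int(math.ceil((hi - lo) / h)))
    counts, edges = np.histogram(x, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best = np.flatnonzero(counts == counts.max())
    med = float(np.median(x))
    pick = best[np.argmin(np.abs(centers[best] - med))]
    return float(centers[pick])


@dataclass
class ConditionComparison:
    """Growth-rate-normalized mode comparison over a reaction subset."""

    reactions: list[str]
    modes_condition1: np.ndarray
    modes_condition2: np.ndarray
    r_squared: float


def compare_conditions(
    set1: FluxSampleSet,
    mu1: float,
    set2: FluxSampleSet,
    mu2: float,
    subsystems: Sequence[str],
) -> ConditionComparison:
    """Compare per-reaction flux modes between two conditions.

    Selects reactions whose subsystem annotation is in ``subsystems``
    (typically the five central-carbon categories), estimates the flux mode
    per reaction and condition, divides by the respective growth rate, and
    returns the paired normalized vectors with their squared Pearson
    correlation.
    """
    if mu1 <= 0 or mu2 <= 0:
        raise SamplingError("growth rates must be positive")
    if set1.reaction_ids != set2.reaction_ids:
        raise SamplingError("sample sets come from different models")
    wanted = set(subsystems)
    idx = [j for j, s in enumerate(set1.subsystem) if s in wanted]
    if not idx:
        raise SamplingError(f"no reactions in subsystems {sorted(wanted)}")
    rids = [set1.reaction_ids[j] for j in idx]
    m1 = np.array([estimate_flux_mode(set1.samples[:, j]) for j in idx]) / mu1
    m2 = np.array([estimate_flux_mode(set2.samples[:, j]) for j in idx]) / mu2
    if np.std(m1) == 0 or np.std(m2) == 0:
        raise SamplingError("zero variance in a normalized mode vector")
    r = float(np.corrcoef(m1, m2)[0, 1])
    return ConditionComparison(
        reactions=rids,
        modes_condition1=m1,
        modes_condition2=m2,
        r_squared=r * r,
    )
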