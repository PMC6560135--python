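"""Growth, uptake and secretion kinetics from batch-culture time series.

The underlying models are the constant-rate exponential growth model

    dB/dt = mu * B,   B(0) = B0      =>   B(t) = B0 * exp(mu * t)

with ``B`` the biomass in OD600 units and ``mu`` the growth rate (1/h), and
the coupled substrate-consumption model

    dG/dt = -r_glc * B(t), G(0) = G0 =>   G(t) = G0 - (B0 / Y) * (exp(mu*t) - 1)

where ``Y = mu / r_glc`` is the biomass yield (OD600 per mM) and ``r_glc``
the specific glucose uptake rate (mM per OD600 per hour).  Fermentation
by-products follow the same closed form with the uptake rate replaced by a
secretion rate and the sign of the accumulation term inverted:

    C(t) = C0 + r_sec * (B0 / mu) * (exp(mu*t) - 1)

Fitting is done by nonlinear least squares on the untransformed closed
forms, so that the OD and substrate series can share ``mu`` and ``B0`` in a
single objective.  Initial guesses come from a log-linear regression of the
OD series and from the endpoint concentrations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "RateFit",
    "KineticsError",
    "fit_exponential_growth",
    "fit_uptake_secretion",
    "compute_yield",
    "to_specific_rate",
    "mean_2sem",
]


class KineticsError(ValueError):
    """Raised when a kinetic fit is impossible on the given data."""


@dataclass
class GrowthCurve:
    """A timestamped OD600 series for one replicate culture.

    ``addition_time`` marks the moment acetate (or blank medium) was added;
    when set, fits on treated cultures only use points at or after it.
    """

    times: np.ndarray
    od: np.ndarray
    strain: str = ""
    condition: str = ""
    replicate: int = 0
    addition_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.od.shape:
            raise KineticsError("times and od must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise KineticsError("times must be strictly increasing")


@dataclass
class GrowthFit:
    """Least-squares estimates of mu and B0 over the selected window."""

    mu: float
    B0: float
    fit_window: tuple[float, float]
    sse: float
    n_points: int
    mu_se: float = math.nan
    B0_se: float = math.nan
    log_r_squared: float = math.nan
    exponential_ok: bool = True


@dataclass
class RateFit:
    """Fitted uptake or secretion kinetics for one metabolite.

    ``rate`` is positive for glucose uptake and positive for product
    secretion (the sign convention of the closed forms above).  ``yield_Y``
    is only defined for the glucose (uptake) fit.
    """

    metabolite: str
    rate: float
    C0: float
    mu_used: float
    B0_used: float
    yield_Y: Optional[float] = None
    rate_se: float = math.nan
    C0_se: float = math.nan
    yield_se: float = math.nan
    mu_se: float = math.nan
    sse: float = math.nan


def _exp_model(t: np.ndarray, b0: float, mu: float) -> np.ndarray:
    return b0 * np.exp(mu * t)


def _glucose_model(t, g0, b0, mu, yield_y):
    return g0 - (b0 / yield_y) * (np.exp(mu * t) - 1.0)


def _product_model(t, c0, rate, b0, mu):
    # limit mu -> 0: C0 + rate * B0 * t
    if abs(mu) < 1e-12:
        return c0 + rate * b0 * t
    return c0 + rate * (b0 / mu) * (np.exp(mu * t) - 1.0)


def _select_window(curve: GrowthCurve, od_ceiling: float) -> np.ndarray:
    mask = (curve.od > 0) & (curve.od < od_ceiling)
    if curve.addition_time is not None:
        mask &= curve.times >= curve.addition_time
    return mask


def fit_exponential_growth(
    curve: GrowthCurve,
    od_ceiling: float = 1.0,
    min_points: int = 3,
    r2_threshold: float = 0.98,
) -> GrowthFit:
    """Fit B(t) = B0 * exp(mu * t) to the eligible window of a growth curve.

    The window keeps points with 0 < OD < ``od_ceiling`` (growth rates are
    determined from optical densities below 1 by default) and, when an
    addition time is recorded, points at or after it.  An exponentiality
    check (R^2 of ln OD vs t against ``r2_threshold``) flags, but does not
    reject, curves that deviate from constant-rate exponential growth.
    """
    mask = _select_window(curve, od_ceiling)
    t = curve.times[mask]
    y = curve.od[mask]
    if t.size < min_points:
        raise KineticsError(
            f"only {t.size} eligible points (need >= {min_points}) "
            f"below OD {od_ceiling}"
        )
    # log-linear initial guess; exact when the data are noiseless
    slope, intercept = np.polyfit(t, np.log(y), 1)
    try:
        popt, pcov = optimize.curve_fit(
            _exp_model, t, y, p0=[math.exp(intercept), slope], maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise KineticsError(f"exponential fit did not converge: {exc}") from exc
    b0, mu = popt
    resid = y - _exp_model(t, *popt)
    ses = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    log_fit = np.polyval([slope, intercept], t)
    ss_res = float(np.sum((np.log(y) - log_fit) ** 2))
    ss_tot = float(np.sum((np.log(y) - np.mean(np.log(y))) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    ok = r2 >= r2_threshold
    if not ok:
        warnings.warn(
            f"exponentiality check failed (R^2={r2:.4f} < {r2_threshold}) for "
            f"{curve.strain}/{curve.condition} rep {curve.replicate}",
            stacklevel=2,
        )
    return GrowthFit(
        mu=float(mu),
        B0=float(b0),
        fit_window=(float(t[0]), float(t[-1])),
        sse=float(np.sum(resid**2)),
        n_points=int(t.size),
        mu_se=float(ses[1]),
        B0_se=float(ses[0]),
        log_r_squared=float(r2),
        exponential_ok=bool(ok),
    )


def _joint_glucose_fit(
    t_od: np.ndarray,
    od: np.ndarray,
    t_c: np.ndarray,
    conc: np.ndarray,
    p0: Sequence[float],
    n_reweight: int = 2,
):
    """Simultaneous weighted NLS of the OD and glucose closed forms.

    Parameters are (mu, B0, Y, G0).  The two series live on different
    scales, so residuals are reweighted by per-series noise estimates from
    the previous iteration (``n_reweight`` rounds); the parameter covariance
    is taken at the final weights.
    """
    n_od = t_od.size

    def residuals(p, w_od, w_c):
        mu, b0, yy, g0 = p
        r_od = (od - _exp_model(t_od, b0, mu)) / w_od
        r_c = (conc - _glucose_model(t_c, g0, b0, mu, yy)) / w_c
        return np.concatenate([r_od, r_c])

    w_od, w_c = 1.0, 1.0
    p = np.asarray(p0, dtype=float)
    lower = [-np.inf, 1e-12, 1e-12, -np.inf]
    res = None
    for _ in range(max(1, n_reweight)):
        res = optimize.least_squares(
            residuals, p, args=(w_od, w_c), bounds=(lower, np.inf),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        p = res.x
        raw = residuals(p, 1.0, 1.0)
        # noise estimates with df correction: 2 of the 4 shared parameters
        # are charged to each series
        s_od = math.sqrt(float(np.sum(raw[:n_od] ** 2)) / max(n_od - 2, 1))
        s_c = math.sqrt(float(np.sum(raw[n_od:] ** 2)) / max(raw.size - n_od - 2, 1))
        # guard against exactly noiseless series
        w_od = max(s_od, 1e-12)
        w_c = max(s_c, 1e-12)
    # covariance from the weighted Jacobian at the final iterate
    jac = res.jac
    try:
        cov = np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        cov = np.full((4, 4), np.nan)
    return p, cov, res


def fit_uptake_secretion(
    conc_series: tuple[np.ndarray, np.ndarray],
    growth: GrowthFit | GrowthCurve,
    mode: Literal["uptake", "secretion"],
    metabolite: str = "glucose",
    od_ceiling: float = 1.0,
) -> RateFit:
    """Fit uptake (glucose) or secretion (product) kinetics.

    ``mode='uptake'`` performs the simultaneous fit of the growth and
    glucose models sharing mu and B0 (``growth`` must then be the
    :class:`GrowthCurve` itself), returning mu, Y, G0 and the uptake rate
    r_glc = mu / Y.  ``mode='secretion'`` holds mu and B0 fixed at the
    supplied :class:`GrowthFit` values and fits only C0 and the secretion
    rate; the model is then linear in its two parameters and solved exactly.
    """
    t_c = np.asarray(conc_series[0], dtype=float)
    conc = np.asarray(conc_series[1], dtype=float)
    if t_c.shape != conc.shape or t_c.ndim != 1:
        raise KineticsError("concentration series must be 1-D, aligned arrays")

    if mode == "uptake":
        if not isinstance(growth, GrowthCurve):
            raise KineticsError("uptake mode requires the GrowthCurve for the joint fit")
        if np.all(conc == 0):
            raise KineticsError("all-zero concentration series in uptake mode")
        mask = _select_window(growth, od_ceiling)
        t_od, od = growth.times[mask], growth.od[mask]
        if t_od.size < 3:
            raise KineticsError("fewer than 3 eligible OD points in the window")
        cmask = np.ones_like(t_c, dtype=bool)
        if growth.addition_time is not None:
            cmask = t_c >= growth.addition_time
        t_cc, cc = t_c[cmask], conc[cmask]
        if t_cc.size < 3:
            raise KineticsError("fewer than 3 concentration points in the window")
        init = fit_exponential_growth(growth, od_ceiling=od_ceiling)
        g0_guess = float(cc[0])
        db = _exp_model(t_cc[-1], init.B0, init.mu) - _exp_model(t_cc[0], init.B0, init.mu)
        dg = float(cc[0] - cc[-1])
        y_guess = db / dg if dg > 0 else 0.05
        y_guess = y_guess if np.isfinite(y_guess) and y_guess > 0 else 0.05
        p, cov, res = _joint_glucose_fit(
            t_od, od, t_cc, cc, [init.mu, init.B0, y_guess, g0_guess]
        )
        mu, b0, yy, g0 = (float(v) for v in p)
        if yy <= 0:
            raise KineticsError(f"negative fitted yield ({yy:.4g})")
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        rate = mu / yy
        # delta method for r = mu / Y
        grad = np.array([1.0 / yy, 0.0, -mu / yy**2, 0.0])
        rate_var = float(grad @ cov @ grad)
        return RateFit(
            metabolite=metabolite,
            rate=rate,
            C0=g0,
            mu_used=mu,
            B0_used=b0,
            yield_Y=yy,
            rate_se=math.sqrt(max(rate_var, 0.0)),
            C0_se=float(ses[3]),
            yield_se=float(ses[2]),
            mu_se=float(ses[0]),
            sse=float(np.sum(res.fun**2)),
        )

    if mode == "secretion":
        if not isinstance(growth, GrowthFit):
            raise KineticsError("secretion mode requires a GrowthFit with mu and B0")
        mu, b0 = growth.mu, growth.B0
        if abs(mu) < 1e-12:
            basis = b0 * t_c
        else:
            basis = (b0 / mu) * (np.exp(mu * t_c) - 1.0)
        X = np.column_stack([np.ones_like(t_c), basis])
        coef, _, _, _ = np.linalg.lstsq(X, conc, rcond=None)
        c0, rate = (float(v) for v in coef)
        resid = conc - X @ coef
        sse = float(np.sum(resid**2))
        dof = max(t_c.size - 2, 1)
        sigma2 = sse / dof
        try:
            cov = sigma2 * np.linalg.inv(X.T @ X)
            ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            ses = np.array([math.nan, math.nan])
        return RateFit(
            metabolite=metabolite,
            rate=rate,
            C0=c0,
            mu_used=mu,
            B0_used=b0,
            rate_se=float(ses[1]),
            C0_se=float(ses[0]),
            sse=sse,
        )

    raise KineticsError(f"unknown mode {mode!r}")


def compute_yield(mu: float, r_glc: float) -> float:
    """Biomass yield Y = mu / r_glc (OD600 per mM)."""
    if r_glc <= 0:
        raise KineticsError("glucose uptake rate must be positive")
    return mu / r_glc


def to_specific_rate(rate: float, od_to_gdw: float = 0.47) -> float:
    """Convert mM * OD600^-1 * h^-1 to mmol * gDW^-1 * h^-1.

    ``od_to_gdw`` is the biomass conversion factor in gDW per litre per
    OD600 unit (default 0.47, a standard E. coli value).
    """
    if od_to_gdw <= 0:
        raise KineticsError("OD-to-gDW conversion factor must be positive")
    return rate / od_to_gdw


def mean_2sem(values: Sequence[float]) -> tuple[float, float]:
    """Replicate aggregate: (mean, twice the standard error of the mean)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise KineticsError("cannot aggregate an empty replicate set")
    if v.size == 1:
        return float(v[0]), math.nan
    return float(v.mean()), float(2.0 * v.std(ddof=1) / math.sqrt(v.size))
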