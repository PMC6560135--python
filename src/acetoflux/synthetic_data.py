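"""In-silico shake-flask experiments, assay plates and toy metabolic
networks with known ground truth.

The growth simulator draws a replicate-specific growth rate from a normal
distribution around the true rate (default 3% coefficient of variation,
matching the small replicate scatter of typical batch experiments) and
evaluates the exponential-growth and consumption/secretion closed forms on
the sampling grid, adding independent Gaussian measurement noise.  The
addition of acetate (or blank medium) part-way through the culture is
modelled as a step change: all concentrations and the optical density are
diluted by V_culture / (V_culture + V_added), and the acetate concentration
is raised by the nominal added amount; optionally the growth rate switches
to a post-addition (inhibited) value.

All randomness derives from a single integer seed through one
``numpy.random.Generator`` stream, so equal seeds give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .flux_analysis import MetabolicModel
from .growth_kinetics import GrowthCurve

__all__ = [
    "SimulationConfig",
    "ReplicateData",
    "GrowthExperiment",
    "PlateReads",
    "ToyNetworkSpec",
    "SyntheticDataError",
    "simulate_growth_experiment",
    "simulate_assay_plate",
    "make_toy_network",
    "mini_central_carbon",
    "CENTRAL_CARBON_SUBSYSTEMS",
]


class SyntheticDataError(ValueError):
    """Raised for invalid simulation configurations."""


# The five central-carbon subsystem annotations used for the
# cross-condition flux comparison.
CENTRAL_CARBON_SUBSYSTEMS = (
    "Glycolysis/Gluconeogenesis",
    "Citric Acid Cycle",
    "Pentose Phosphate Pathway",
    "Pyruvate Metabolism",
    "Anaplerotic Reactions",
)


@dataclass
class SimulationConfig:
    """Ground truth and sampling design for one simulated condition.

    Units: ``mu_true`` 1/h; ``B0_true`` OD600; ``yield_true`` OD600/mM;
    ``secretion_rates_true`` mM OD600^-1 h^-1 per product; ``G0`` mM;
    ``t_grid`` h; noise SDs in OD600 and mM.  ``acetate_add_time`` (h)
    triggers the dilution/addition event; ``mu_after`` is the post-addition
    growth rate when the added acetate inhibits growth.
    """

    mu_true: float = 0.65
    B0_true: float = 0.02
    yield_true: float = 0.09
    secretion_rates_true: dict[str, float] = field(
        default_factory=lambda: {"acetate": 1.5}
    )
    G0: float = 16.65
    t_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 6.01, 0.5)
    )
    od_noise_sd: float = 0.005
    conc_noise_sd: float = 0.15
    n_replicates: int = 4
    seed: int = 0
    replicate_cv: float = 0.03
    acetate_add_time: Optional[float] = None
    acetate_added_mM: float = 0.0
    added_volume_ml: float = 2.0
    culture_volume_ml: float = 50.0
    mu_after: Optional[float] = None
    strain: str = "wt"
    condition: str = ""

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        scalars = [
            self.mu_true, self.B0_true, self.yield_true, self.G0,
            self.od_noise_sd, self.conc_noise_sd, self.replicate_cv,
            self.added_volume_ml, self.culture_volume_ml, self.acetate_added_mM,
        ]
        if not all(np.isfinite(scalars)):
            raise SyntheticDataError("non-finite value in simulation config")
        if self.mu_true < 0:
            raise SyntheticDataError("mu_true must be >= 0")
        if self.B0_true <= 0 or self.yield_true <= 0:
            raise SyntheticDataError("B0_true and yield_true must be positive")
        if self.t_grid.ndim != 1 or np.any(np.diff(self.t_grid) <= 0):
            raise SyntheticDataError("t_grid must be strictly increasing")
        if self.n_replicates < 1:
            raise SyntheticDataError("need at least one replicate")
        if self.G0 < 0:
            raise SyntheticDataError("initial glucose cannot be negative")

    @property
    def dilution_factor(self) -> float:
        """(V_culture + V_added) / V_culture, e.g. 52/50 for 2 ml into 50 ml."""
        return (self.culture_volume_ml + self.added_volume_ml) / self.culture_volume_ml


@dataclass
class ReplicateData:
    """One simulated replicate: growth curve, metabolite series, and truth."""

    curve: GrowthCurve
    metabolites: dict[str, np.ndarray]
    mu_rep: float
    mu_after_rep: Optional[float] = None


@dataclass
class GrowthExperiment:
    """All replicates of one simulated strain x condition."""

    config: SimulationConfig
    replicates: list[ReplicateData]

    def to_tidy(self) -> pd.DataFrame:
        """Tidy long table: strain, condition, replicate, time_h, variable, value."""
        rows = []
        for rep in self.replicates:
            c = rep.curve
            for t, v in zip(c.times, c.od):
                rows.append((c.strain, c.condition, c.replicate, t, "od600", v))
            for name, series in rep.metabolites.items():
                for t, v in zip(c.times, series):
                    rows.append((c.strain, c.condition, c.replicate, t, name, v))
        return pd.DataFrame(
            rows,
            columns=["strain", "condition", "replicate", "time_h", "variable", "value"],
        )


def _piecewise_series(
    t: np.ndarray,
    value_pre,
    value_post,
    t_add: Optional[float],
):
    if t_add is None:
        return value_pre(t)
    out = np.empty_like(t, dtype=float)
    pre = t < t_add
    out[pre] = value_pre(t[pre])
    out[~pre] = value_post(t[~pre])
    return out


def _replicate_closed_forms(cfg: SimulationConfig, mu1: float, mu2: float):
    """Noise-free OD, glucose and product closed forms with the dilution
    step at the addition time."""
    b0, y, g0 = cfg.B0_true, cfg.yield_true, cfg.G0
    ta = cfg.acetate_add_time
    dil = 1.0 / cfg.dilution_factor  # concentration/OD multiplier at addition

    def od_pre(t):
        return b0 * np.exp(mu1 * t)

    if ta is not None:
        b_add = dil * b0 * math.exp(mu1 * ta)
        g_add = dil * (g0 - (b0 / y) * (math.exp(mu1 * ta) - 1.0))

    def od_post(t):
        return b_add * np.exp(mu2 * (t - ta))

    def glc_pre(t):
        return g0 - (b0 / y) * (np.exp(mu1 * t) - 1.0)

    def glc_post(t):
        return g_add - (b_add / y) * (np.exp(mu2 * (t - ta)) - 1.0)

    def product(rate: float, is_acetate: bool):
        def pre(t):
            if mu1 < 1e-12:
                return rate * b0 * t
            return rate * (b0 / mu1) * (np.exp(mu1 * t) - 1.0)

        def post(t):
            p_add = dil * float(pre(np.asarray([ta]))[0])
            if is_acetate:
                p_add += cfg.acetate_added_mM
            if mu2 < 1e-12:
                return p_add + rate * b_add * (t - ta)
            return p_add + rate * (b_add / mu2) * (np.exp(mu2 * (t - ta)) - 1.0)

        return pre, post

    return od_pre, od_post, glc_pre, glc_post, product


def simulate_growth_experiment(cfg: SimulationConfig) -> GrowthExperiment:
    """Simulate a batch-culture experiment with ``cfg.n_replicates`` flasks.

    Per replicate, the growth rate is drawn from
    N(mu_true, (replicate_cv * mu_true)^2); OD and concentration series are
    the exact closed forms plus additive Gaussian noise, with concentrations
    floored at 0 mM.
    """
    rng = np.random.default_rng(cfg.seed)
    ta = cfg.acetate_add_time
    # refuse grids on which glucose is already exhausted before sampling starts
    if cfg.G0 - (cfg.B0_true / cfg.yield_true) * (
        math.exp(cfg.mu_true * cfg.t_grid[0]) - 1.0
    ) < 0:
        raise SyntheticDataError("t_grid implies negative glucose before the first sample")

    condition = cfg.condition or (
        f"{cfg.acetate_added_mM:g}mM_acetate" if cfg.acetate_added_mM else "control"
    )
    reps = []
    for r in range(cfg.n_replicates):
        mu1 = rng.normal(cfg.mu_true, cfg.replicate_cv * cfg.mu_true)
        if cfg.mu_after is not None:
            mu2 = rng.normal(cfg.mu_after, cfg.replicate_cv * cfg.mu_after)
        else:
            mu2 = mu1
        od_pre, od_post, glc_pre, glc_post, product = _replicate_closed_forms(
            cfg, mu1, mu2
        )
        t = cfg.t_grid
        od = _piecewise_series(t, od_pre, od_post, ta)
        if cfg.od_noise_sd > 0:
            od = od + rng.normal(0.0, cfg.od_noise_sd, t.size)
        glc = _piecewise_series(t, glc_pre, glc_post, ta)
        if cfg.conc_noise_sd > 0:
            glc = glc + rng.normal(0.0, cfg.conc_noise_sd, t.size)
        mets = {"glucose": np.maximum(glc, 0.0)}
        for name, rate in cfg.secretion_rates_true.items():
            pre, post = product(rate, is_acetate=(name == "acetate"))
            series = _piecewise_series(t, pre, post, ta)
            if cfg.conc_noise_sd > 0:
                series = series + rng.normal(0.0, cfg.conc_noise_sd, t.size)
            mets[name] = np.maximum(series, 0.0)
        curve = GrowthCurve(
            times=t.copy(),
            od=od,
            strain=cfg.strain,
            condition=condition,
            replicate=r,
            addition_time=ta,
        )
        reps.append(
            ReplicateData(
                curve=curve,
                metabolites=mets,
                mu_rep=float(mu1),
                mu_after_rep=float(mu2) if ta is not None else None,
            )
        )
    return GrowthExperiment(config=cfg, replicates=reps)


# ---------------------------------------------------------------------------
# Enzymatic assay plates
# ---------------------------------------------------------------------------


@dataclass
class PlateReads:
    """Repeated absorbance reads of one well, before (A1) and after (A2)
    the enzymatic reactions."""

    well: str
    phase1_times: np.ndarray
    phase1_abs: np.ndarray
    phase2_times: np.ndarray
    phase2_abs: np.ndarray
    addition_time: float
    standard_flag: bool = False
    standard_conc: float = math.nan
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("phase1_times", "phase1_abs", "phase2_times", "phase2_abs"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.phase1_times.size < 2 or self.phase2_times.size < 2:
            raise SyntheticDataError("need at least 2 reads per phase for the line fit")


def simulate_assay_plate(
    true_conc: float,
    drift_slopes: tuple[float, float] = (0.0, 0.0),
    read_times: Optional[tuple[Sequence[float], Sequence[float]]] = None,
    standard_conc: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    dilution_factor: float = 1.0,
    delta_standard: float = 0.6,
    baseline_abs: float = 0.5,
) -> dict[str, PlateReads]:
    """Simulate a metabolite well and a standard well of an assay plate.

    Both wells are read ten times (by default) before (A1) and after (A2)
    the enzymatic reactions; each phase drifts linearly in time with the
    given slope (absorbance/min) plus Gaussian noise.  The true absorbance
    difference at the enzyme-addition time is proportional to the assayed
    concentration: dA_well = delta_standard * C_well / standard_conc, with
    the metabolite well containing the sample diluted by
    ``dilution_factor``.
    """
    if standard_conc <= 0:
        raise SyntheticDataError("standard_conc must be positive")
    if dilution_factor < 1.0:
        raise SyntheticDataError("dilution_factor must be >= 1")
    if read_times is None:
        read_times = (np.arange(10.0), 15.0 + np.arange(10.0))
    t1 = np.asarray(read_times[0], dtype=float)
    t2 = np.asarray(read_times[1], dtype=float)
    if t1.size < 2 or t2.size < 2:
        raise SyntheticDataError("need at least 2 reads per phase for the line fit")
    t_add = 0.5 * (t1[-1] + t2[0])
    s1, s2 = drift_slopes
    rng = np.random.default_rng(seed)

    def well(conc_in_well: float, name: str, standard: bool) -> PlateReads:
        da = delta_standard * conc_in_well / standard_conc
        a1 = baseline_abs + s1 * t1
        a2 = (baseline_abs + s1 * t_add + da) + s2 * (t2 - t_add)
        if noise_sd > 0:
            a1 = a1 + rng.normal(0.0, noise_sd, t1.size)
            a2 = a2 + rng.normal(0.0, noise_sd, t2.size)
        return PlateReads(
            well=name,
            phase1_times=t1.copy(),
            phase1_abs=a1,
            phase2_times=t2.copy(),
            phase2_abs=a2,
            addition_time=t_add,
            standard_flag=standard,
            standard_conc=standard_conc if standard else math.nan,
            dilution_factor=dilution_factor,
        )

    return {
        "metabolite": well(true_conc / dilution_factor, "metabolite", False),
        "standard": well(standard_conc, "standard", True),
    }


# ---------------------------------------------------------------------------
# Toy metabolic networks
# ---------------------------------------------------------------------------


@dataclass
class ToyNetworkSpec:
    """Specification for a random toy network with a known feasible flux."""

    n_internal_metabolites: int = 5
    n_reactions: int = 9
    uptake_flux: float = 10.0
    secretion_fraction: float = 0.4
    seed: int = 0


def mini_central_carbon() -> tuple[MetabolicModel, np.ndarray]:
    """The embedded deterministic fixture: a 14-reaction central-carbon
    sketch (glucose uptake, glycolysis-like chain, pentose-phosphate and
    acetate branches, TCA-like oxidation, anaplerosis, biomass sink,
    maintenance, O2/CO2/acetate exchanges) with a hand-balanced reference
    flux.

    Returns (model, reference_flux); the reference flux satisfies
    N v = 0 exactly and all bounds.
    """
    mets = ["glc_c", "g6p", "p5p", "pyr", "accoa", "oaa", "ac_c", "co2_c", "o2_c"]
    formulas = {
        "glc_c": "C6H12O6",
        "g6p": "C6H13O9P",
        "p5p": "C5H11O8P",
        "pyr": "C3H3O3",
        "accoa": "C2H3O",
        "oaa": "C4H2O5",
        "ac_c": "C2H3O2",
        "co2_c": "CO2",
        "o2_c": "O2",
    }
    # reaction id -> (stoichiometry, lb, ub, subsystem)
    reactions = {
        "EX_glc": ({"glc_c": -1}, -10.0, 1000.0, "Exchange"),
        "EX_o2": ({"o2_c": -1}, -60.0, 1000.0, "Exchange"),
        "EX_co2": ({"co2_c": -1}, 0.0, 1000.0, "Exchange"),
        "EX_ac": ({"ac_c": -1}, -1000.0, 1000.0, "Exchange"),
        "GLK": ({"glc_c": -1, "g6p": 1}, 0.0, 1000.0, "Glycolysis/Gluconeogenesis"),
        "GLYC": ({"g6p": -1, "pyr": 2}, 0.0, 1000.0, "Glycolysis/Gluconeogenesis"),
        "PPP": ({"g6p": -1, "p5p": 1, "co2_c": 1}, 0.0, 1000.0,
                "Pentose Phosphate Pathway"),
        "PDH": ({"pyr": -1, "accoa": 1, "co2_c": 1}, 0.0, 1000.0,
                "Pyruvate Metabolism"),
        # finite capacities on the acetate branch: Pta-AckA at a generous
        # 20, Acs at 2 (catabolite-repressed on glucose); these also keep
        # the Pta/Acs futile cycle bounded so its sampled marginals stay
        # informative
        "PTA_ACK": ({"accoa": -1, "ac_c": 1}, 0.0, 20.0, "Pyruvate Metabolism"),
        "ACS": ({"ac_c": -1, "accoa": 1}, 0.0, 2.0, "Pyruvate Metabolism"),
        "TCA": ({"accoa": -1, "o2_c": -2, "co2_c": 2}, 0.0, 1000.0,
                "Citric Acid Cycle"),
        "ANA": ({"pyr": -1, "co2_c": -1, "oaa": 1}, 0.0, 1000.0,
                "Anaplerotic Reactions"),
        # biomass coefficients sized so the sink carries 30 mmol C per gDW
        # (close to the ~40 of real E. coli biomass) and the biomass flux is
        # on the scale of a growth rate in 1/h
        "BIOMASS": (
            {"g6p": -1.5, "pyr": -2.25, "accoa": -2.25, "p5p": -0.75, "oaa": -1.5},
            0.0, 1000.0, "Biomass",
        ),
        "NGAM": ({"g6p": -1, "o2_c": -6, "co2_c": 6}, 0.5, 0.5, "Maintenance"),
    }
    rids = list(reactions)
    S = np.zeros((len(mets), len(rids)))
    lb = np.zeros(len(rids))
    ub = np.zeros(len(rids))
    subsystem = []
    for j, rid in enumerate(rids):
        stoich, lo, hi, sub = reactions[rid]
        for mid, coef in stoich.items():
            S[mets.index(mid), j] = coef
        lb[j], ub[j] = lo, hi
        subsystem.append(sub)
    model = MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=rids,
        S=S,
        lb=lb,
        ub=ub,
        subsystem=subsystem,
        biomass_id="BIOMASS",
        maintenance_id="NGAM",
        medium={"EX_glc", "EX_o2"},
        formulas=formulas,
    )
    model.validate()
    # hand-balanced reference: glucose uptake 10, growth 0.625, acetate
    # secretion 4; all values dyadic so N v = 0 holds exactly in floats
    ref = {
        "EX_glc": -10.0, "EX_o2": -19.875, "EX_co2": 33.25, "EX_ac": 4.0,
        "GLK": 10.0, "GLYC": 8.09375, "PPP": 0.46875, "PDH": 13.84375,
        "PTA_ACK": 4.0, "ACS": 0.0, "TCA": 8.4375, "ANA": 0.9375,
        "BIOMASS": 0.625, "NGAM": 0.5,
    }
    reference_flux = np.array([ref[r] for r in rids])
    assert np.abs(S @ reference_flux).max() < 1e-12
    return model, reference_flux


def make_toy_network(
    spec: Optional[ToyNetworkSpec] = None,
) -> tuple[MetabolicModel, np.ndarray]:
    """Generate a mass-balanced toy network with a known feasible flux.

    Without a spec, returns the deterministic :func:`mini_central_carbon`
    fixture.  With a spec, builds a linear uptake -> conversion chain ->
    {secretion, biomass} backbone over ``n_internal_metabolites`` species
    plus randomly placed extra 1:1 conversion reactions (zero flux in the
    reference).  Requires ``n_reactions >= n_internal_metabolites + 2`` so
    that uptake, secretion and a biomass sink all fit.
    """
    if spec is None:
        return mini_central_carbon()
    m, r = spec.n_internal_metabolites, spec.n_reactions
    if m < 1:
        raise SyntheticDataError("need at least one internal metabolite")
    if r < m + 2:
        raise SyntheticDataError(
            "need n_reactions >= n_internal_metabolites + 2 "
            "(uptake + chain + secretion + biomass)"
        )
    rng = np.random.default_rng(spec.seed)
    mets = [f"M{i}" for i in range(m)]
    subsys_cycle = list(CENTRAL_CARBON_SUBSYSTEMS)
    rids, cols, lbs, ubs, subs, ref = [], [], [], [], [], []

    def add(rid, stoich, lo, hi, sub, flux):
        col = np.zeros(m)
        for mid, coef in stoich.items():
            col[mets.index(mid)] = coef
        rids.append(rid)
        cols.append(col)
        lbs.append(lo)
        ubs.append(hi)
        subs.append(sub)
        ref.append(flux)

    up = spec.uptake_flux
    sec = spec.secretion_fraction * up
    add("EX_up", {"M0": -1}, -1000.0, 1000.0, "Exchange", -up)
    for i in range(m - 1):
        add(f"R{i}", {f"M{i}": -1, f"M{i+1}": 1}, 0.0, 1000.0,
            subsys_cycle[i % len(subsys_cycle)], up)
    last = f"M{m-1}"
    add("EX_sec", {last: -1}, 0.0, 1000.0, "Exchange", sec)
    add("BIOMASS", {last: -1}, 0.0, 1000.0, "Biomass", up - sec)
    n_extra = r - len(rids)
    for k in range(n_extra):
        i, j = rng.choice(m, size=2, replace=False)
        add(f"X{k}", {f"M{i}": -1, f"M{j}": 1}, 0.0, 1000.0,
            subsys_cycle[(m + k) % len(subsys_cycle)], 0.0)
    S = np.column_stack(cols)
    model = MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=rids,
        S=S,
        lb=np.array(lbs),
        ub=np.array(ubs),
        subsystem=subs,
        biomass_id="BIOMASS",
        medium={"EX_up"},
        formulas={mid: "C3H4O3" for mid in mets},
    )
    model.validate()
    reference_flux = np.array(ref)
    if np.abs(S @ reference_flux).max() > 1e-12:
        raise SyntheticDataError("generated reference flux is not balanced")
    return model, reference_flux
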