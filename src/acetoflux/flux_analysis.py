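"""Constraint-based metabolic model, condition constraints, and the L1 MFA
and FBA linear programs.

The flux space is {v : N v = 0, lb <= v <= ub}.  Metabolic flux analysis
fits a steady-state flux vector to p measured exchange fluxes (and the
growth rate) by minimizing the total L1 deviation,

    min sum_j (u+_j + u-_j)
    s.t. N v = 0,  lb <= v <= ub,
         v_j - u+_j + u-_j = vhat_j   for measured j,
         u+, u- >= 0,

so that at the optimum u+_j + u-_j = |v_j - vhat_j|.  Flux balance analysis
maximizes a single flux (biomass) over the same polytope.  Both programs
are solved with the HiGHS solver behind scipy.optimize.linprog.

Sign convention for exchange fluxes: negative = uptake, positive =
secretion.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

__all__ = [
    "MetabolicModel",
    "FluxMeasurements",
    "MFAResult",
    "FBAResult",
    "ModelError",
    "ConstraintError",
    "CarbonBalanceError",
    "parse_carbon_count",
    "read_model",
    "write_model",
    "to_cobra",
    "from_cobra",
    "add_acetate_transport",
    "apply_condition_constraints",
    "carbon_balance_co2",
    "solve_mfa",
    "solve_fba",
]

# iAF1260 default non-growth-associated maintenance (mmol gDW^-1 h^-1); the
# growth-associated maintenance (59.81) is part of the biomass reaction.
DEFAULT_NGAM = 8.39


class ModelError(ValueError):
    """Raised for structurally invalid models."""


class ConstraintError(ValueError):
    """Raised when applied constraints are contradictory."""


class CarbonBalanceError(ValueError):
    """Raised when the measured rates violate the carbon mass balance."""


_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_carbon_count(formula: Optional[str]) -> int:
    """Number of carbon atoms in a chemical formula string ('C6H12O6' -> 6)."""
    if not formula:
        return 0
    total = 0
    for element, count in _ELEMENT_RE.findall(formula):
        if element == "C":
            total += int(count) if count else 1
    return total


@dataclass
class MetabolicModel:
    """Stoichiometric model: N (metabolites x reactions), bounds, labels."""

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    subsystem: list[str]
    biomass_id: Optional[str] = None
    maintenance_id: Optional[str] = None
    medium: set[str] = field(default_factory=set)
    formulas: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)

    # -- basic queries ---------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def rindex(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise ModelError(f"unknown reaction {reaction_id!r}") from None

    @property
    def exchange_mask(self) -> np.ndarray:
        """Reactions touching exactly one metabolite (boundary reactions),
        excluding the biomass sink."""
        mask = np.count_nonzero(self.S, axis=0) == 1
        if self.biomass_id is not None and self.biomass_id in self.reaction_ids:
            mask[self.rindex(self.biomass_id)] = False
        return mask

    @property
    def carbon_count(self) -> dict[str, int]:
        return {m: parse_carbon_count(self.formulas.get(m)) for m in self.metabolite_ids}

    def exchange_carbon(self, reaction_id: str) -> int:
        """Carbon atoms of the single metabolite moved by an exchange."""
        j = self.rindex(reaction_id)
        rows = np.flatnonzero(self.S[:, j])
        if rows.size != 1:
            raise ModelError(f"{reaction_id!r} is not a single-metabolite exchange")
        return parse_carbon_count(self.formulas.get(self.metabolite_ids[rows[0]]))

    def validate(self) -> None:
        m, n = self.S.shape
        if m != len(self.metabolite_ids) or n != len(self.reaction_ids):
            raise ModelError("stoichiometry matrix dimensions do not match id lists")
        if self.lb.shape != (n,) or self.ub.shape != (n,):
            raise ModelError("bound vectors must have one entry per reaction")
        if len(self.subsystem) != n:
            raise ModelError("need one subsystem label per reaction")
        if np.any(self.lb > self.ub):
            bad = [self.reaction_ids[i] for i in np.flatnonzero(self.lb > self.ub)]
            raise ModelError(f"lb > ub for reactions {bad}")
        if self.biomass_id is not None and self.biomass_id not in self.reaction_ids:
            raise ModelError(f"biomass reaction {self.biomass_id!r} missing")
        if len(set(self.reaction_ids)) != n or len(set(self.metabolite_ids)) != m:
            raise ModelError("duplicate reaction or metabolite ids")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            subsystem=list(self.subsystem),
            biomass_id=self.biomass_id,
            maintenance_id=self.maintenance_id,
            medium=set(self.medium),
            formulas=dict(self.formulas),
        )


@dataclass
class FluxMeasurements:
    """Measured exchange rates (model sign convention) and growth rate.

    ``entries`` maps exchange reaction id -> (mean, sem), both in
    mmol gDW^-1 h^-1 with uptake negative.  ``growth_rate`` is (mean, sem)
    in 1/h.  ``acetate_excess`` marks the condition with excess acetate in
    the medium, where the acetate exchange is left unconstrained.
    """

    entries: dict[str, tuple[float, float]]
    growth_rate: Optional[tuple[float, float]] = None
    acetate_excess: bool = False

    def __post_init__(self) -> None:
        for rid, (mean, sem) in self.entries.items():
            if sem < 0:
                raise ValueError(f"negative SEM for {rid}")


@dataclass
class MFAResult:
    """Solution of the L1 metabolic-flux-analysis LP."""

    status: str
    objective: float
    v: np.ndarray
    u_plus: np.ndarray
    u_minus: np.ndarray
    measured_ids: list[str]
    reaction_ids: list[str]

    def flux(self, reaction_id: str) -> float:
        return float(self.v[self.reaction_ids.index(reaction_id)])


@dataclass
class FBAResult:
    status: str
    optimum: float
    v: np.ndarray
    reaction_ids: list[str]

    def flux(self, reaction_id: str) -> float:
        return float(self.v[self.reaction_ids.index(reaction_id)])


# ---------------------------------------------------------------------------
# I/O: cobra/SBML bridge and a JSON tabular dialect
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (used for SBML I/O and cross-checks)."""
    import cobra

    cm = cobra.Model("acetoflux_model")
    mets = {}
    for mid in model.metabolite_ids:
        met = cobra.Metabolite(mid, formula=model.formulas.get(mid) or None,
                               compartment="c")
        mets[mid] = met
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lb[j])
        rxn.upper_bound = float(model.ub[j])
        rxn.subsystem = model.subsystem[j]
        reactions.append(rxn)
    cm.add_reactions(reactions)
    for j, rid in enumerate(model.reaction_ids):
        coefs = {
            mets[model.metabolite_ids[i]]: float(model.S[i, j])
            for i in np.flatnonzero(model.S[:, j])
        }
        cm.reactions.get_by_id(rid).add_metabolites(coefs)
    if model.biomass_id:
        cm.objective = model.biomass_id
    # persist subsystem annotation through SBML via the groups extension
    by_subsystem: dict[str, list] = {}
    for j, rid in enumerate(model.reaction_ids):
        if model.subsystem[j]:
            by_subsystem.setdefault(model.subsystem[j], []).append(
                cm.reactions.get_by_id(rid)
            )
    groups = []
    for k, (name, members) in enumerate(by_subsystem.items()):
        g = cobra.core.Group(f"g{k}", name=name, members=members, kind="partonomy")
        groups.append(g)
    if groups:
        cm.add_groups(groups)
    return cm


def from_cobra(cm, biomass_id: Optional[str] = None,
               maintenance_id: Optional[str] = None) -> MetabolicModel:
    """Build a :class:`MetabolicModel` from a cobrapy model."""
    from cobra.util.array import create_stoichiometric_matrix

    S = create_stoichiometric_matrix(cm)
    reaction_ids = [r.id for r in cm.reactions]
    metabolite_ids = [m.id for m in cm.metabolites]
    lb = np.array([r.lower_bound for r in cm.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cm.reactions], dtype=float)
    subsystem = [r.subsystem or "" for r in cm.reactions]
    if not any(subsystem):  # recover annotation from SBML groups
        by_rxn: dict[str, str] = {}
        for g in getattr(cm, "groups", []):
            for member in g.members:
                by_rxn.setdefault(member.id, g.name or g.id)
        subsystem = [by_rxn.get(r.id, "") for r in cm.reactions]
    if biomass_id is None:
        # objective reaction, else first id containing 'biomass'
        obj = [r.id for r in cm.reactions if r.objective_coefficient]
        if obj:
            biomass_id = obj[0]
        else:
            named = [r for r in reaction_ids if "biomass" in r.lower()]
            biomass_id = named[0] if named else None
    if maintenance_id is None:
        for cand in ("ATPM", "NGAM"):
            if cand in reaction_ids:
                maintenance_id = cand
                break
    formulas = {m.id: m.formula or "" for m in cm.metabolites}
    model = MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lb=lb,
        ub=ub,
        subsystem=subsystem,
        biomass_id=biomass_id,
        maintenance_id=maintenance_id,
        formulas=formulas,
    )
    # medium: boundary reactions with open uptake
    exch = model.exchange_mask
    model.medium = {
        reaction_ids[j] for j in np.flatnonzero(exch) if lb[j] < 0
    }
    model.validate()
    return model


def _model_to_dict(model: MetabolicModel) -> dict:
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        stoich = {
            model.metabolite_ids[i]: float(model.S[i, j])
            for i in np.flatnonzero(model.S[:, j])
        }
        reactions.append(
            {
                "id": rid,
                "lb": float(model.lb[j]),
                "ub": float(model.ub[j]),
                "subsystem": model.subsystem[j],
                "stoichiometry": stoich,
            }
        )
    return {
        "metabolites": [
            {"id": m, "formula": model.formulas.get(m, "")}
            for m in model.metabolite_ids
        ],
        "reactions": reactions,
        "biomass_id": model.biomass_id,
        "maintenance_id": model.maintenance_id,
        "medium": sorted(model.medium),
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    metabolite_ids = [m["id"] for m in data["metabolites"]]
    formulas = {m["id"]: m.get("formula", "") for m in data["metabolites"]}
    reaction_ids = [r["id"] for r in data["reactions"]]
    midx = {m: i for i, m in enumerate(metabolite_ids)}
    S = np.zeros((len(metabolite_ids), len(reaction_ids)))
    lb = np.zeros(len(reaction_ids))
    ub = np.zeros(len(reaction_ids))
    subsystem = []
    for j, r in enumerate(data["reactions"]):
        for mid, coef in r["stoichiometry"].items():
            if mid not in midx:
                raise ModelError(f"reaction {r['id']!r} uses unknown metabolite {mid!r}")
            S[midx[mid], j] = coef
        lb[j], ub[j] = r["lb"], r["ub"]
        subsystem.append(r.get("subsystem", ""))
    model = MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lb=lb,
        ub=ub,
        subsystem=subsystem,
        biomass_id=data.get("biomass_id"),
        maintenance_id=data.get("maintenance_id"),
        medium=set(data.get("medium", [])),
        formulas=formulas,
    )
    model.validate()
    return model


def _infer_dialect(path: Path) -> str:
    return "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "tabular"


def read_model(
    path: str | Path,
    dialect: Optional[str] = None,
    biomass_id: Optional[str] = None,
    add_actp: bool = False,
) -> MetabolicModel:
    """Read a model from SBML (L3 FBC, via cobrapy) or the JSON dialect.

    ``add_actp=True`` appends a transport reaction for acetate anions (the
    ActP symporter) between the external and cytosolic acetate species.
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "sbml":
        import cobra.io

        cm = cobra.io.read_sbml_model(str(path))
        model = from_cobra(cm, biomass_id=biomass_id)
    elif dialect in {"tabular", "json"}:
        with open(path) as fh:
            model = _model_from_dict(json.load(fh))
        if biomass_id is not None:
            model.biomass_id = biomass_id
            model.validate()
    else:
        raise ModelError(f"unknown model dialect {dialect!r}")
    if add_actp:
        model = add_acetate_transport(model)
    return model


def write_model(model: MetabolicModel, path: str | Path,
                dialect: Optional[str] = None) -> None:
    """Write a model as SBML L3 FBC (via cobrapy) or the JSON dialect."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(to_cobra(model), str(path))
    elif dialect in {"tabular", "json"}:
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=True)
    else:
        raise ModelError(f"unknown model dialect {dialect!r}")


def add_acetate_transport(
    model: MetabolicModel,
    external: str = "ac_e",
    internal: str = "ac_c",
    reaction_id: str = "ACt_actp",
) -> MetabolicModel:
    """Append an acetate-anion transport reaction (external -> internal)."""
    if external not in model.metabolite_ids or internal not in model.metabolite_ids:
        raise ModelError(
            f"acetate species {external!r}/{internal!r} not both present"
        )
    if reaction_id in model.reaction_ids:
        return model.copy()
    out = model.copy()
    col = np.zeros((out.n_metabolites, 1))
    col[out.metabolite_ids.index(external), 0] = -1.0
    col[out.metabolite_ids.index(internal), 0] = 1.0
    out.S = np.hstack([out.S, col])
    out.lb = np.append(out.lb, 0.0)
    out.ub = np.append(out.ub, 1000.0)
    out.reaction_ids.append(reaction_id)
    out.subsystem.append("Transport")
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Condition constraints and carbon balance
# ---------------------------------------------------------------------------

def apply_condition_constraints(
    model: MetabolicModel,
    meas: FluxMeasurements,
    o2_cap: float = 20.0,
    extra_constraints: Optional[Sequence[tuple[float, ...]]] = None,
    *,
    sem_multiplier: float = 2.0,
    hard_biomass: bool = False,
    biomass_band: bool = False,
    o2_exchange: str = "EX_o2",
    acetate_exchange: str = "EX_ac",
    open_exchanges: Iterable[str] = ("EX_co2", "EX_h2o", "EX_h"),
    ngam: Optional[float] = None,
) -> MetabolicModel:
    """Build the condition-specific bounds for MFA / FBA / sampling.

    The rules, in order: uptake lower bounds are zeroed except for medium
    components; the oxygen uptake magnitude is capped at ``o2_cap``
    (20 mmol gDW^-1 h^-1 by default); secretion upper bounds are zeroed
    except for measured products (and permanently open exchanges such as
    CO2 and water); measured exchanges are bounded to mean +/-
    ``sem_multiplier`` * SEM -- except the acetate exchange under excess
    acetate, which is left at its model defaults; the biomass reaction is
    clamped to the measured growth rate when ``hard_biomass`` (otherwise
    the growth rate enters :func:`solve_mfa` as a soft L1 term); the
    non-growth maintenance flux is fixed to ``ngam`` when given; and
    ``extra_constraints`` (an iterable of (reaction_id, lb, ub), e.g.
    literature bounds) are applied last.
    """
    if o2_cap <= 0:
        raise ConstraintError("o2_cap must be positive")
    out = model.copy()
    exch = out.exchange_mask
    measured = set(meas.entries)
    open_set = set(open_exchanges)
    skip_acetate = meas.acetate_excess and acetate_exchange in out.reaction_ids

    for j in np.flatnonzero(exch):
        rid = out.reaction_ids[j]
        if skip_acetate and rid == acetate_exchange:
            continue
        if rid not in out.medium:
            out.lb[j] = max(out.lb[j], 0.0)
        if rid == o2_exchange:
            out.lb[j] = max(out.lb[j], -o2_cap)
        if rid not in out.medium and rid not in open_set and rid not in measured:
            out.ub[j] = min(out.ub[j], 0.0)

    for rid, (mean, sem) in meas.entries.items():
        if skip_acetate and rid == acetate_exchange:
            continue
        j = out.rindex(rid)
        out.lb[j] = mean - sem_multiplier * sem
        out.ub[j] = mean + sem_multiplier * sem

    if meas.growth_rate is not None and out.biomass_id is not None:
        j = out.rindex(out.biomass_id)
        if hard_biomass:
            out.lb[j] = out.ub[j] = meas.growth_rate[0]
        elif biomass_band:
            # for flux-space sampling: the distributions are conditioned on
            # the measured growth rate like any other measured flux
            mu, sem = meas.growth_rate
            out.lb[j] = mu - sem_multiplier * sem
            out.ub[j] = mu + sem_multiplier * sem

    if ngam is not None:
        if out.maintenance_id is None:
            raise ConstraintError("model has no maintenance reaction to fix")
        j = out.rindex(out.maintenance_id)
        out.lb[j] = out.ub[j] = ngam

    for rid, lo, hi in extra_constraints or []:
        j = out.rindex(rid)
        out.lb[j], out.ub[j] = float(lo), float(hi)

    bad = np.flatnonzero(out.lb > out.ub + 1e-12)
    if bad.size:
        names = [out.reaction_ids[j] for j in bad]
        raise ConstraintError(f"contradictory bounds (lb > ub) for {names}")
    return out


def carbon_balance_co2(
    meas: FluxMeasurements,
    carbon_count: Mapping[str, int],
    biomass_carbon: float,
    tol: float = 1e-9,
) -> float:
    """Theoretical CO2 secretion flux from the carbon mass balance.

    ``carbon_count`` maps measured exchange reaction id -> carbon atoms of
    the exchanged species; ``biomass_carbon`` is the carbon content of
    biomass in mmol C per gDW, multiplied by the measured growth rate.
    Returns sum(uptake * C) - sum(secretion * C) - mu * biomass_carbon.
    """
    uptake_c = secretion_c = 0.0
    for rid, (mean, _sem) in meas.entries.items():
        if rid not in carbon_count:
            raise CarbonBalanceError(f"no carbon count for measured species {rid!r}")
        c = carbon_count[rid]
        if mean < 0:
            uptake_c += -mean * c
        else:
            secretion_c += mean * c
    mu = meas.growth_rate[0] if meas.growth_rate is not None else 0.0
    co2 = uptake_c - secretion_c - mu * biomass_carbon
    if co2 < -tol:
        raise CarbonBalanceError(
            f"carbon balance violated: CO2 flux {co2:.4g} < 0 "
            f"(uptake C {uptake_c:.4g}, secretion C {secretion_c:.4g}, "
            f"biomass C {mu * biomass_carbon:.4g})"
        )
    return max(co2, 0.0)


# ---------------------------------------------------------------------------
# Linear programs
# ---------------------------------------------------------------------------

_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_mfa(
    model: MetabolicModel,
    meas: FluxMeasurements,
    hard_biomass: bool = False,
    feas_tol: float = 1e-9,
) -> MFAResult:
    """Solve the L1 metabolic-flux-analysis LP.

    The growth rate, when measured and not hard-fixed, is included among
    the fitted measurements (a soft L1 term on the biomass reaction).
    """
    model.validate()
    n = model.n_reactions
    measured: list[tuple[str, float]] = [
        (rid, mean) for rid, (mean, _sem) in meas.entries.items()
    ]
    if meas.growth_rate is not None and model.biomass_id is not None and not hard_biomass:
        measured.append((model.biomass_id, meas.growth_rate[0]))
    p = len(measured)
    for rid, _ in measured:
        model.rindex(rid)  # raises for unknown ids

    c = np.concatenate([np.zeros(n), np.ones(2 * p)])
    S_eq = sparse.hstack(
        [sparse.csr_matrix(model.S), sparse.csr_matrix((model.n_metabolites, 2 * p))]
    )
    rows, cols, vals = [], [], []
    rhs = np.zeros(p)
    for k, (rid, vhat) in enumerate(measured):
        j = model.rindex(rid)
        rows += [k, k, k]
        cols += [j, n + k, n + p + k]
        vals += [1.0, -1.0, 1.0]
        rhs[k] = vhat
    M_eq = sparse.csr_matrix((vals, (rows, cols)), shape=(p, n + 2 * p))
    A_eq = sparse.vstack([S_eq, M_eq], format="csr")
    b_eq = np.concatenate([np.zeros(model.n_metabolites), rhs])
    bounds = [(model.lb[j], model.ub[j]) for j in range(n)] + [(0, None)] * (2 * p)
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return MFAResult(
            status=status,
            objective=math.nan,
            v=np.full(n, np.nan),
            u_plus=np.full(p, np.nan),
            u_minus=np.full(p, np.nan),
            measured_ids=[rid for rid, _ in measured],
            reaction_ids=list(model.reaction_ids),
        )
    v = res.x[:n]
    balance = np.abs(model.S @ v).max() if n else 0.0
    if balance > 1e-6:  # pragma: no cover - solver contract
        raise ConstraintError(f"MFA solution violates mass balance ({balance:.2e})")
    return MFAResult(
        status=status,
        objective=float(res.fun),
        v=v,
        u_plus=res.x[n:n + p],
        u_minus=res.x[n + p:],
        measured_ids=[rid for rid, _ in measured],
        reaction_ids=list(model.reaction_ids),
    )


def solve_fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    direction: str = "max",
) -> FBAResult:
    """Flux balance analysis: optimize one flux over the steady-state polytope."""
    model.validate()
    objective = objective or model.biomass_id
    if objective is None:
        raise ModelError("no objective reaction given and no biomass reaction set")
    j = model.rindex(objective)
    n = model.n_reactions
    c = np.zeros(n)
    c[j] = -1.0 if direction == "max" else 1.0
    res = linprog(
        c,
        A_eq=sparse.csr_matrix(model.S),
        b_eq=np.zeros(model.n_metabolites),
        bounds=list(zip(model.lb, model.ub)),
        method="highs",
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FBAResult(status=status, optimum=math.nan,
                         v=np.full(n, np.nan), reaction_ids=list(model.reaction_ids))
    return FBAResult(
        status=status,
        optimum=float(res.x[j]),
        v=res.x,
        reaction_ids=list(model.reaction_ids),
    )
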