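"""The L1-MFA LP against brute-force and independent-formulation oracles,
FBA against hand-enumerated optima and cobrapy, constraint building, and
the carbon balance."""

import numpy as np
import pytest
from scipy.optimize import linprog

from acetoflux.flux_analysis import (
    CarbonBalanceError,
    ConstraintError,
    FluxMeasurements,
    MetabolicModel,
    ModelError,
    add_acetate_transport,
    apply_condition_constraints,
    carbon_balance_co2,
    parse_carbon_count,
    solve_fba,
    solve_mfa,
    to_cobra,
)
from acetoflux.synthetic_data import ToyNetworkSpec, make_toy_network


def chain_model():
    """S_ext -> S -> P -> P_ext: uptake, conversion, secretion."""
    return MetabolicModel(
        metabolite_ids=["S", "P"],
        reaction_ids=["EX_S", "CONV", "EX_P"],
        S=np.array([[-1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]),
        lb=np.array([-100.0, 0.0, 0.0]),
        ub=np.array([100.0, 100.0, 100.0]),
        subsystem=["Exchange", "Core", "Exchange"],
        medium={"EX_S"},
    )


class TestCarbonParsing:
    @pytest.mark.parametrize(
        "formula,count",
        [("C6H12O6", 6), ("CO2", 1), ("C", 1), ("H2O", 0), ("CaCl2", 0),
         ("C10H12N5O13P3", 10), (None, 0), ("", 0)],
    )
    def test_formula_carbon_counts(self, formula, count):
        assert parse_carbon_count(formula) == count


class TestModelValidation:
    def test_lb_above_ub_rejected(self, fixture_model):
        model, _ = fixture_model
        bad = model.copy()
        bad.lb[0] = bad.ub[0] + 1.0
        with pytest.raises(ModelError):
            bad.validate()

    def test_unknown_metabolite_rejected(self):
        from acetoflux.flux_analysis import _model_from_dict

        data = {
            "metabolites": [{"id": "A"}],
            "reactions": [
                {"id": "r1", "lb": 0, "ub": 1, "stoichiometry": {"B": 1.0}}
            ],
        }
        with pytest.raises(ModelError):
            _model_from_dict(data)

    def test_acetate_transport_reaction_added(self):
        model = MetabolicModel(
            metabolite_ids=["ac_e", "ac_c"],
            reaction_ids=["EX_ac", "SINK"],
            S=np.array([[-1.0, 0.0], [0.0, -1.0]]),
            lb=np.array([-10.0, 0.0]),
            ub=np.array([10.0, 10.0]),
            subsystem=["Exchange", "Demand"],
        )
        out = add_acetate_transport(model)
        j = out.rindex("ACt_actp")
        assert out.S[out.metabolite_ids.index("ac_e"), j] == -1.0
        assert out.S[out.metabolite_ids.index("ac_c"), j] == 1.0


class TestConditionConstraints:
    def test_zero_sem_collapses_exchange_to_point(self, fixture_model):
        model, _ = fixture_model
        meas = FluxMeasurements(entries={"EX_glc": (-9.0, 0.0)})
        out = apply_condition_constraints(model, meas)
        j = out.rindex("EX_glc")
        assert out.lb[j] == out.ub[j] == -9.0

    def test_acetate_excess_leaves_acetate_exchange_untouched(self, fixture_model):
        model, _ = fixture_model
        meas = FluxMeasurements(
            entries={"EX_glc": (-9.0, 0.1), "EX_ac": (3.0, 0.1)},
            acetate_excess=True,
        )
        out = apply_condition_constraints(model, meas)
        j = out.rindex("EX_ac")
        assert out.lb[j] == model.lb[j] and out.ub[j] == model.ub[j]

    def test_o2_cap_and_unmeasured_secretion_closed(self, fixture_model):
        model, _ = fixture_model
        meas = FluxMeasurements(entries={"EX_glc": (-9.0, 0.1)})
        out = apply_condition_constraints(model, meas, o2_cap=20.0)
        assert out.lb[out.rindex("EX_o2")] == -20.0
        # acetate not measured, not medium -> secretion closed, uptake closed
        j = out.rindex("EX_ac")
        assert out.lb[j] == 0.0 and out.ub[j] == 0.0
        # CO2 stays open for secretion
        assert out.ub[out.rindex("EX_co2")] > 0

    def test_consistent_measurements_remain_feasible(self, fixture_model):
        """LP feasibility oracle: reference-flux measurements leave a
        nonempty polytope."""
        model, ref = fixture_model
        rid = dict(zip(model.reaction_ids, ref))
        meas = FluxMeasurements(
            entries={r: (rid[r], 0.05) for r in ("EX_glc", "EX_ac", "EX_co2")},
            growth_rate=(rid["BIOMASS"], 0.01),
        )
        out = apply_condition_constraints(model, meas, ngam=0.5)
        res = linprog(
            np.zeros(out.n_reactions),
            A_eq=out.S, b_eq=np.zeros(out.n_metabolites),
            bounds=list(zip(out.lb, out.ub)), method="highs",
        )
        assert res.status == 0

    def test_contradictory_extra_constraints_rejected(self, fixture_model):
        model, _ = fixture_model
        meas = FluxMeasurements(entries={})
        with pytest.raises(ConstraintError):
            apply_condition_constraints(
                model, meas, extra_constraints=[("GLK", 5.0, 1.0)]
            )


class TestCarbonBalance:
    def test_hand_bookkeeping_example(self):
        """Glucose uptake 10 (C6), acetate secretion 4 (C2), biomass drain
        40 mmolC -> CO2 = 60 - 8 - 40 = 12."""
        meas = FluxMeasurements(
            entries={"EX_glc": (-10.0, 0.0), "EX_ac": (4.0, 0.0)},
            growth_rate=(1.0, 0.0),
        )
        co2 = carbon_balance_co2(meas, {"EX_glc": 6, "EX_ac": 2}, biomass_carbon=40.0)
        assert co2 == pytest.approx(12.0)

    def test_empty_balance_is_zero(self):
        meas = FluxMeasurements(entries={}, growth_rate=(0.0, 0.0))
        assert carbon_balance_co2(meas, {}, biomass_carbon=40.0) == 0.0

    def test_linearity_in_rates(self):
        def co2(scale):
            meas = FluxMeasurements(
                entries={"EX_glc": (-10.0 * scale, 0.0), "EX_ac": (4.0 * scale, 0.0)},
                growth_rate=(1.0 * scale, 0.0),
            )
            return carbon_balance_co2(meas, {"EX_glc": 6, "EX_ac": 2}, 40.0)

        assert co2(2.0) == pytest.approx(2.0 * co2(1.0))

    def test_violated_balance_rejected(self):
        meas = FluxMeasurements(
            entries={"EX_glc": (-1.0, 0.0), "EX_ac": (10.0, 0.0)},
            growth_rate=(0.0, 0.0),
        )
        with pytest.raises(CarbonBalanceError):
            carbon_balance_co2(meas, {"EX_glc": 6, "EX_ac": 2}, 40.0)


def _mfa_oracle_bound_splitting(model, meas):
    """Independent LP formulation: min sum t_j with t_j >= +-(v_j - vhat_j)."""
    n = model.n_reactions
    entries = list(meas.entries.items())
    p = len(entries)
    c = np.concatenate([np.zeros(n), np.ones(p)])
    A_ub, b_ub = [], []
    for k, (rid, (vhat, _)) in enumerate(entries):
        j = model.rindex(rid)
        row = np.zeros(n + p)
        row[j], row[n + k] = 1.0, -1.0
        A_ub.append(row.copy())
        b_ub.append(vhat)
        row = np.zeros(n + p)
        row[j], row[n + k] = -1.0, -1.0
        A_ub.append(row)
        b_ub.append(-vhat)
    A_eq = np.hstack([model.S, np.zeros((model.n_metabolites, p))])
    bounds = list(zip(model.lb, model.ub)) + [(0, None)] * p
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub), A_eq=A_eq,
                  b_eq=np.zeros(model.n_metabolites), bounds=bounds, method="highs")
    assert res.status == 0
    return res.fun


class TestMFA:
    def test_chain_with_inconsistent_measurements(self):
        """Uptake 10, secretion 8: the best steady state leaves a total
        L1 gap of 2, confirmed by a grid scan over the chain flux."""
        model = chain_model()
        meas = FluxMeasurements(entries={"EX_S": (-10.0, 0.0), "EX_P": (8.0, 0.0)})
        res = solve_mfa(model, meas)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(2.0, abs=1e-9)
        # grid-scan oracle over the single degree of freedom
        grid = np.linspace(0.0, 20.0, 4001)
        best = min(abs(-v + 10.0) + abs(v - 8.0) for v in grid)
        assert res.objective == pytest.approx(best, abs=1e-9)

    def test_consistent_measurements_give_zero_objective(self, fixture_model):
        model, ref = fixture_model
        rid = dict(zip(model.reaction_ids, ref))
        meas = FluxMeasurements(
            entries={r: (rid[r], 0.0) for r in ("EX_glc", "EX_ac", "EX_co2", "EX_o2")},
            growth_rate=(rid["BIOMASS"], 0.0),
        )
        res = solve_mfa(model, meas)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(0.0, abs=1e-8)
        for r in meas.entries:
            assert res.flux(r) == pytest.approx(rid[r], abs=1e-8)
        assert res.flux("BIOMASS") == pytest.approx(rid["BIOMASS"], abs=1e-8)

    def test_slack_identity_and_mass_balance(self, fixture_model):
        model, ref = fixture_model
        meas = FluxMeasurements(
            entries={"EX_glc": (-9.0, 0.0), "EX_ac": (6.0, 0.0)},
            growth_rate=(0.7, 0.0),
        )
        res = solve_mfa(model, meas)
        assert res.status == "optimal"
        for k, rid in enumerate(res.measured_ids):
            vhat = dict(meas.entries).get(rid, (meas.growth_rate[0],))[0]
            gap = abs(res.flux(rid) - vhat)
            assert res.u_plus[k] + res.u_minus[k] == pytest.approx(gap, abs=1e-8)
            assert min(res.u_plus[k], res.u_minus[k]) == pytest.approx(0.0, abs=1e-8)
        assert np.abs(model.S @ res.v).max() < 1e-8
        assert np.all(res.v >= model.lb - 1e-9) and np.all(res.v <= model.ub + 1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_formulation_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        model, ref = make_toy_network(
            ToyNetworkSpec(n_internal_metabolites=4, n_reactions=9, seed=seed)
        )
        rid = dict(zip(model.reaction_ids, ref))
        noisy = {
            r: (rid[r] + rng.normal(0, 2.0), 0.0)
            for r in ("EX_up", "EX_sec", "BIOMASS")
        }
        meas = FluxMeasurements(entries=noisy)
        res = solve_mfa(model, meas)
        assert res.status == "optimal"
        oracle = _mfa_oracle_bound_splitting(model, meas)
        assert res.objective == pytest.approx(oracle, abs=1e-7)

    def test_zero_objective_iff_consistent(self):
        """Both directions on the chain: consistent measurements give 0;
        any positive objective implies the measurements are jointly
        infeasible (checked by solving the feasibility LP directly)."""
        model = chain_model()
        consistent = FluxMeasurements(entries={"EX_S": (-7.0, 0.0), "EX_P": (7.0, 0.0)})
        assert solve_mfa(model, consistent).objective == pytest.approx(0.0, abs=1e-10)
        inconsistent = FluxMeasurements(entries={"EX_S": (-7.0, 0.0), "EX_P": (5.0, 0.0)})
        res = solve_mfa(model, inconsistent)
        assert res.objective > 1e-6
        fix = model.copy()
        for r, (vhat, _) in inconsistent.entries.items():
            fix.lb[fix.rindex(r)] = fix.ub[fix.rindex(r)] = vhat
        lp = linprog(np.zeros(3), A_eq=fix.S, b_eq=np.zeros(2),
                     bounds=list(zip(fix.lb, fix.ub)), method="highs")
        assert lp.status == 2  # infeasible

    def test_infeasible_model_reported(self):
        model = chain_model()
        model.lb[1], model.ub[1] = 5.0, 6.0
        model.lb[2], model.ub[2] = 0.0, 1.0  # conversion 5 but secretion <= 1
        res = solve_mfa(model, FluxMeasurements(entries={"EX_S": (-5.0, 0.0)}))
        assert res.status == "infeasible"


class TestFBA:
    def test_hand_enumerated_optima(self, fixture_model):
        """With glucose uptake <= 10 and fixed maintenance 0.5 the biomass
        optimum is 9.5/5.25 when acetate is unavailable (all carbon routed
        to precursors).  With acetate uptake open, Acs (capacity 2)
        substitutes part of the acetyl-CoA demand: the glucose balance
        becomes (3v - 1) + 0.75v + 1.5v = 9.5, i.e. v = 2 exactly."""
        model, _ = fixture_model
        closed = model.copy()
        closed.lb[closed.rindex("EX_ac")] = 0.0
        assert solve_fba(closed).optimum == pytest.approx(9.5 / 5.25, abs=1e-6)
        assert solve_fba(model).optimum == pytest.approx(2.0, abs=1e-6)

    def test_matches_cobrapy_on_fixture(self, fixture_model):
        model, _ = fixture_model
        cm = to_cobra(model)
        expected = cm.optimize().objective_value
        assert solve_fba(model).optimum == pytest.approx(expected, abs=1e-6)

    def test_all_exchanges_closed_gives_zero(self, fixture_model):
        model, _ = fixture_model
        closed = model.copy()
        for j in np.flatnonzero(closed.exchange_mask):
            closed.lb[j] = closed.ub[j] = 0.0
        closed.lb[closed.rindex("NGAM")] = closed.ub[closed.rindex("NGAM")] = 0.0
        assert solve_fba(closed).optimum == pytest.approx(0.0, abs=1e-9)

    def test_optimum_monotone_in_bound_relaxation(self, fixture_model):
        model, _ = fixture_model
        base = solve_fba(model).optimum
        relaxed = model.copy()
        relaxed.lb[relaxed.rindex("EX_glc")] = -12.0
        assert solve_fba(relaxed).optimum >= base - 1e-9

    def test_mass_balance_and_bounds_of_solution(self, fixture_model):
        model, _ = fixture_model
        res = solve_fba(model)
        assert np.abs(model.S @ res.v).max() < 1e-8
        assert np.all(res.v >= model.lb - 1e-9) and np.all(res.v <= model.ub + 1e-9)
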