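"""End-to-end orchestration: simulate or ingest -> growth and rate fits ->
inhibition statistics -> metabolic flux analysis -> flux-space sampling ->
cross-condition comparison.

One YAML configuration drives the whole run.  Every stage writes its
outputs to the run directory, and downstream stages read those files back,
so any stage can be re-run from disk without recomputation.  All stochastic
stages derive their seeds from the single top-level seed, making the run a
pure function of (config, seed, input files).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as afio
from .flux_analysis import (
    FluxMeasurements,
    MetabolicModel,
    apply_condition_constraints,
    carbon_balance_co2,
    read_model,
    solve_fba,
    solve_mfa,
)
from .growth_kinetics import (
    GrowthFit,
    fit_exponential_growth,
    fit_uptake_secretion,
    mean_2sem,
    to_specific_rate,
)
from .inhibition_stats import (
    ReplicateSet,
    bootstrap_index_test,
    fit_dose_response,
    inhibition_index,
    welch_test,
)
from .flux_sampling import build_polytope, compare_conditions, sample_flux_space
from .synthetic_data import (
    CENTRAL_CARBON_SUBSYSTEMS,
    SimulationConfig,
    mini_central_carbon,
    simulate_growth_experiment,
)

log = logging.getLogger("acetoflux.pipeline")

__all__ = ["PipelineConfig", "ConditionSpec", "PipelineError", "run_pipeline",
           "load_config", "template_config", "ALL_STAGES"]

ALL_STAGES = ("simulate", "fit", "rates", "stats", "dose", "mfa", "sample")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and condition."""


@dataclass
class ConditionSpec:
    strain: str
    acetate_mM: float = 0.0
    ph: float = 7.4
    simulate: dict[str, Any] = field(default_factory=dict)
    data: Optional[str] = None  # path to an existing tidy time-series table

    @property
    def label(self) -> str:
        return f"{self.strain}_ac{self.acetate_mM:g}"


@dataclass
class PipelineConfig:
    seed: int = 1
    output_dir: str = "results/pipeline"
    od_ceiling: float = 1.0
    od_to_gdw: float = 0.47
    n_boot: int = 10_000
    o2_cap: float = 20.0
    ngam: Optional[float] = 0.5
    sampler: dict[str, int] = field(
        default_factory=lambda: {"n_draws": 2000, "burn_in": 500, "thinning": 5}
    )
    model: dict[str, Any] = field(default_factory=lambda: {"builtin": "mini_central_carbon"})
    exchange_map: dict[str, str] = field(
        default_factory=lambda: {"glucose": "EX_glc", "acetate": "EX_ac"}
    )
    o2_exchange: str = "EX_o2"
    co2_exchange: str = "EX_co2"
    conditions: list[ConditionSpec] = field(default_factory=list)
    dose_response: Optional[dict[str, Any]] = None

    def validate(self) -> None:
        if not self.conditions:
            raise PipelineError("configuration lists no conditions")
        if self.seed is None:
            raise PipelineError("a seed is required for stochastic stages")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise PipelineError(f"duplicate condition labels: {labels}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    conditions = [ConditionSpec(**c) for c in raw.pop("conditions", [])]
    cfg = PipelineConfig(**raw, conditions=conditions)
    cfg.validate()
    return cfg


def template_config() -> str:
    """A fully-populated YAML template listing every default."""
    cfg = PipelineConfig(
        conditions=[
            ConditionSpec(
                strain="wt", acetate_mM=0.0,
                simulate={"mu_true": 0.625, "yield_true": 0.133,
                          "secretion_rates_true": {"acetate": 1.88},
                          "acetate_add_time": 1.5, "acetate_added_mM": 0.0},
            ),
            ConditionSpec(
                strain="wt", acetate_mM=128.0,
                simulate={"mu_true": 0.625, "yield_true": 0.133,
                          "secretion_rates_true": {"acetate": 1.88},
                          "acetate_add_time": 1.5, "acetate_added_mM": 128.0,
                          "mu_after": 0.34},
            ),
        ],
        dose_response={
            "baseline": 0.3, "amplitude": 0.45, "decay_k": 0.011757,
            "concentrations": [0, 2, 8, 16, 32, 64, 128],
        },
    )
    d = dataclasses.asdict(cfg)
    return yaml.safe_dump(d, sort_keys=False)


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _condition_seed(cfg: PipelineConfig, idx: int, stage: int = 0) -> int:
    return int(
        np.random.default_rng([cfg.seed, stage, idx]).integers(0, 2**31 - 1)
    )


def _load_model(cfg: PipelineConfig) -> Optional[MetabolicModel]:
    spec = cfg.model or {}
    if not spec:
        return None
    if spec.get("builtin") == "mini_central_carbon":
        return mini_central_carbon()[0]
    if "path" in spec:
        return read_model(spec["path"], dialect=spec.get("dialect"),
                          add_actp=bool(spec.get("add_actp", False)))
    return None


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    for i, cond in enumerate(cfg.conditions):
        if cond.data:
            df = afio.read_timeseries(cond.data)
        else:
            sim = SimulationConfig(
                **cond.simulate,
                seed=_condition_seed(cfg, i),
                strain=cond.strain,
                condition=cond.label,
            )
            df = simulate_growth_experiment(sim).to_tidy()
        afio.write_timeseries(df, outdir / f"timeseries_{cond.label}.csv")
        log.info("simulate: %s -> %d rows", cond.label, len(df))


def _addition_time(cond: ConditionSpec) -> Optional[float]:
    return cond.simulate.get("acetate_add_time")


def _stage_fit(cfg: PipelineConfig, outdir: Path) -> None:
    rows = []
    for cond in cfg.conditions:
        df = afio.read_timeseries(outdir / f"timeseries_{cond.label}.csv")
        for (strain, condition, rep), sub in afio.iter_replicates(df):
            curve = afio.curve_from_tidy(sub, addition_time=_addition_time(cond))
            fit = fit_exponential_growth(curve, od_ceiling=cfg.od_ceiling)
            rows.append(
                dict(strain=strain, condition=condition, replicate=rep,
                     mu=fit.mu, B0=fit.B0, mu_se=fit.mu_se, sse=fit.sse,
                     n_points=fit.n_points, window_start=fit.fit_window[0],
                     window_end=fit.fit_window[1], log_r_squared=fit.log_r_squared,
                     exponential_ok=fit.exponential_ok)
            )
    pd.DataFrame(rows).to_csv(outdir / "growth_fits.csv", index=False)
    log.info("fit: %d growth fits", len(rows))


def _stage_rates(cfg: PipelineConfig, outdir: Path) -> None:
    fits = pd.read_csv(outdir / "growth_fits.csv")
    rows = []
    for cond in cfg.conditions:
        df = afio.read_timeseries(outdir / f"timeseries_{cond.label}.csv")
        metabolites = sorted(set(df["variable"]) - {"od600"})
        for (strain, condition, rep), sub in afio.iter_replicates(df):
            curve = afio.curve_from_tidy(sub, addition_time=_addition_time(cond))
            frow = fits[
                (fits.strain == strain) & (fits.condition == condition)
                & (fits.replicate == rep)
            ].iloc[0]
            gfit = GrowthFit(mu=frow.mu, B0=frow.B0,
                             fit_window=(frow.window_start, frow.window_end),
                             sse=frow.sse, n_points=int(frow.n_points))
            for met in metabolites:
                t, c = afio.metabolite_series(sub, met)
                if _addition_time(cond) is not None:
                    keep = t >= _addition_time(cond)
                    t, c = t[keep], c[keep]
                mode = "uptake" if met == "glucose" else "secretion"
                try:
                    rf = fit_uptake_secretion(
                        (t, c), curve if mode == "uptake" else gfit,
                        mode=mode, metabolite=met, od_ceiling=cfg.od_ceiling,
                    )
                except Exception as exc:
                    log.warning("rates: %s/%s rep %s %s failed: %s",
                                strain, condition, rep, met, exc)
                    continue
                rows.append(
                    dict(strain=strain, condition=condition, replicate=rep,
                         metabolite=met, mode=mode, rate=rf.rate,
                         rate_se=rf.rate_se, C0=rf.C0, yield_Y=rf.yield_Y,
                         mu_used=rf.mu_used, B0_used=rf.B0_used)
                )
    pd.DataFrame(rows).to_csv(outdir / "rate_fits.csv", index=False)
    log.info("rates: %d rate fits", len(rows))


def _growth_rates(outdir: Path, label: str) -> np.ndarray:
    fits = pd.read_csv(outdir / "growth_fits.csv")
    sel = fits[fits.condition == label].sort_values("replicate")
    return sel["mu"].to_numpy(dtype=float)


def _stage_stats(cfg: PipelineConfig, outdir: Path, report: dict) -> None:
    strains: dict[str, dict[str, ConditionSpec]] = {}
    for cond in cfg.conditions:
        slot = "acetate" if cond.acetate_mM > 0 else "control"
        strains.setdefault(cond.strain, {})[slot] = cond
    summary: dict[str, Any] = {}
    pairs = {}
    for strain, slots in strains.items():
        if "control" not in slots or "acetate" not in slots:
            continue
        mu_c = _growth_rates(outdir, slots["control"].label)
        mu_a = _growth_rates(outdir, slots["acetate"].label)
        pairs[strain] = (mu_c, mu_a)
        mc, semc2 = mean_2sem(mu_c)
        ma, sema2 = mean_2sem(mu_a)
        summary[strain] = {
            "mu_control": {"mean": mc, "two_sem": semc2, "n": int(mu_c.size)},
            "mu_acetate": {"mean": ma, "two_sem": sema2, "n": int(mu_a.size)},
            "inhibition_index": inhibition_index(mc, ma),
        }
    ref = cfg.conditions[0].strain
    for k, strain in enumerate(pairs):
        if strain == ref or ref not in pairs:
            continue
        test, res_ref, res_s = bootstrap_index_test(
            ReplicateSet(f"{ref}_control", pairs[ref][0]),
            ReplicateSet(f"{ref}_acetate", pairs[ref][1]),
            ReplicateSet(f"{strain}_control", pairs[strain][0]),
            ReplicateSet(f"{strain}_acetate", pairs[strain][1]),
            n_boot=cfg.n_boot,
            seed=_condition_seed(cfg, k, stage=4),
        )
        w = welch_test(
            ReplicateSet(f"{ref}_control", pairs[ref][0]),
            ReplicateSet(f"{strain}_control", pairs[strain][0]),
        )
        summary[strain]["vs_" + ref] = {
            "bootstrap_p": test.p_value,
            "bootstrap_seed": test.seed,
            "n_boot": test.n_boot,
            "index_ref_ci": [res_ref.ci_low, res_ref.ci_high],
            "index_ci": [res_s.ci_low, res_s.ci_high],
            "welch_control_p": w.p_value,
            "welch_control_df": w.df,
        }
    report["inhibition"] = summary
    with open(outdir / "inhibition_stats.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log.info("stats: %d strains", len(summary))


def _stage_dose(cfg: PipelineConfig, outdir: Path, report: dict) -> None:
    spec = cfg.dose_response
    if not spec:
        return
    b, a, k = spec["baseline"], spec["amplitude"], spec["decay_k"]
    concs = np.asarray(spec["concentrations"], dtype=float)
    base = dict(spec.get("simulate", {}))
    mus = []
    for i, c in enumerate(concs):
        mu_c = b + a * float(np.exp(-k * c))
        sim = SimulationConfig(
            **base, mu_true=mu_c, seed=_condition_seed(cfg, i, stage=5),
            strain="wt", condition=f"dose_{c:g}", n_replicates=spec.get("n_replicates", 3),
        )
        exp = simulate_growth_experiment(sim)
        reps = [fit_exponential_growth(r.curve, od_ceiling=cfg.od_ceiling).mu
                for r in exp.replicates]
        mus.append(mean_2sem(reps)[0])
    fit = fit_dose_response(concs, mus)
    report["dose_response"] = {
        "baseline_b": fit.baseline_b, "amplitude": fit.amplitude,
        "decay_k": fit.decay_k, "rss": fit.rss,
        "concentrations": concs.tolist(), "mu": list(mus),
    }
    with open(outdir / "dose_response.json", "w") as fh:
        json.dump(report["dose_response"], fh, indent=1, sort_keys=True)
    log.info("dose: baseline %.3f amplitude %.3f k %.4f",
             fit.baseline_b, fit.amplitude, fit.decay_k)


def _condition_measurements(
    cfg: PipelineConfig, model: MetabolicModel, cond: ConditionSpec, outdir: Path
) -> FluxMeasurements:
    rates = pd.read_csv(outdir / "rate_fits.csv")
    sel = rates[rates.condition == cond.label]
    entries: dict[str, tuple[float, float]] = {}
    for met, rid in cfg.exchange_map.items():
        sub = sel[sel.metabolite == met]
        if sub.empty or rid not in model.reaction_ids:
            continue
        specific = np.array(
            [to_specific_rate(r, cfg.od_to_gdw) for r in sub["rate"]]
        )
        mean, two_sem = mean_2sem(specific)
        sem = two_sem / 2.0 if np.isfinite(two_sem) else 0.0
        sign = -1.0 if (sub["mode"] == "uptake").all() else 1.0
        entries[rid] = (sign * mean, sem)
    glc = sel[sel.metabolite == "glucose"]
    mu_mean, mu_2sem = mean_2sem(glc["mu_used"]) if not glc.empty else (
        mean_2sem(_growth_rates(outdir, cond.label))
    )
    meas = FluxMeasurements(
        entries=entries,
        growth_rate=(mu_mean, (mu_2sem / 2.0) if np.isfinite(mu_2sem) else 0.0),
        acetate_excess=cond.acetate_mM > 0,
    )
    if not meas.acetate_excess and cfg.co2_exchange in model.reaction_ids:
        carbon = {rid: model.exchange_carbon(rid) for rid in entries}
        bc = _biomass_carbon(model)
        sem_co2 = sum(abs(carbon[r]) * s for r, (m, s) in entries.items())
        sem_co2 += meas.growth_rate[1] * bc
        co2 = carbon_balance_co2(meas, carbon, bc)
        meas.entries[cfg.co2_exchange] = (co2, sem_co2)
    return meas


def _biomass_carbon(model: MetabolicModel) -> float:
    """Carbon drained by one unit of biomass flux (mmol C per gDW)."""
    j = model.rindex(model.biomass_id)
    counts = model.carbon_count
    return float(
        sum(-model.S[i, j] * counts[model.metabolite_ids[i]]
            for i in np.flatnonzero(model.S[:, j] < 0))
    )


def _stage_mfa(cfg: PipelineConfig, outdir: Path, report: dict) -> None:
    model = _load_model(cfg)
    if model is None:
        log.info("mfa: no model configured, skipping")
        return
    results = {}
    flux_rows = []
    for cond in cfg.conditions:
        meas = _condition_measurements(cfg, model, cond, outdir)
        constrained = apply_condition_constraints(
            model, meas, o2_cap=cfg.o2_cap, ngam=cfg.ngam,
            o2_exchange=cfg.o2_exchange,
            acetate_exchange=cfg.exchange_map.get("acetate", "EX_ac"),
            open_exchanges=(cfg.co2_exchange,),
        )
        mfa = solve_mfa(constrained, meas)
        fba = solve_fba(constrained)
        results[cond.label] = {
            "status": mfa.status,
            "objective": mfa.objective,
            "measured": {rid: meas.entries[rid] for rid in meas.entries},
            "growth_rate": meas.growth_rate,
            "fba_biomass_optimum": fba.optimum,
        }
        if mfa.status == "optimal":
            for rid, v in zip(mfa.reaction_ids, mfa.v):
                flux_rows.append(dict(condition=cond.label, reaction=rid, flux=v))
    pd.DataFrame(flux_rows).to_csv(outdir / "mfa_fluxes.csv", index=False)
    report["mfa"] = results
    with open(outdir / "mfa_summary.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
    log.info("mfa: %d conditions", len(results))


def _stage_sample(cfg: PipelineConfig, outdir: Path, report: dict) -> None:
    model = _load_model(cfg)
    if model is None:
        log.info("sample: no model configured, skipping")
        return
    sets, mus = [], []
    for i, cond in enumerate(cfg.conditions[:2]):
        meas = _condition_measurements(cfg, model, cond, outdir)
        constrained = apply_condition_constraints(
            model, meas, o2_cap=cfg.o2_cap, ngam=cfg.ngam,
            o2_exchange=cfg.o2_exchange,
            acetate_exchange=cfg.exchange_map.get("acetate", "EX_ac"),
            open_exchanges=(cfg.co2_exchange,),
            biomass_band=True,
        )
        seed = _condition_seed(cfg, i, stage=6)
        poly = build_polytope(constrained, seed=seed)
        ss = sample_flux_space(poly, seed=seed + 1, **cfg.sampler)
        np.savetxt(outdir / f"flux_samples_{cond.label}.csv",
                   ss.samples, delimiter=",", fmt="%.8g",
                   header=",".join(ss.reaction_ids), comments="")
        with open(outdir / f"flux_samples_{cond.label}.json", "w") as fh:
            json.dump({"seed": ss.seed, "n_draws": ss.n_draws,
                       "burn_in": ss.burn_in, "thinning": ss.thinning}, fh)
        sets.append(ss)
        mus.append(meas.growth_rate[0])
    if len(sets) == 2:
        comp = compare_conditions(sets[0], mus[0], sets[1], mus[1],
                                  CENTRAL_CARBON_SUBSYSTEMS)
        report["flux_comparison"] = {
            "reactions": comp.reactions,
            "modes_condition1_per_mu": comp.modes_condition1.tolist(),
            "modes_condition2_per_mu": comp.modes_condition2.tolist(),
            "r_squared": comp.r_squared,
        }
        with open(outdir / "flux_comparison.json", "w") as fh:
            json.dump(report["flux_comparison"], fh, indent=1, sort_keys=True)
        log.info("sample: central-carbon R^2 = %.4f", comp.r_squared)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(
    cfg: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES
) -> dict[str, Any]:
    """Execute the requested stages in order; returns the run report.

    The report is a plain dict (JSON-serializable, no timestamps) so that
    two runs with the same config and seed produce byte-identical
    ``report.json`` files.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    canon = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    report: dict[str, Any] = {
        "provenance": {
            "seed": cfg.seed,
            "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
            "stages": list(stages),
        }
    }
    dispatch = {
        "simulate": lambda: _stage_simulate(cfg, outdir),
        "fit": lambda: _stage_fit(cfg, outdir),
        "rates": lambda: _stage_rates(cfg, outdir),
        "stats": lambda: _stage_stats(cfg, outdir, report),
        "dose": lambda: _stage_dose(cfg, outdir, report),
        "mfa": lambda: _stage_mfa(cfg, outdir, report),
        "sample": lambda: _stage_sample(cfg, outdir, report),
    }
    for stage in stages:
        if stage not in dispatch:
            raise PipelineError(f"unknown stage {stage!r}")
        t0 = time.monotonic()
        try:
            dispatch[stage]()
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2f s", stage, time.monotonic() - t0)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
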