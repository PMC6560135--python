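"""Shared run configuration for the numbered analysis scripts.

The scripts walk through the same study design: a wild-type-like strain
and a Pta/AckA-deletion-like strain, each grown with and without the
addition of 128 mM acetate at mid-exponential phase, over four replicate
flasks; the embedded mini-central-carbon network provides the flux model.
Everything is derived from one seed, so re-running a script reproduces
its numbers exactly.
"""

from pathlib import Path

from acetoflux.pipeline import ConditionSpec, PipelineConfig

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"

_SIM = {
    "mu_true": 0.625,          # 1/h, matches the reference flux scale
    "yield_true": 0.133,       # OD600/mM -> specific uptake ~10 mmol/gDW/h
    "secretion_rates_true": {"acetate": 1.88},  # mM/OD600/h -> ~4 mmol/gDW/h
    "acetate_add_time": 1.5,   # h
}


def build_config(seed: int = 1) -> PipelineConfig:
    def cond(strain: str, acetate: float, mu_after: float | None) -> ConditionSpec:
        sim = dict(_SIM, acetate_added_mM=acetate)
        if mu_after is not None:
            sim["mu_after"] = mu_after
        return ConditionSpec(strain=strain, acetate_mM=acetate, simulate=sim)

    return PipelineConfig(
        seed=seed,
        output_dir=str(RUN_DIR),
        n_boot=10_000,
        sampler={"n_draws": 2000, "burn_in": 500, "thinning": 5},
        conditions=[
            cond("wt", 0.0, None),
            cond("wt", 128.0, 0.34),
            cond("acs_pta_acka", 0.0, None),
            cond("acs_pta_acka", 128.0, 0.38),
        ],
        dose_response={
            "baseline": 0.3, "amplitude": 0.45, "decay_k": 0.011757,
            "concentrations": [0, 2, 8, 16, 32, 64, 128],
        },
    )
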