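"""Condition-constrained L1 metabolic flux analysis.

Converts the fitted rates to specific fluxes (mmol/gDW/h), closes the
carbon balance for the theoretical CO2 exchange, builds the
condition-specific bounds (medium uptakes open, O2 capped at 20,
measured exchanges at mean +/- 2 SEM, acetate exchange free under excess
acetate, maintenance fixed), and solves the L1 flux-fitting LP plus the
biomass-maximization FBA sanity check.
"""

import logging

from common import build_config
from acetoflux.pipeline import run_pipeline

logging.basicConfig(level=logging.INFO, format="%(message)s")

cfg = build_config()
report = run_pipeline(cfg, stages=("mfa",))

for label, block in report["mfa"].items():
    print(f"{label}: status={block['status']} "
          f"L1 objective={block['objective']:.4f} "
          f"measured growth={block['growth_rate'][0]:.3f} "
          f"FBA biomass optimum={block['fba_biomass_optimum']:.3f}")
    for rid, (mean, sem) in sorted(block["measured"].items()):
        print(f"  {rid:8s} measured {mean:8.3f} +/- {2 * sem:.3f}")
print(f"full flux vectors: {cfg.output_dir}/mfa_fluxes.csv")
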