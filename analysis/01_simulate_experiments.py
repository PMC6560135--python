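"""Simulate the shake-flask experiments.

Generates four replicate batch cultures per strain x condition (growth
rates drawn with 3% CV around the condition's true rate; OD and
concentration series carry additive measurement noise) and writes tidy
time-series tables under results/run/.  Treated cultures receive 128 mM
acetate at 1.5 h, with the accompanying 52/50 dilution of the culture.
"""

import logging

from common import build_config
from acetoflux.pipeline import run_pipeline

logging.basicConfig(level=logging.INFO, format="%(message)s")

cfg = build_config()
run_pipeline(cfg, stages=("simulate",))
print(f"wrote tidy time series for {len(cfg.conditions)} conditions to "
      f"{cfg.output_dir}/timeseries_*.csv")
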