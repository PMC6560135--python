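"""Fit growth, uptake and secretion kinetics.

Fits B(t) = B0 exp(mu t) to each replicate OD series (window: OD < 1,
post-addition for treated cultures), then the joint growth + glucose
model for mu, Y and r_glc = mu/Y, and the fixed-(mu, B0) secretion model
for acetate.  Prints the replicate aggregates as mean +/- 2 SEM.
"""

import logging
import warnings

import pandas as pd

from common import build_config
from acetoflux.growth_kinetics import mean_2sem
from acetoflux.pipeline import run_pipeline

logging.basicConfig(level=logging.INFO, format="%(message)s")

cfg = build_config()
with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    run_pipeline(cfg, stages=("fit", "rates"))

fits = pd.read_csv(f"{cfg.output_dir}/growth_fits.csv")
rates = pd.read_csv(f"{cfg.output_dir}/rate_fits.csv")
print(f"{'condition':24s} {'mu (1/h)':>18s} {'Y (OD/mM)':>18s} {'r_glc (mM/OD/h)':>18s}")
for label, sub in fits.groupby("condition"):
    m, s = mean_2sem(sub["mu"])
    glc = rates[(rates.condition == label) & (rates.metabolite == "glucose")]
    ym, ys = mean_2sem(glc["yield_Y"])
    rm, rs = mean_2sem(glc["rate"])
    print(f"{label:24s} {m:8.3f} +/- {s:5.3f} {ym:8.4f} +/- {ys:6.4f} "
          f"{rm:8.2f} +/- {rs:5.2f}")
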