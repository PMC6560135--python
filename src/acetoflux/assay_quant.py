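"""Quantification of metabolite concentrations from plate-reader
absorbance records, and the fluorescent-reporter concentration proxy.

Coupled enzymatic assays produce or consume NADH; the assayed
concentration follows from the absorbance change at 340 nm,

    C_metabolite = (dA_metabolite / dA_standard) * C_standard,

scaled by the dilution factor of the culture sample.  To compensate for
instrument drift, the repeated reads before (A1) and after (A2) the
reactions are each fitted with a straight line by ordinary least squares,
and dA = A2 - A1 is evaluated at the time the last enzyme was added.
"""

from __future__ import annotations

import warnings

import numpy as np

from .synthetic_data import PlateReads

__all__ = [
    "AssayError",
    "AssayResult",
    "drift_corrected_delta",
    "concentration_from_assay",
    "quantify_well",
    "reporter_concentration",
]


class AssayError(ValueError):
    """Raised when an assay record cannot be quantified."""


from dataclasses import dataclass


@dataclass
class AssayResult:
    metabolite: str
    delta_A: float
    concentration: float


def _line_at(times: np.ndarray, values: np.ndarray, t: float) -> float:
    if np.allclose(times, times[0]):
        raise AssayError("all reads at the same time: line fit is singular")
    slope, intercept = np.polyfit(times, values, 1)
    return float(slope * t + intercept)


def drift_corrected_delta(reads: PlateReads) -> float:
    """dA = A2 - A1, both extrapolated to the enzyme-addition time."""
    a1 = _line_at(reads.phase1_times, reads.phase1_abs, reads.addition_time)
    a2 = _line_at(reads.phase2_times, reads.phase2_abs, reads.addition_time)
    return a2 - a1


def concentration_from_assay(
    delta_metabolite: float,
    delta_standard: float,
    standard_conc: float,
    dilution_factor: float = 1.0,
) -> float:
    """Concentration (mM) from the absorbance-difference ratio.

    Returns (dA_met / dA_std) * C_std * dilution_factor; small negative
    dA_met (noise around zero) is clamped to 0 with a warning.
    """
    if delta_standard <= 0:
        raise AssayError("standard absorbance difference must be positive")
    if dilution_factor < 1.0:
        raise AssayError("dilution factor must be >= 1")
    if delta_metabolite < 0:
        warnings.warn(
            f"negative absorbance difference ({delta_metabolite:.4g}) clamped to 0",
            stacklevel=2,
        )
        delta_metabolite = 0.0
    return (delta_metabolite / delta_standard) * standard_conc * dilution_factor


def quantify_well(
    metabolite_reads: PlateReads,
    standard_reads: PlateReads,
    metabolite: str = "metabolite",
) -> AssayResult:
    """End-to-end quantification of one sample well against its standard."""
    if not standard_reads.standard_flag:
        raise AssayError("second record must be the standard well")
    da_met = drift_corrected_delta(metabolite_reads)
    da_std = drift_corrected_delta(standard_reads)
    conc = concentration_from_assay(
        da_met,
        da_std,
        standard_reads.standard_conc,
        metabolite_reads.dilution_factor,
    )
    return AssayResult(metabolite=metabolite, delta_A=da_met, concentration=conc)


def reporter_concentration(fluorescence: float, background: float, od: float) -> float:
    """Reporter concentration proxy: (fluorescence - background) / OD600.

    Used for promoter-GFP fusions, where background-corrected fluorescence
    per optical density is proportional to the reporter concentration.
    """
    if od <= 0:
        raise AssayError("optical density must be positive")
    corrected = fluorescence - background
    if corrected < 0:
        warnings.warn(
            f"background exceeds fluorescence ({corrected:.4g} a.u.)", stacklevel=2
        )
    return corrected / od
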