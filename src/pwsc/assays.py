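"""Closed-form metrics for the two companion assays.

Flow cytometry: marker intensity versus the fluorescence-minus-one (FMO)
control, summarized as a Cohen's-d-style effect size — the mean difference
over the root-mean-square of the two standard deviations.  Referencing
each stain to its own FMO cancels donor-specific autofluorescence.

Mitochondrial stress test: oxygen consumption rates (OCR, pmol O2/min)
measured at baseline and after oligomycin, FCCP, and rotenone + antimycin
A injections.  The derived quantities are phase differences relative to
the rotenone/antimycin-A-inhibited (non-mitochondrial) rate.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

import numpy as np

__all__ = ["FmoPair", "fmo_effect_size", "OcrTrace", "ocr_metrics",
           "ocr_trace_from_cycles"]


@dataclasses.dataclass
class FmoPair:
    """Summary intensities of a complete stain and its FMO control."""

    mean_full: float
    sd_full: float
    mean_fmo: float
    sd_fmo: float

    def __post_init__(self) -> None:
        if self.sd_full < 0 or self.sd_fmo < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.sd_full == 0 and self.sd_fmo == 0:
            raise ValueError("at least one standard deviation must be positive")


def fmo_effect_size(p: FmoPair) -> float:
    """(mean_full − mean_fmo) / sqrt((sd_full² + sd_fmo²) / 2)."""
    denom = math.sqrt((p.sd_full ** 2 + p.sd_fmo ** 2) / 2.0)
    if denom == 0:
        raise ValueError("zero pooled standard deviation")
    return (p.mean_full - p.mean_fmo) / denom


@dataclasses.dataclass
class OcrTrace:
    """Per-phase OCR summaries (baseline-corrected convention)."""

    baseline: float
    post_oligomycin: float
    post_fccp: float
    post_rot_aa: float

    def __post_init__(self) -> None:
        vals = (self.baseline, self.post_oligomycin, self.post_fccp,
                self.post_rot_aa)
        if not all(np.isfinite(vals)):
            raise ValueError("OCR values must be finite")


def ocr_trace_from_cycles(cycles: Sequence[Sequence[float]],
                          summary: Literal["mean", "last"] = "mean") -> OcrTrace:
    """Collapse a 4-phase × n-cycle OCR time series to phase summaries.

    Each phase is measured over (typically 3) cycles; the phase value is
    the cycle mean by default, or the last cycle with ``summary="last"``.
    """
    if len(cycles) != 4:
        raise ValueError("expected 4 phases (baseline, oligomycin, FCCP, rot/AA)")
    vals = []
    for phase in cycles:
        arr = np.asarray(phase, dtype=float)
        if arr.size == 0:
            raise ValueError("empty phase")
        vals.append(float(arr.mean() if summary == "mean" else arr[-1]))
    return OcrTrace(*vals)


def ocr_metrics(t: OcrTrace) -> dict[str, float]:
    """Basal respiration, maximal respiration, proton leak (and, as a
    derived convenience, ATP-linked respiration = basal − proton leak)."""
    basal = t.baseline - t.post_rot_aa
    maximal = t.post_fccp - t.post_rot_aa
    proton_leak = t.post_oligomycin - t.post_rot_aa
    return {"basal": basal, "maximal": maximal, "proton_leak": proton_leak,
            "atp_linked": basal - proton_leak}
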