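"""Closed-form assay metrics: FMO-referenced flow-cytometry effect size and
mitochondrial-stress respiration quantities."""

from pwsc.assays import (FmoPair, fmo_effect_size, ocr_metrics,
                         ocr_trace_from_cycles)

# marker intensity vs its fluorescence-minus-one control
pair = FmoPair(mean_full=100.0, sd_full=10.0, mean_fmo=50.0, sd_fmo=10.0)
print(f"FMO effect size: {fmo_effect_size(pair):.2f}")
# 5.0 = the stain shifts the mean five pooled standard deviations above
# background; referencing the FMO cancels donor autofluorescence.

# OCR time series: 3 measurement cycles per phase (baseline, oligomycin,
# FCCP, rotenone+antimycin A), pmol O2/min
cycles = [[78, 80, 82], [30, 31, 29], [118, 120, 122], [20, 20, 20]]
trace = ocr_trace_from_cycles(cycles)
for k, v in ocr_metrics(trace).items():
    print(f"{k:12s} {v:6.1f} pmol O2/min")
# basal = baseline minus non-mitochondrial respiration; maximal = FCCP
# -uncoupled rate minus non-mitochondrial; proton leak = oligomycin
# -insensitive mitochondrial rate.
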