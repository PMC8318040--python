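"""Segment synthetic microstate EEG and recover the planted classes.

Generates 45 s of 32-channel EEG in which six fixed scalp topographies
alternate as a Markov segment process (mean dwell 100 ms) under an
alpha-band strength envelope, then runs the standard segmentation path:
GFP -> smoothed-GFP peaks -> peak topographies -> dual-threshold AAHC.
"""

import numpy as np

import mstates as ms
from mstates.cluster import polarity_dissimilarity

cfg = ms.SynthConfig(K=6, length=45.0, snr=5.0, seed=42)
rec, truth = ms.simulate(cfg)
rec = ms.average_reference(rec)

maps = ms.collect_peak_maps([rec], window=50)
model = ms.dtaahc(maps)

print(f"peak maps submitted to clustering : {maps.n_maps}")
print(f"classes found (6 planted)         : {model.K}")
print(f"total GEV on peak maps            : {100 * model.total_gev:.1f} %")
print("per-class GEV (%)                 :",
      np.round(100 * model.per_class_gev, 2))
worst = max(
    min(polarity_dissimilarity(t, p) for p in truth.templates)
    for t in model.templates
)
print(f"worst template-recovery dissimilarity : {worst:.3f}")
print()
print("The clustering should find exactly the planted class count, explain")
print(">= 85 % of the GFP^2-weighted peak-map variance, and return templates")
print("nearly identical (dissimilarity << 0.1) to the planted topographies.")
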