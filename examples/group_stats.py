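"""Compare microstate parameters between high- and low-rated trial groups.

Builds a rated synthetic dataset in which the high-valence condition
lengthens class 1's dwell time (150 ms vs 100 ms), extracts per-trial
features, and runs Wilcoxon rank-sum comparisons between groups.
"""

import numpy as np

import mstates as ms
from mstates.backfit import SmoothingConfig
from mstates.cluster import TemplateSet
from mstates.features import feature_names, temporal_features, transition_matrix

K = 3
high = ms.SynthConfig(K=K, length=5.0, snr=5.0, seed=1,
                      mean_duration=[150.0, 100.0, 100.0])
low = ms.SynthConfig(K=K, length=5.0, snr=5.0, seed=1)
trials, planted = ms.make_dataset(high, low, n_trials_per_class=50, seed=3)

templates = TemplateSet(templates=planted, labels=np.zeros(0, dtype=int),
                        per_class_gev=np.zeros(K), total_gev=0.0)
rows = []
for rec in trials.trials:
    rec = ms.average_reference(rec)
    seq = ms.assign_labels(rec, templates)
    seq = ms.smooth_labels(seq, SmoothingConfig(), rec, templates)
    vec = ms.build_feature_vector(
        temporal_features(seq, rec, templates),
        transition_matrix(ms.extract_segments(seq), K),
    )
    rows.append(dict(zip(feature_names(K), vec), trial_id=rec.meta["trial_id"]))

import pandas as pd

feats = pd.DataFrame(rows)
split = ms.split_high_low(trials.ratings, "valence")
report = ms.compare_parameters(feats, split)

flagged = report[report["sig_05"]]
print(f"features tested            : {len(report)}")
print(f"flagged at alpha = 0.05    : {len(flagged)}")
print("\nmost significant rows:")
cols = ["parameter", "class", "mean_high", "mean_low", "p_value"]
print(report.nsmallest(5, "p_value")[cols].round(4).to_string(index=False))
print()
print("The planted effect (longer class-1 dwell in the high group) should")
print("surface as a highly significant duration difference for class 1,")
print("echoed in coverage/occurrence; unrelated features stay mostly flat.")
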