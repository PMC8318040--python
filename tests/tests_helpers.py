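"""Shared helpers for tests: ground-truth-template feature extraction."""

import numpy as np
import pandas as pd

import mstates as ms
from mstates.backfit import SmoothingConfig
from mstates.cluster import TemplateSet
from mstates.features import feature_names, temporal_features, transition_matrix


def trial_features(trialset: ms.TrialSet, templates: np.ndarray) -> pd.DataFrame:
    """Backfit every trial with the given templates and build a feature table."""
    K = templates.shape[0]
    ts = TemplateSet(
        templates=templates,
        labels=np.zeros(0, dtype=int),
        per_class_gev=np.zeros(K),
        total_gev=0.0,
    )
    rows = []
    for rec in trialset.trials:
        rec_ar = ms.average_reference(rec)
        seq = ms.assign_labels(rec_ar, ts)
        seq = ms.smooth_labels(seq, SmoothingConfig(), rec_ar, ts)
        tf = temporal_features(seq, rec_ar, ts)
        tm = transition_matrix(ms.extract_segments(seq), K)
        vec = ms.build_feature_vector(tf, tm, which="combined")
        row = dict(zip(feature_names(K, "combined"), vec))
        row["trial_id"] = rec.meta["trial_id"]
        rows.append(row)
    return pd.DataFrame(rows)
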