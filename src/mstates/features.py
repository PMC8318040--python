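"""Microstate sequence features: temporal parameters and transition matrix.

Per class l the temporal parameters are mean segment duration (ms),
occurrence (segments per second), time coverage (%), and GEV (%). The exact
identity coverage_l = occurrence_l * duration_l / 10 links the first three.
Transitions are counted between consecutive *segments* (distinct-class run
pairs), so the diagonal is zero and the matrix captures switching structure
rather than dwell times; a sample-level mode (diagonal included) is
available for the classical Markov-chain reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backfit import MicrostateSequence, SegmentList, extract_segments
from .cluster import TemplateSet
from .io import EEGRecording

__all__ = [
    "TransitionMatrix",
    "mean_duration",
    "occurrence",
    "coverage",
    "class_gev",
    "transition_matrix",
    "split_windows",
    "temporal_features",
    "build_feature_vector",
    "feature_names",
]

log = logging.getLogger(__name__)


@dataclass
class TransitionMatrix:
    """Row-stochastic K x K matrix of class-switch probabilities."""

    probs: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def K(self) -> int:
        return self.probs.shape[0]


def mean_duration(segs: SegmentList, cls: int, rate: float) -> float:
    """Average run length of a class in milliseconds; 0 if absent."""
    if not rate > 0:
        raise ValueError("rate must be positive")
    lengths = segs.runs[segs.runs[:, 0] == cls, 2]
    if lengths.size == 0:
        return 0.0
    return float(lengths.mean() * 1000.0 / rate)


def occurrence(segs: SegmentList, cls: int, rate: float) -> float:
    """Segments of the class per second of analysis time."""
    if not rate > 0:
        raise ValueError("rate must be positive")
    n_runs = int(np.sum(segs.runs[:, 0] == cls))
    return n_runs / (segs.n_samples / rate)


def coverage(segs: SegmentList, cls: int) -> float:
    """Percentage of samples labeled with the class."""
    covered = int(np.sum(segs.runs[segs.runs[:, 0] == cls, 2]))
    return 100.0 * covered / segs.n_samples


def class_gev(
    seq: MicrostateSequence, rec: EEGRecording, templates: TemplateSet
) -> np.ndarray:
    """Per-class explained variance (%) over all samples of a recording.

    GFP^2-weighted squared spatial correlation between each sample and its
    assigned template, normalized by the total GFP^2. Distinct from the
    clustering-time GEV, which is evaluated on peak maps only.
    """
    X = rec.data.T - rec.data.T.mean(axis=1, keepdims=True)
    gfp = np.sqrt(np.mean(X**2, axis=1))
    w = gfp**2
    denom = w.sum()
    if denom == 0:
        raise ValueError("recording has zero total GFP")
    Tn = templates.templates / np.linalg.norm(templates.templates, axis=1, keepdims=True)
    Xn = X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-300)
    own = Tn[seq.labels - 1]
    c2 = np.einsum("ij,ij->i", Xn, own) ** 2
    c2[gfp == 0] = 0.0
    per = np.bincount(seq.labels - 1, weights=w * c2, minlength=templates.K)
    return 100.0 * per / denom


def transition_matrix(
    segs: SegmentList | MicrostateSequence, K: int, level: str = "segment"
) -> TransitionMatrix:
    """Empirical transition probabilities between microstate classes.

    ``level='segment'`` (default) counts consecutive-run pairs, diagonal 0;
    ``level='sample'`` counts consecutive-sample pairs, diagonal included.
    Rows with no outgoing transition stay all-zero.
    """
    if level == "segment":
        runs = segs.runs if isinstance(segs, SegmentList) else extract_segments(segs).runs
        seq_ids = runs[:, 0]
    elif level == "sample":
        seq_ids = segs.decode() if isinstance(segs, SegmentList) else segs.labels
    else:
        raise ValueError("level must be 'segment' or 'sample'")
    counts = np.zeros((K, K))
    if len(seq_ids) >= 2:
        np.add.at(counts, (seq_ids[:-1] - 1, seq_ids[1:] - 1), 1.0)
    row_sums = counts.sum(axis=1, keepdims=True)
    probs = np.divide(counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0)
    return TransitionMatrix(probs=probs, counts=counts)


def split_windows(rec: EEGRecording, length: float = 5.0, stride: float | None = None) -> list[EEGRecording]:
    """Cut a recording into consecutive windows of ``length`` seconds.

    Default stride equals the length (non-overlapping). A trailing remainder
    shorter than one window is dropped.
    """
    n_win = int(round(length * rec.rate))
    n_step = int(round((stride or length) * rec.rate))
    if n_win > rec.n_samples:
        raise ValueError("recording shorter than one window")
    out = []
    start, w = 0, 0
    while start + n_win <= rec.n_samples:
        win = rec.with_data(rec.data[:, start : start + n_win])
        win.meta = dict(rec.meta, window_id=w, window_start=start)
        out.append(win)
        start += n_step
        w += 1
    dropped = rec.n_samples - (start - n_step + n_win)
    if dropped > 0:
        log.info("split_windows dropped %d trailing samples", dropped)
    return out


def temporal_features(
    seq: MicrostateSequence,
    rec: EEGRecording | None = None,
    templates: TemplateSet | None = None,
) -> pd.DataFrame:
    """The four temporal parameters for every class, as one tidy row set.

    GEV requires the source recording and templates; without them the gev
    column is NaN.
    """
    segs = extract_segments(seq)
    gevs = (
        class_gev(seq, rec, templates)
        if rec is not None and templates is not None
        else np.full(seq.K, np.nan)
    )
    rows = [
        {
            "class": cls,
            "duration_ms": mean_duration(segs, cls, seq.rate),
            "occurrence": occurrence(segs, cls, seq.rate),
            "coverage_pct": coverage(segs, cls),
            "gev_pct": gevs[cls - 1],
        }
        for cls in range(1, seq.K + 1)
    ]
    return pd.DataFrame(rows)


def feature_names(K: int, which: str = "combined") -> list[str]:
    """Stable column names: per-class temporal block, then off-diagonal
    transitions row-major."""
    temporal = [
        f"{stem}.c{cls}"
        for cls in range(1, K + 1)
        for stem in ("dur_ms", "occ", "cov", "gev")
    ]
    transitions = [
        f"tp.c{i}.c{j}"
        for i in range(1, K + 1)
        for j in range(1, K + 1)
        if i != j
    ]
    if which == "temporal":
        return temporal
    if which == "transitions":
        return transitions
    if which == "combined":
        return temporal + transitions
    raise ValueError("which must be 'temporal', 'transitions' or 'combined'")


def build_feature_vector(
    tf: pd.DataFrame, tm: TransitionMatrix, which: str = "combined"
) -> np.ndarray:
    """Flatten temporal parameters and transition probabilities.

    Ordering: classes ascending, within class (duration, occurrence,
    coverage, gev); then transitions row-major excluding the diagonal.
    """
    K = len(tf)
    if tm.K != K:
        raise ValueError("class count mismatch between temporal table and transitions")
    tf = tf.sort_values("class")
    temporal = tf[["duration_ms", "occurrence", "coverage_pct", "gev_pct"]].to_numpy().ravel()
    off = ~np.eye(K, dtype=bool)
    transitions = tm.probs[off]
    if which == "temporal":
        return temporal
    if which == "transitions":
        return transitions
    if which == "combined":
        return np.concatenate([temporal, transitions])
    raise ValueError("which must be 'temporal', 'transitions' or 'combined'")
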