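"""Backfitting: label every sample with its best microstate class.

Each sample's topography is compared with every class template by spatial
correlation (absolute correlation in polarity-invariant mode) and assigned
the winning class, producing a symbolic sequence. Temporal smoothing then
removes runs shorter than a minimum duration, relabeling their samples to
whichever flanking class fits better, so that sensor noise cannot shatter a
quasi-stable period into spurious micro-segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cluster import TemplateSet
from .io import EEGRecording

__all__ = [
    "MicrostateSequence",
    "SegmentList",
    "SmoothingConfig",
    "assign_labels",
    "smooth_labels",
    "extract_segments",
]

log = logging.getLogger(__name__)


@dataclass
class MicrostateSequence:
    """Per-sample class ids in {1..K} at a given sampling rate."""

    labels: np.ndarray
    K: int
    rate: float
    origin: object = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.K):
            raise ValueError("labels must lie in {1..K}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SegmentList:
    """Run-length encoding: rows of (class id, start sample, length)."""

    runs: np.ndarray  # (n_runs, 3) int
    n_samples: int
    rate: float

    def __post_init__(self) -> None:
        self.runs = np.asarray(self.runs, dtype=int).reshape(-1, 3)
        if self.runs.size:
            starts = self.runs[:, 1]
            lengths = self.runs[:, 2]
            if np.any(lengths < 1):
                raise ValueError("runs must have positive length")
            if starts[0] != 0 or np.any(starts[1:] != starts[:-1] + lengths[:-1]):
                raise ValueError("runs must be contiguous and non-overlapping")
            if starts[-1] + lengths[-1] != self.n_samples:
                raise ValueError("runs must cover the sequence")
            if np.any(self.runs[1:, 0] == self.runs[:-1, 0]):
                raise ValueError("adjacent runs must differ in class")

    def __len__(self) -> int:
        return len(self.runs)

    def decode(self) -> np.ndarray:
        """Reconstruct the per-sample label array."""
        return np.repeat(self.runs[:, 0], self.runs[:, 2])


@dataclass(frozen=True)
class SmoothingConfig:
    min_duration: int = 3  # samples
    max_passes: int = 10

    def __post_init__(self) -> None:
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")


def _correlation_rows(data: np.ndarray, templates: np.ndarray, invariant: bool) -> np.ndarray:
    """(n_samples, K) spatial correlation of each sample with each template."""
    X = data.T - data.T.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    Tn = templates / np.linalg.norm(templates, axis=1, keepdims=True)
    C = np.divide(X, np.maximum(norms, 1e-300)) @ Tn.T
    C[norms[:, 0] == 0] = np.nan  # degenerate samples resolved by caller
    return np.abs(C) if invariant else C


def assign_labels(
    rec: EEGRecording,
    templates: TemplateSet,
    polarity: str = "invariant",
    at_peaks=None,
) -> MicrostateSequence:
    """Label each sample with the class of highest (absolute) correlation.

    Zero-GFP samples cannot be scored; they inherit the previous sample's
    label (the first such sample takes the label of the first scorable one).
    With ``at_peaks`` (a PeakIndexSet or index array), only peak samples are
    fitted and every other sample takes the label of its nearest peak.
    """
    if rec.n_channels != templates.n_channels:
        raise ValueError("channel count mismatch between recording and templates")
    if at_peaks is not None:
        idx = np.asarray(getattr(at_peaks, "indices", at_peaks), dtype=int)
        if idx.size == 0:
            raise ValueError("peak-only labeling needs at least one peak")
        peak_rec = rec.with_data(rec.data[:, idx])
        peak_seq = assign_labels(peak_rec, templates, polarity)
        nearest = np.abs(np.arange(rec.n_samples)[:, None] - idx[None, :]).argmin(axis=1)
        return MicrostateSequence(
            labels=peak_seq.labels[nearest],
            K=templates.K,
            rate=rec.rate,
            origin=rec.meta.get("trial_id"),
        )
    C = _correlation_rows(rec.data, templates.templates, polarity == "invariant")
    degenerate = np.isnan(C[:, 0])
    labels = np.empty(len(degenerate), dtype=int)
    valid = ~degenerate
    if not valid.any():
        raise ValueError("all samples are degenerate (zero GFP)")
    labels[valid] = np.argmax(C[valid], axis=1) + 1
    if degenerate.any():
        log.warning("%d zero-GFP samples inherit neighboring labels", degenerate.sum())
        first_valid = int(np.flatnonzero(valid)[0])
        labels[:first_valid] = labels[first_valid]
        for t in np.flatnonzero(degenerate):
            if t > first_valid:
                labels[t] = labels[t - 1]
    return MicrostateSequence(
        labels=labels, K=templates.K, rate=rec.rate, origin=rec.meta.get("trial_id")
    )


def extract_segments(seq: MicrostateSequence) -> SegmentList:
    """Run-length encode the label sequence."""
    labels = seq.labels
    if labels.size == 0:
        raise ValueError("empty sequence")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    runs = np.column_stack([labels[starts], starts, ends - starts])
    return SegmentList(runs=runs, n_samples=len(labels), rate=seq.rate)


def smooth_labels(
    seq: MicrostateSequence,
    cfg: SmoothingConfig,
    rec: EEGRecording,
    templates: TemplateSet,
    polarity: str = "invariant",
) -> MicrostateSequence:
    """Reject runs shorter than ``min_duration`` samples.

    Each offending run's samples are relabeled one by one to whichever
    flanking run's template correlates better with that sample's topography
    (edge runs have a single flank), repeating up to ``max_passes`` times.
    Because per-sample relabeling can split a rejected run between its
    flanks and spawn fresh short runs, a final phase absorbs any remaining
    short interior run wholly into its better-correlated flank, which
    strictly reduces the run count and therefore terminates with no interior
    run shorter than ``min_duration``.
    """
    C = _correlation_rows(rec.data, templates.templates, polarity == "invariant")
    C = np.nan_to_num(C, nan=-np.inf)
    labels = seq.labels.copy()

    def short_interior(runs: np.ndarray) -> list[int]:
        return [
            r
            for r in range(len(runs))
            if runs[r, 2] < cfg.min_duration and 0 < r < len(runs) - 1
        ]

    for _ in range(cfg.max_passes):
        runs = extract_segments(
            MicrostateSequence(labels, seq.K, seq.rate, seq.origin)
        ).runs
        short = short_interior(runs)
        if not short:
            break
        for r in short:
            cls, start, length = runs[r]
            left = runs[r - 1, 0]
            right = runs[r + 1, 0]
            for t in range(start, start + length):
                labels[t] = left if C[t, left - 1] >= C[t, right - 1] else right

    while True:
        runs = extract_segments(
            MicrostateSequence(labels, seq.K, seq.rate, seq.origin)
        ).runs
        short = short_interior(runs)
        if not short:
            break
        cls, start, length = runs[short[0]]
        left = runs[short[0] - 1, 0]
        right = runs[short[0] + 1, 0]
        span = slice(start, start + length)
        take_left = C[span, left - 1].sum() >= C[span, right - 1].sum()
        labels[span] = left if take_left else right
    return MicrostateSequence(labels=labels, K=seq.K, rate=seq.rate, origin=seq.origin)
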