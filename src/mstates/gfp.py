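"""Global field power: computation, smoothing, peak picking, peak-map pooling.

GFP at time t is the standard deviation of the scalp potential across
electrodes — a reference-free measure of momentary global response strength.
Topographies at GFP local maxima have the best signal-to-noise ratio and are
the material submitted to microstate clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EEGRecording, TrialSet

__all__ = [
    "GFPSeries",
    "PeakIndexSet",
    "TopographyMatrix",
    "compute_gfp",
    "smooth_gfp",
    "find_gfp_peaks",
    "collect_peak_maps",
]

log = logging.getLogger(__name__)


@dataclass
class GFPSeries:
    """Per-sample GFP values (µV) with their sampling rate."""

    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("GFP series must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("GFP values must be nonnegative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PeakIndexSet:
    """Strictly increasing sample indices of GFP local maxima."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class TopographyMatrix:
    """Average-referenced scalp maps stacked row-wise, with GFP and origin.

    ``maps`` is ``(n_maps, n_channels)``; ``gfp[i]`` is the field power of row
    i; ``origin`` records ``(recording id, sample index)`` per row.
    """

    maps: np.ndarray
    gfp: np.ndarray
    origin: pd.DataFrame
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.gfp = np.asarray(self.gfp, dtype=float)
        if self.maps.shape[0] != len(self.gfp):
            raise ValueError("one GFP value per map required")
        if len(self.origin) != self.maps.shape[0]:
            raise ValueError("one origin row per map required")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]


def compute_gfp(rec: EEGRecording) -> GFPSeries:
    """Standard deviation across electrodes at every sample.

    GFP(t) = sqrt( (1/N) * sum_i (u_i(t) - mean(t))^2 ); invariant to any
    per-sample offset common to all channels, hence to the reference choice.
    """
    if rec.n_channels < 2:
        raise ValueError("GFP needs at least 2 channels")
    return GFPSeries(values=rec.data.std(axis=0, ddof=0), rate=rec.rate)


def _gaussian_kernel(window: int) -> np.ndarray:
    # sigma = window/6 so the window spans about +/- 3 sigma
    half = window // 2
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / (window / 6.0)) ** 2)
    return k / k.sum()


def smooth_gfp(gfp: GFPSeries, window: int = 50) -> GFPSeries:
    """Gaussian-weighted moving average; edges use a renormalized kernel.

    An even window is widened by one sample to stay symmetric. ``window=1``
    is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(gfp):
        raise ValueError("window longer than series")
    if window == 1:
        return GFPSeries(gfp.values.copy(), gfp.rate)
    if window % 2 == 0:
        window += 1
    kernel = _gaussian_kernel(window)
    # renormalized truncated kernel at the edges: convolve values and a
    # ones-mask with zero padding, then divide
    num = np.convolve(gfp.values, kernel, mode="same")
    den = np.convolve(np.ones_like(gfp.values), kernel, mode="same")
    return GFPSeries(num / den, gfp.rate)


def find_gfp_peaks(
    gfp: GFPSeries,
    min_distance: int | None = None,
    min_prominence: float | None = None,
) -> PeakIndexSet:
    """Local maxima: v[t-1] < v[t] >= v[t+1], first sample of plateaus.

    Endpoints are never peaks. A plateau counts once, at its first sample,
    and only if the series falls (or stays level to the end) after it.
    Optional constraints: ``min_prominence`` drops shallow peaks;
    ``min_distance`` greedily keeps the highest peaks at least that many
    samples apart. Neither is applied by default.
    """
    v = gfp.values
    if len(v) < 3:
        raise ValueError("series too short for peak detection")
    peaks = []
    t = 1
    n = len(v)
    while t < n - 1:
        if v[t] > v[t - 1]:
            # scan the plateau starting at t
            end = t
            while end + 1 < n and v[end + 1] == v[t]:
                end += 1
            if end == n - 1 or v[end + 1] < v[t]:
                peaks.append(t)
            t = end + 1
        else:
            t += 1
    idx = np.array(peaks, dtype=int)
    if min_prominence is not None and idx.size:
        from scipy.signal import peak_prominences

        prom = peak_prominences(v, idx)[0]
        idx = idx[prom >= min_prominence]
    if min_distance is not None and idx.size:
        keep: list[int] = []
        for t in idx[np.argsort(-v[idx], kind="stable")]:
            if all(abs(t - k) >= min_distance for k in keep):
                keep.append(int(t))
        idx = np.array(sorted(keep), dtype=int)
    return PeakIndexSet(idx)


def collect_peak_maps(trials: TrialSet | list[EEGRecording], window: int = 50) -> TopographyMatrix:
    """Pool original topographies at smoothed-GFP peaks across all trials.

    Peaks are located on the smoothed GFP, but the maps are taken from the
    unsmoothed data at those indices, so the pooled topographies are genuine
    instantaneous fields. Maps are average-referenced on extraction. Trials
    without any peak contribute nothing.
    """
    recs = trials.trials if isinstance(trials, TrialSet) else trials
    maps, gfps, rows = [], [], []
    names: tuple[str, ...] = ()
    for k, rec in enumerate(recs):
        names = rec.montage.channel_names
        rid = rec.meta.get("trial_id", k)
        series = compute_gfp(rec)
        try:
            peaks = find_gfp_peaks(smooth_gfp(series, window))
        except ValueError:
            log.warning("trial %r too short for peak detection; skipped", rid)
            continue
        if len(peaks) == 0:
            log.warning("trial %r has no GFP peaks; contributes no maps", rid)
            continue
        topo = rec.data[:, peaks.indices].T
        topo = topo - topo.mean(axis=1, keepdims=True)
        maps.append(topo)
        gfps.append(series.values[peaks.indices])
        rows.extend((rid, int(i)) for i in peaks.indices)
    if not maps:
        return TopographyMatrix(
            maps=np.zeros((0, recs[0].n_channels if recs else 0)),
            gfp=np.zeros(0),
            origin=pd.DataFrame(columns=["recording_id", "sample"]),
            channel_names=names,
        )
    return TopographyMatrix(
        maps=np.vstack(maps),
        gfp=np.concatenate(gfps),
        origin=pd.DataFrame(rows, columns=["recording_id", "sample"]),
        channel_names=names,
    )
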