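"""Synthetic microstate-structured EEG with known ground truth.

The generator emulates the standard microstate model of spontaneous EEG: a
small set of fixed scalp topographies alternates as a first-order Markov
segment process, each class dwelling for ~80-120 ms on average, while an
oscillatory strength envelope (alpha-band by default) waxes and wanes the
field and white sensor noise is added on top. Segment polarity flips at
random so that polarity-invariant clustering is genuinely exercised. Every
quantity a pipeline stage should recover — templates, per-sample labels,
segment list — is returned alongside the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .backfit import MicrostateSequence, SegmentList, extract_segments
from .cluster import polarity_dissimilarity
from .io import ChannelMontage, EEGRecording, RatingTable, TrialSet

__all__ = ["SynthConfig", "GroundTruth", "make_templates", "simulate", "make_dataset"]


@dataclass
class SynthConfig:
    """Study conditions for one simulated recording.

    mean_duration is the mean microstate dwell time in ms (a scalar, or one
    value per class); snr is the ratio of template-signal power to additive
    white-noise power; the envelope is ``floor + (1-floor)*|sin|`` at
    ``envelope_freq`` Hz so field strength waxes and wanes without ever
    vanishing exactly on the sample grid.
    """

    n_channels: int = 32
    K: int = 6
    rate: float = 500.0
    mean_duration: float | Sequence[float] = 100.0
    duration_distribution: str = "geometric"
    duration_shape: float = 2.0  # gamma shape when duration_distribution='gamma'
    transition_matrix: object = "uniform"
    envelope_freq: float = 10.0
    envelope_floor: float = 0.1
    amplitude: float = 10.0  # µV scale of the template signal
    snr: float = 5.0
    length: float = 10.0
    min_gmd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if isinstance(self.transition_matrix, str):
            if self.transition_matrix != "uniform":
                raise ValueError("transition_matrix must be a matrix or 'uniform'")
        else:
            T = np.asarray(self.transition_matrix, dtype=float)
            if T.shape != (self.K, self.K):
                raise ValueError("transition matrix must be K x K")
            if np.any(np.diag(T) != 0):
                raise ValueError("transition matrix diagonal must be 0")
            if not np.allclose(T.sum(axis=1), 1.0):
                raise ValueError("transition rows must sum to 1")
            self.transition_matrix = T

    def durations_ms(self) -> np.ndarray:
        d = np.broadcast_to(np.asarray(self.mean_duration, dtype=float), (self.K,))
        if np.any(d <= 0):
            raise ValueError("mean durations must be positive")
        return d.copy()

    def markov_matrix(self) -> np.ndarray:
        if isinstance(self.transition_matrix, str):
            return (np.ones((self.K, self.K)) - np.eye(self.K)) / (self.K - 1)
        return np.asarray(self.transition_matrix, dtype=float)


@dataclass
class GroundTruth:
    """What the generator planted: templates, labels, segments, config echo."""

    templates: np.ndarray
    labels: MicrostateSequence
    segments: SegmentList
    config: dict = field(default_factory=dict)


def make_templates(
    n_channels: int, K: int, min_gmd: float = 0.8, seed: int = 0
) -> np.ndarray:
    """K zero-mean unit-GFP topographies with pairwise dissimilarity >= min_gmd.

    Maps are drawn as random orthogonal directions inside the zero-mean
    subspace (mutually orthogonal maps have polarity-aware dissimilarity
    sqrt(2)); a bounded number of redraws guards the dissimilarity floor.
    """
    if K > n_channels - 1:
        raise ValueError("K must be <= n_channels - 1 (zero-mean subspace capacity)")
    for attempt in range(50):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
        raw = rng.standard_normal((n_channels, K))
        raw -= raw.mean(axis=0, keepdims=True)
        q, _ = np.linalg.qr(raw)
        maps = q.T  # K orthonormal zero-mean rows
        maps = maps - maps.mean(axis=1, keepdims=True)  # numerically re-center
        maps /= np.sqrt(np.mean(maps**2, axis=1, keepdims=True))  # unit GFP
        ok = all(
            polarity_dissimilarity(maps[i], maps[j]) >= min_gmd
            for i in range(K)
            for j in range(i + 1, K)
        )
        if ok:
            return maps
    raise ValueError(f"could not construct {K} maps with min_gmd={min_gmd}")


def _draw_length(rng: np.random.Generator, mean_samples: float, cfg: SynthConfig) -> int:
    if cfg.duration_distribution == "geometric":
        return int(rng.geometric(min(1.0 / mean_samples, 1.0)))
    if cfg.duration_distribution == "gamma":
        return max(1, int(round(rng.gamma(cfg.duration_shape, mean_samples / cfg.duration_shape))))
    raise ValueError("duration_distribution must be 'geometric' or 'gamma'")


def simulate(
    cfg: SynthConfig,
    templates: np.ndarray | None = None,
    dynamics_seed: int | None = None,
) -> tuple[EEGRecording, GroundTruth]:
    """Generate one recording plus its ground truth; deterministic per seed.

    ``templates`` overrides the seed-derived topographies (used when many
    trials must share one template set); ``dynamics_seed`` decouples the
    segment/noise randomness from the template seed.
    """
    if templates is None:
        templates = make_templates(cfg.n_channels, cfg.K, cfg.min_gmd, cfg.seed)
    else:
        templates = np.asarray(templates, dtype=float)
        if templates.shape != (cfg.K, cfg.n_channels):
            raise ValueError("templates must be (K, n_channels)")
    dseed = cfg.seed if dynamics_seed is None else dynamics_seed
    rng = np.random.default_rng(np.random.SeedSequence([int(dseed), 0xEE]))

    n_samples = int(round(cfg.length * cfg.rate))
    means = cfg.durations_ms() / 1000.0 * cfg.rate  # samples per class
    T = cfg.markov_matrix()

    labels = np.empty(n_samples, dtype=int)
    signs = np.empty(n_samples)
    t = 0
    cls = int(rng.integers(cfg.K)) + 1
    while t < n_samples:
        length = min(_draw_length(rng, means[cls - 1], cfg), n_samples - t)
        labels[t : t + length] = cls
        signs[t : t + length] = rng.choice([-1.0, 1.0])
        t += length
        cls = int(rng.choice(cfg.K, p=T[cls - 1])) + 1

    time = np.arange(n_samples) / cfg.rate
    env = cfg.envelope_floor + (1.0 - cfg.envelope_floor) * np.abs(
        np.sin(2.0 * np.pi * cfg.envelope_freq * time)
    )
    clean = templates[labels - 1].T * (cfg.amplitude * env * signs)  # (N, S)
    # templates have unit GFP, so mean clean power per channel is
    # amplitude^2 * mean(env^2); solve the noise sigma from the target SNR
    sigma = cfg.amplitude * np.sqrt(np.mean(env**2) / cfg.snr)
    noise = rng.standard_normal(clean.shape) * sigma
    data = clean + noise

    montage = ChannelMontage(tuple(f"ch{i + 1:02d}" for i in range(cfg.n_channels)))
    rec = EEGRecording(data=data, rate=cfg.rate, montage=montage, meta={"synthetic": True})
    seq = MicrostateSequence(labels=labels, K=cfg.K, rate=cfg.rate)
    cfg_echo = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in asdict(cfg).items()
    }
    truth = GroundTruth(
        templates=templates, labels=seq, segments=extract_segments(seq), config=cfg_echo
    )
    return rec, truth


def make_dataset(
    recipe_high: SynthConfig,
    recipe_low: SynthConfig,
    n_trials_per_class: int,
    seed: int = 0,
    dimension: str = "valence",
) -> tuple[TrialSet, np.ndarray]:
    """Simulate a rated two-condition trial set from two recipes.

    High-recipe trials are rated 7.0 and low-recipe trials 3.0 on the chosen
    dimension (5.0 on the other); per-trial seeds derive from the master
    seed. Both recipes must share channels, K, and rate; all trials use the
    high recipe's template set so the conditions differ only in dynamics.
    Returns the trial set and the shared templates.
    """
    for attr in ("n_channels", "K", "rate"):
        if getattr(recipe_high, attr) != getattr(recipe_low, attr):
            raise ValueError(f"recipes must share {attr}")
    shared = make_templates(
        recipe_high.n_channels, recipe_high.K, recipe_high.min_gmd, recipe_high.seed
    )
    trials, rows = [], []
    for i in range(2 * n_trials_per_class):
        is_high = i < n_trials_per_class
        recipe = recipe_high if is_high else recipe_low
        dseed = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % (2**31))
        rec, truth = simulate(recipe, templates=shared, dynamics_seed=dseed)
        rec.meta.update(trial_id=f"trial{i:03d}", condition="high" if is_high else "low")
        truth.labels.origin = rec.meta["trial_id"]
        rec.meta["ground_truth"] = truth
        trials.append(rec)
        rating = 7.0 if is_high else 3.0
        rows.append(
            {
                "trial_id": rec.meta["trial_id"],
                "valence": rating if dimension == "valence" else 5.0,
                "arousal": rating if dimension == "arousal" else 5.0,
            }
        )
    ratings = RatingTable(pd.DataFrame(rows))
    return TrialSet(trials=trials, ratings=ratings), shared
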