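"""Topographic similarity measures and dual-threshold AAHC segmentation.

Atomize-and-agglomerate hierarchical clustering (AAHC) protects clusters by
their global-explained-variance (GEV) contribution: each pass the lowest-GEV
cluster is dissolved and its maps re-assigned, instead of letting short but
well-explained periods be swallowed by agglomeration. The dual-threshold
variant implemented here adds two criteria that make the class count K
automatic: near-duplicate templates (global map dissimilarity below a
threshold, default 0.1) are merged, and reduction continues only while the
total GEV of the clustering stays at or above a threshold (default 0.85).
The returned model is the coarsest clustering still meeting the GEV bound.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gfp import TopographyMatrix

__all__ = [
    "ClusteringConfig",
    "TemplateSet",
    "spatial_correlation",
    "gmd",
    "polarity_dissimilarity",
    "gev",
    "centroid",
    "dtaahc",
    "dtaahc_two_stage",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusteringConfig:
    """Thresholds and modes for DTAAHC.

    th_gev
        Fraction of GFP^2-weighted variance the clustering must keep
        explaining for reduction to continue.
    th_gmd
        Templates closer than this dissimilarity are considered duplicates
        and merged.
    polarity
        'invariant' ignores map sign (spontaneous-EEG convention); 'signed'
        uses the correlation and dissimilarity exactly as defined.
    """

    th_gev: float = 0.85
    th_gmd: float = 0.1
    polarity: str = "invariant"
    max_iterations: int | None = None
    normalize_maps: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.th_gev <= 1:
            raise ValueError("th_gev must lie in (0, 1]")
        if not 0 <= self.th_gmd < 2:
            raise ValueError("th_gmd must lie in [0, 2)")
        if self.polarity not in ("signed", "invariant"):
            raise ValueError("polarity must be 'signed' or 'invariant'")


@dataclass
class TemplateSet:
    """K microstate class topographies with training-fit bookkeeping.

    ``templates`` rows are zero-mean, unit-GFP maps; class l (1-based) is row
    l-1. ``labels`` gives the class of every training map; ``per_class_gev``
    and ``total_gev`` are fractions of the GFP^2-weighted training variance.
    """

    templates: np.ndarray
    labels: np.ndarray
    per_class_gev: np.ndarray
    total_gev: float
    iteration_log: list = field(default_factory=list)
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.templates = np.atleast_2d(np.asarray(self.templates, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        self.per_class_gev = np.asarray(self.per_class_gev, dtype=float)

    @property
    def K(self) -> int:
        return self.templates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]


def spatial_correlation(v: np.ndarray, m: np.ndarray) -> float:
    """Cosine similarity of two topographies (Pearson r once average-referenced)."""
    v = np.asarray(v, dtype=float)
    m = np.asarray(m, dtype=float)
    if v.shape != m.shape:
        raise ValueError("topographies must have equal channel counts")
    nv, nm = np.linalg.norm(v), np.linalg.norm(m)
    if nv == 0 or nm == 0:
        raise ValueError("degenerate (zero-norm) topography")
    return float(np.dot(v, m) / (nv * nm))


def _normalize(u: np.ndarray) -> np.ndarray:
    """Center to zero channel mean and scale to unit GFP."""
    u = np.asarray(u, dtype=float)
    u = u - u.mean()
    g = np.sqrt(np.mean(u**2))
    if g == 0:
        raise ValueError("zero-GFP topography")
    return u / g


def gmd(u: np.ndarray, v: np.ndarray) -> float:
    """Global map dissimilarity: RMS difference of GFP-normalized maps.

    Ranges over [0, 2]: 0 for identical shapes, 2 for an exact polarity
    inversion. Independent of field strength and reference.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("topographies must have equal channel counts")
    return float(np.sqrt(np.mean((_normalize(u) - _normalize(v)) ** 2)))


def polarity_dissimilarity(u: np.ndarray, v: np.ndarray, mode: str = "invariant") -> float:
    """GMD, optionally minimized over a sign flip of one map."""
    if mode == "signed":
        return gmd(u, v)
    if mode == "invariant":
        return min(gmd(u, v), gmd(u, -np.asarray(v, dtype=float)))
    raise ValueError(f"unknown polarity mode {mode!r}")


def gev(
    maps: TopographyMatrix,
    templates: TemplateSet | np.ndarray,
    labels: np.ndarray,
) -> tuple[np.ndarray, float]:
    """GFP^2-weighted explained variance per class and in total.

    GEV_l = sum_t GFP_t^2 C(V_t, M_l)^2 [L_t = l] / sum_t GFP_t^2, summed
    over the maps assigned to class l; the total is the sum over classes.
    Labels are 1-based class ids.
    """
    T = templates.templates if isinstance(templates, TemplateSet) else np.atleast_2d(templates)
    labels = np.asarray(labels, dtype=int)
    K = T.shape[0]
    if labels.min(initial=1) < 1 or labels.max(initial=1) > K:
        raise ValueError("labels reference nonexistent templates")
    w = maps.gfp**2
    denom = w.sum()
    if denom == 0:
        raise ValueError("all maps have zero GFP")
    X = maps.maps
    Xn = X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-300)
    Tn = T / np.maximum(np.linalg.norm(T, axis=1, keepdims=True), 1e-300)
    C = Xn @ Tn.T  # (n_maps, K)
    per_class = np.zeros(K)
    for l in range(1, K + 1):
        sel = labels == l
        per_class[l - 1] = np.sum(w[sel] * C[sel, l - 1] ** 2) / denom
    return per_class, float(per_class.sum())


def centroid(maps: np.ndarray, mode: str = "invariant") -> np.ndarray:
    """Mean topography of a cluster, re-centered to zero channel mean.

    In invariant mode each member is first sign-aligned to the running mean
    (iterated to a fixed point, at most 10 passes) so that antiparallel
    members reinforce instead of cancelling.
    """
    X = np.atleast_2d(np.asarray(maps, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty cluster")
    if mode == "signed":
        c = X.mean(axis=0)
    else:
        signs = np.ones(X.shape[0])
        ref = X[0]
        for _ in range(10):
            new_signs = np.sign(X @ ref)
            new_signs[new_signs == 0] = 1.0
            if np.array_equal(new_signs, signs):
                break
            signs = new_signs
            ref = (X * signs[:, None]).mean(axis=0)
        c = (X * signs[:, None]).mean(axis=0)
    c = c - c.mean()
    if np.linalg.norm(c) == 0:
        raise ValueError("cluster members cancel to the zero vector")
    return c


# ---------------------------------------------------------------------------
# DTAAHC
# ---------------------------------------------------------------------------

class _State:
    """Partition of training maps plus unit-norm centroids."""

    __slots__ = ("clusters", "cents")

    def __init__(self, clusters: list[np.ndarray], cents: np.ndarray):
        self.clusters = clusters
        self.cents = cents

    def copy(self) -> "_State":
        return _State([c.copy() for c in self.clusters], self.cents.copy())

    @property
    def k(self) -> int:
        return len(self.clusters)


def _unit(rows: np.ndarray) -> np.ndarray:
    return rows / np.maximum(np.linalg.norm(rows, axis=-1, keepdims=True), 1e-300)


def _cluster_centroid(Xn: np.ndarray, idx: np.ndarray, invariant: bool) -> np.ndarray:
    c = centroid(Xn[idx], mode="invariant" if invariant else "signed")
    return c / np.linalg.norm(c)


def _state_gev(Xn: np.ndarray, w: np.ndarray, state: _State, invariant: bool) -> tuple[np.ndarray, float]:
    denom = w.sum()
    lab = np.empty(Xn.shape[0], dtype=int)
    for l, idx in enumerate(state.clusters):
        lab[idx] = l
    # squared correlation of each map with its own template only
    c2 = np.einsum("ij,ij->i", Xn, state.cents[lab]) ** 2
    per = np.bincount(lab, weights=w * c2, minlength=state.k) / denom
    return per, float(per.sum())


def _pair_dissim(cents: np.ndarray, invariant: bool) -> np.ndarray:
    # unit-norm rows: gmd^2 = 2(1 - C); invariant uses |C|
    C = cents @ cents.T
    if invariant:
        C = np.abs(C)
    np.clip(C, -1.0, 1.0, out=C)
    return np.sqrt(np.maximum(2.0 * (1.0 - C), 0.0))


def dtaahc(maps: TopographyMatrix, config: ClusteringConfig | None = None) -> TemplateSet:
    """Dual-threshold atomize-and-agglomerate hierarchical clustering.

    Starting from one singleton cluster per GFP-peak map, each pass
    (i) merges the cluster pair with maximum template correlation,
    (ii) atomizes the minimum-GEV cluster, re-assigning its maps to the
    best-correlated survivors, and (iii) merges template pairs whose
    dissimilarity falls below ``th_gmd``. Reduction continues while total
    GEV stays >= ``th_gev``; the last state meeting the threshold is
    returned, so K is selected by the data. Ties break toward the lowest
    cluster index; the algorithm is deterministic and seed-free.
    """
    config = config or ClusteringConfig()
    if maps.n_maps < 2:
        raise ValueError("clustering needs at least 2 maps")
    invariant = config.polarity == "invariant"
    X = maps.maps - maps.maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate zero-GFP map in input")
    Xn = _unit(X) if config.normalize_maps else X.copy()
    w = maps.gfp**2
    if w.sum() == 0:
        raise ValueError("all maps have zero GFP")
    max_iter = config.max_iterations or 10 * maps.n_maps

    state = _State(
        [np.array([i]) for i in range(maps.n_maps)],
        _unit(X),
    )
    per, total = _state_gev(Xn, w, state, invariant)
    log_rows = [(state.k, total)]
    best = state.copy()
    warned = False
    below = False  # set once a reduction drops total GEV under the threshold

    def _merge_pair(state: _State, i: int, j: int) -> _State:
        i, j = min(i, j), max(i, j)
        merged = np.concatenate([state.clusters[i], state.clusters[j]])
        clusters = [c for l, c in enumerate(state.clusters) if l not in (i, j)]
        clusters.insert(i, merged)
        cents = [c for l, c in enumerate(state.cents) if l not in (i, j)]
        cents.insert(i, _cluster_centroid(Xn, merged, invariant))
        return _State(clusters, np.array(cents))

    def _track(state: _State) -> bool:
        """Candidate-state bookkeeping; True once GEV falls below threshold."""
        nonlocal best, below
        _, t = _state_gev(Xn, w, state, invariant)
        if t >= config.th_gev:
            best = state.copy()
            return False
        below = True
        return True

    # Each pass: (i) merge the most-correlated template pair, (ii) recompute
    # centroids, (iii) atomize the minimum-GEV cluster and re-assign its maps,
    # (iv) merge near-duplicate templates. Receivers of atomized maps keep
    # their template until the next pass's recompute step, so dissolving a
    # genuine class costs its full GEV share at once — this sharp drop is
    # what lets the GEV threshold pin the class count. Every sub-step yields
    # a candidate clustering; the returned model is the last candidate whose
    # total GEV still met the threshold, and reduction stops at the first
    # candidate below it.
    dirty: set[int] = set()
    for it in range(max_iter):
        if state.k == 1 or below:
            break

        # (i) merge most-correlated template pair (lowest indices on ties)
        C = state.cents @ state.cents.T
        if invariant:
            C = np.abs(C)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        i, j = min(i, j), max(i, j)
        # re-index the deferred-recompute set around the removed pair
        dirty = {
            (l if l < j else l - 1)
            for l in (dirty - {i, j})
        }
        state = _merge_pair(state, i, j)

        # (ii) recompute centroids of clusters whose membership changed
        for l in dirty:
            state.cents[l] = _cluster_centroid(Xn, state.clusters[l], invariant)
        dirty = set()
        if _track(state) or state.k == 1:
            per, total = _state_gev(Xn, w, state, invariant)
            log_rows.append((state.k, total))
            break

        # (iii) atomize the minimum-GEV cluster; re-assign without updating
        # the receiving templates (deferred to the next pass)
        per, _ = _state_gev(Xn, w, state, invariant)
        drop = int(np.argmin(per))
        freed = state.clusters[drop]
        clusters = [c for l, c in enumerate(state.clusters) if l != drop]
        cents = np.delete(state.cents, drop, axis=0).copy()
        sim = Xn[freed] @ cents.T
        if invariant:
            sim = np.abs(sim)
        target = np.argmax(sim, axis=1)
        for l in np.unique(target):
            clusters[l] = np.concatenate([clusters[l], freed[target == l]])
            dirty.add(int(l))
        state = _State(clusters, cents)
        stop = _track(state)

        # (iv) merge near-duplicate templates (dissimilarity < th_gmd)
        while not stop and state.k > 1:
            D = _pair_dissim(state.cents, invariant)
            np.fill_diagonal(D, np.inf)
            i, j = np.unravel_index(np.argmin(D), D.shape)
            if D[i, j] >= config.th_gmd:
                break
            i, j = min(i, j), max(i, j)
            dirty = {(l if l < j else l - 1) for l in (dirty - {i, j})}
            state = _merge_pair(state, i, j)
            stop = _track(state)

        per, total = _state_gev(Xn, w, state, invariant)
        log_rows.append((state.k, total))
        if stop:
            break
    else:
        warnings.warn(
            "dtaahc hit the iteration cap before the GEV threshold was "
            "crossed; returning the best state reached",
            RuntimeWarning,
        )
        warned = True

    # the selected state must satisfy the duplicate threshold itself
    while best.k > 1:
        D = _pair_dissim(best.cents, invariant)
        np.fill_diagonal(D, np.inf)
        i, j = np.unravel_index(np.argmin(D), D.shape)
        if D[i, j] >= config.th_gmd:
            break
        best = _merge_pair(best, i, j)

    if best.k == 1:
        _, t1 = _state_gev(Xn, w, best, invariant)
        if t1 < config.th_gev and not warned:
            warnings.warn(
                "only the 1-cluster solution was reachable; its GEV is below "
                "the threshold",
                RuntimeWarning,
            )

    per, total = _state_gev(Xn, w, best, invariant)
    # order classes by descending GEV so class 1 is the dominant microstate
    order = np.argsort(-per)
    clusters = [best.clusters[l] for l in order]
    cents = best.cents[order]
    per = per[order]
    labels = np.zeros(maps.n_maps, dtype=int)
    for l, idx in enumerate(clusters, start=1):
        labels[idx] = l
    templates = np.array([_normalize(c) for c in cents])
    return TemplateSet(
        templates=templates,
        labels=labels,
        per_class_gev=per,
        total_gev=total,
        iteration_log=log_rows,
        channel_names=maps.channel_names,
    )


def dtaahc_two_stage(
    per_subject_maps: list[TopographyMatrix], config: ClusteringConfig | None = None
) -> TemplateSet:
    """Per-subject clustering followed by clustering of subject templates.

    Each subject's peak maps are clustered separately; the resulting subject
    templates (weighted by the GFP-share they explain) are then pooled and
    clustered once more. An alternative to pooling all maps in one pass when
    inter-subject amplitude differences would let one subject dominate.
    """
    config = config or ClusteringConfig()
    rows, weights = [], []
    for maps in per_subject_maps:
        ts = dtaahc(maps, config)
        rows.append(ts.templates)
        # weight subject templates by the GFP mass they account for
        w = np.sqrt(np.bincount(ts.labels - 1, weights=maps.gfp**2, minlength=ts.K))
        weights.append(w)
    pooled = TopographyMatrix(
        maps=np.vstack(rows),
        gfp=np.concatenate(weights),
        origin=pd.DataFrame(
            [
                {"recording_id": f"subject{s}", "sample": l}
                for s, r in enumerate(rows)
                for l in range(len(r))
            ]
        ),
        channel_names=per_subject_maps[0].channel_names,
    )
    return dtaahc(pooled, config)
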