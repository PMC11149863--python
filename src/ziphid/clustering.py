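"""Graph-based unsupervised identification of click types.

Pass 1 clusters the detections inside each 5-minute bin: truncated, normalized
spectra are compared pairwise (Pearson-correlation similarity on [0, 1]), weak
edges are pruned at a percentile threshold, and the Chinese Whispers label
propagation algorithm partitions the resulting network. Among several seeded
runs, the partition with the highest average normalized mutual information
(NMI) against the others is kept. Pass 2 applies the same machinery to the
bin-level cluster summaries (mean spectrum + mean envelope + modal-ICI
similarity) to group them into signal types for training-set construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import normalized_mutual_info_score

from .detector import ClickDetection
from .features import ClusterSummary, cluster_summary, norm01

__all__ = [
    "ClusterConfig",
    "ClickCluster",
    "ChineseWhispers",
    "similarity_matrix",
    "prune_edges",
    "chinese_whispers",
    "select_partition",
    "nmi",
    "cluster_bin",
    "cluster_types_across_bins",
]


@dataclass
class ClusterConfig:
    """Settings for within-bin (pass 1) and across-bin (pass 2) clustering.

    ``prune_threshold`` is a pruning *level* (percentile of off-diagonal edge
    weights) by default; ``prune_mode="absolute"`` interprets it as a weight
    cutoff instead. ``min_cluster`` is 10 in the generalized pipeline and 50
    in the moderate-filter first pass (with pruning at 95).
    """

    bin_length: float = 300.0
    prune_threshold: float = 80.0
    prune_mode: str = "percentile"
    max_iterations: int = 25
    max_network: int = 40_000
    min_cluster: int = 10
    n_partitions: int = 5
    spectrum_band: tuple[float, float] = (10.0, 90.0)
    min_bin_clusters_pass2: int = 5
    use_envelope_pass2: bool = True
    #: pass-2 pruning is per-node so types of different internal tightness
    #: all keep their strongest edges
    prune_mode_pass2: str = "row_percentile"
    #: pass-1 similarity uses spectra only unless these are switched on
    use_envelope_pass1: bool = False
    use_ici_pass1: bool = False
    #: e-folding scale (s) of the modal-ICI distance-to-similarity transform
    ici_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.prune_mode == "percentile" and not (0 <= self.prune_threshold <= 100):
            raise ValueError("percentile prune_threshold must be within [0, 100]")
        if self.min_cluster < 2:
            raise ValueError("min_cluster must be >= 2")


@dataclass
class ClickCluster:
    """A cluster of detections within one bin.

    ``member_indices`` index into the list of detections handed to
    :func:`cluster_bin`. ``pseudo`` marks the no-clustering case: bins with
    fewer clicks than ``min_cluster`` forward a single pseudo-cluster of all
    clicks so their averaged features can still be classified.
    """

    bin_id: int
    member_indices: np.ndarray
    summary: ClusterSummary
    pseudo: bool = False

    @property
    def n_clicks(self) -> int:
        return int(self.member_indices.size)


def _corr_similarity(rows: np.ndarray) -> np.ndarray:
    """Pearson-correlation similarity clipped to [0, 1]; constant rows get 0
    similarity to everything but themselves."""
    rows = np.asarray(rows, dtype=float)
    sd = rows.std(axis=1)
    safe = rows.copy()
    degenerate = sd == 0
    if degenerate.any():
        # give constant rows nonzero variance so corrcoef is finite; zero after
        safe[degenerate, 0] += 1.0
    r = np.corrcoef(safe)
    r = np.clip(r, 0.0, 1.0)
    if degenerate.any():
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def _ici_similarity(modal_icis: np.ndarray, scale: float) -> np.ndarray:
    """exp(-d / scale) of pairwise Euclidean modal-ICI distances; undefined
    (NaN) modal ICIs are maximally dissimilar to everything else."""
    icis = np.asarray(modal_icis, dtype=float)
    d = np.abs(icis[:, None] - icis[None, :])
    sim = np.exp(-d / scale)
    bad = np.isnan(icis)
    sim[bad, :] = 0.0
    sim[:, bad] = 0.0
    both = np.outer(bad, bad)
    sim[both] = 1.0  # two undefined ICIs carry no evidence either way
    np.fill_diagonal(sim, 1.0)
    return sim


def similarity_matrix(
    spectra: np.ndarray | None = None,
    envelopes: np.ndarray | None = None,
    modal_icis: np.ndarray | None = None,
    config: ClusterConfig | None = None,
) -> np.ndarray:
    """Symmetric [0, 1] edge-weight matrix with unit diagonal.

    Spectral and envelope similarity are Pearson correlation clipped to
    [0, 1] on the (already truncated and normalized) rows; modal-ICI
    similarity is ``exp(-d/scale)`` of the Euclidean distance. When several
    feature families are supplied their similarities are combined by
    arithmetic mean.
    """
    config = config or ClusterConfig()
    sizes = [np.atleast_2d(f).shape[0] for f in (spectra, envelopes) if f is not None]
    if modal_icis is not None:
        sizes.append(np.atleast_1d(modal_icis).size)
    if not sizes:
        raise ValueError("at least one feature family is required")
    if min(sizes) < 2:
        raise ValueError("similarity requires at least 2 items")
    parts = []
    if spectra is not None:
        parts.append(_corr_similarity(np.atleast_2d(spectra)))
    if envelopes is not None:
        parts.append(_corr_similarity(np.atleast_2d(envelopes)))
    if modal_icis is not None:
        parts.append(_ici_similarity(modal_icis, config.ici_scale))
    n = parts[0].shape[0]
    if any(p.shape[0] != n for p in parts):
        raise ValueError("feature families disagree on the number of items")
    sim = np.mean(parts, axis=0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def prune_edges(
    weights: np.ndarray,
    prune_threshold: float,
    mode: str = "percentile",
) -> nx.Graph:
    """Remove weak edges and return the pruned weighted graph.

    In ``"percentile"`` mode the cutoff is the ``prune_threshold``-th
    percentile of all off-diagonal weights; in ``"row_percentile"`` mode each
    node computes its own percentile cutoff and an edge survives if it clears
    the cutoff of either endpoint (a kNN-style construction that cannot
    isolate nodes, used for the across-bin pass where signal types of
    different internal tightness coexist); in ``"absolute"`` mode the
    threshold is the weight cutoff itself. Edges at or above the cutoff are
    retained.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    if mode == "percentile":
        off = w[~np.eye(n, dtype=bool)]
        cutoff = np.percentile(off, prune_threshold) if off.size else 0.0
        keep = vals >= cutoff
    elif mode == "row_percentile":
        mask = ~np.eye(n, dtype=bool)
        rows = np.where(mask, w, np.nan)
        row_cut = np.nanpercentile(rows, prune_threshold, axis=1)
        keep = (vals >= row_cut[iu]) | (vals >= row_cut[ju])
    elif mode == "absolute":
        cutoff = prune_threshold if prune_threshold <= 1.0 else prune_threshold / 100.0
        keep = vals >= cutoff
    else:
        raise ValueError(f"unknown prune mode {mode!r}")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_weighted_edges_from(zip(iu[keep].tolist(), ju[keep].tolist(), vals[keep].tolist()))
    return g


def _cw_arrays(graph: nx.Graph) -> tuple[list, list[np.ndarray], list[np.ndarray]]:
    nodes = list(graph.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    nbrs, wts = [], []
    for u in nodes:
        idx, ww = [], []
        for v, data in graph[u].items():
            idx.append(index[v])
            ww.append(data.get("weight", 1.0))
        nbrs.append(np.asarray(idx, dtype=np.intp))
        wts.append(np.asarray(ww, dtype=float))
    return nodes, nbrs, wts


def _cw_core(
    nbrs: list[np.ndarray],
    wts: list[np.ndarray],
    max_iterations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Label propagation: each node adopts the neighbor label with the largest
    summed edge weight; ties break to the lowest label id; visit order is
    re-randomized from the run seed every iteration; stops at convergence."""
    n = len(nbrs)
    labels = np.arange(n, dtype=np.int64)
    for _ in range(max_iterations):
        changed = False
        for i in rng.permutation(n):
            idx = nbrs[i]
            if idx.size == 0:
                continue
            uniq, inv = np.unique(labels[idx], return_inverse=True)
            sums = np.bincount(inv, weights=wts[i])
            best = uniq[int(np.argmax(sums))]  # argmax -> first max -> lowest id
            if best != labels[i]:
                labels[i] = best
                changed = True
        if not changed:
            break
    return labels


def chinese_whispers(graph: nx.Graph, max_iterations: int = 25, seed=0) -> dict:
    """Partition an undirected weighted graph by Chinese Whispers label
    propagation. Isolated nodes keep singleton labels. Returns a mapping
    node -> cluster id (ids compacted to 0..k-1 by first appearance)."""
    nodes, nbrs, wts = _cw_arrays(graph)
    if not nodes:
        return {}
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = _cw_core(nbrs, wts, max_iterations, rng)
    _, compact = np.unique(labels, return_inverse=True)
    return {u: int(c) for u, c in zip(nodes, compact)}


class ChineseWhispers(ClusterMixin, BaseEstimator):
    """Chinese Whispers label-propagation clustering (scikit-learn style).

    Operates on a precomputed affinity matrix: entries are edge weights and
    zeros mean "no edge". ``fit`` sets ``labels_`` (cluster ids, compacted)
    and ``n_clusters_``.

    Parameters
    ----------
    max_iterations : int
        Iteration cap; propagation stops earlier on convergence.
    prune_threshold : float or None
        If given, the affinity matrix is pruned first (percentile mode).
    random_state : int
        Seed for the per-iteration node visit order.
    """

    def __init__(self, max_iterations: int = 25, prune_threshold: float | None = None, random_state: int = 0):
        self.max_iterations = max_iterations
        self.prune_threshold = prune_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("expected a square affinity matrix")
        if self.prune_threshold is not None:
            graph = prune_edges(X, self.prune_threshold)
        else:
            graph = nx.from_numpy_array(np.where(np.eye(X.shape[0], dtype=bool), 0.0, X))
        part = chinese_whispers(graph, self.max_iterations, self.random_state)
        self.labels_ = np.array([part[i] for i in range(X.shape[0])], dtype=int)
        self.n_clusters_ = int(self.labels_.max()) + 1 if self.labels_.size else 0
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _aligned_labels(a: dict, b: dict) -> tuple[np.ndarray, np.ndarray]:
    if set(a.keys()) != set(b.keys()):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(a.keys(), key=repr)
    return (
        np.array([a[u] for u in nodes]),
        np.array([b[u] for u in nodes]),
    )


def nmi(a: dict, b: dict) -> float:
    """Normalized mutual information between two partitions of one node set,
    normalized by the arithmetic mean of the partition entropies.

    Degenerate conventions: if both partitions have zero entropy (each is a
    single cluster) they are identical as partitions and the score is 1; if
    exactly one has zero entropy the score is 0.
    """
    la, lb = _aligned_labels(a, b)
    single_a = np.unique(la).size <= 1
    single_b = np.unique(lb).size <= 1
    if single_a and single_b:
        return 1.0
    if single_a or single_b:
        return 0.0
    return float(normalized_mutual_info_score(la, lb, average_method="arithmetic"))


def consensus_index(partitions: list[dict]) -> int:
    """Index of the partition with the highest mean NMI against all the
    others (ties resolve to the earliest)."""
    k = len(partitions)
    if k == 1:
        return 0
    pair = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair[i, j] = pair[j, i] = nmi(partitions[i], partitions[j])
    return int(np.argmax(pair.sum(axis=1) / (k - 1)))


def select_partition(graph: nx.Graph, config: ClusterConfig | None = None, seed=0) -> dict:
    """Run Chinese Whispers ``n_partitions`` times with distinct seeds and
    return the consensus partition (highest mean NMI against the other runs).
    Deterministic given the seed."""
    config = config or ClusterConfig()
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    seqs = np.random.SeedSequence(seed).spawn(config.n_partitions)
    parts = [
        chinese_whispers(graph, config.max_iterations, np.random.default_rng(s))
        for s in seqs
    ]
    return parts[consensus_index(parts)]


def _band_slice(freqs_khz: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs_khz >= band[0]) & (freqs_khz <= band[1])


def _truncated_norm_spectra(spectra: np.ndarray, freqs_khz: np.ndarray, band) -> np.ndarray:
    mask = _band_slice(freqs_khz, band)
    return np.stack([norm01(row[mask]) for row in np.atleast_2d(spectra)])


def cluster_bin(
    detections: list[ClickDetection],
    config: ClusterConfig | None = None,
    seed=0,
    bin_id: int = 0,
    allow_pseudo: bool = True,
) -> list[ClickCluster]:
    """Cluster the detections of one bin into signal types.

    Bins with fewer than ``min_cluster`` clicks skip clustering: a single
    pseudo-cluster of all clicks is summarized and forwarded (unless
    ``allow_pseudo`` is off, as in the moderate filter's first pass). Bins
    larger than ``max_network`` are subsampled. Clusters below ``min_cluster``
    members are discarded and their clicks left unlabeled.
    """
    config = config or ClusterConfig()
    n = len(detections)
    if n == 0:
        return []
    if n < config.min_cluster:
        if not allow_pseudo:
            return []
        summary = cluster_summary(detections)
        return [ClickCluster(bin_id, np.arange(n), summary, pseudo=True)]

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    indices = np.arange(n)
    if n > config.max_network:
        indices = np.sort(rng.choice(n, size=config.max_network, replace=False))
    subset = [detections[i] for i in indices]

    spectra = np.stack([d.spectrum for d in subset])
    fs = subset[0].sample_rate
    freqs = np.fft.rfftfreq(2 * (spectra.shape[1] - 1), d=1.0 / fs) / 1e3
    norm_spec = _truncated_norm_spectra(spectra, freqs, config.spectrum_band)

    envelopes = modal = None
    if config.use_envelope_pass1 or config.use_ici_pass1:
        from .features import resample_envelope

        if config.use_envelope_pass1:
            envelopes = np.stack([norm01(resample_envelope(d.envelope)) for d in subset])
    sim = similarity_matrix(norm_spec, envelopes, modal, config)
    graph = prune_edges(sim, config.prune_threshold, config.prune_mode)
    partition = select_partition(graph, config, rng.integers(0, 2**31 - 1))

    labels = np.array([partition[i] for i in range(len(subset))])
    clusters = []
    for lbl in np.unique(labels):
        members = indices[labels == lbl]
        if members.size < config.min_cluster:
            continue
        summary = cluster_summary([detections[i] for i in members])
        clusters.append(ClickCluster(bin_id, members, summary))
    clusters.sort(key=lambda c: -c.n_clicks)
    return clusters


def cluster_types_across_bins(
    bin_clusters: list[ClickCluster],
    config: ClusterConfig | None = None,
    seed=0,
) -> list[list[int]]:
    """Group bin-level clusters into dominant signal types (pass 2).

    Similarity combines mean spectra, mean envelopes (omitted when
    ``use_envelope_pass2`` is off, the variant used for the long-duration BWG
    type) and modal-ICI similarity. Groups with fewer than
    ``min_bin_clusters_pass2`` members are discarded. Returns lists of indices
    into ``bin_clusters``.
    """
    config = config or ClusterConfig()
    if len(bin_clusters) < 2:
        raise ValueError("pass-2 clustering requires at least 2 bin-level clusters")
    freqs = bin_clusters[0].summary.freqs_khz
    spectra = np.stack([c.summary.mean_spectrum for c in bin_clusters])
    if freqs is not None:
        spectra = _truncated_norm_spectra(spectra, freqs, config.spectrum_band)
    envelopes = None
    if config.use_envelope_pass2:
        envelopes = np.stack([c.summary.mean_envelope for c in bin_clusters])
    modal = np.array([c.summary.modal_ici for c in bin_clusters])
    sim = similarity_matrix(spectra, envelopes, modal, config)
    graph = prune_edges(sim, config.prune_threshold, config.prune_mode_pass2)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    partition = select_partition(graph, config, rng.integers(0, 2**31 - 1))
    labels = np.array([partition[i] for i in range(len(bin_clusters))])
    groups = []
    for lbl in np.unique(labels):
        members = np.flatnonzero(labels == lbl)
        if members.size >= config.min_bin_clusters_pass2:
            groups.append(members.tolist())
    groups.sort(key=len, reverse=True)
    return groups
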