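"""Spatial graph construction: KNN adjacency and random-walk PPMI.

Two views of one slice's spatial structure feed the dual-branch encoder:

* a binary k-nearest-neighbour adjacency ``A`` over spot coordinates,
  capturing local neighbourhoods (Visium-style lattices are well served
  by k=6);
* a positive pointwise mutual information matrix ``P`` computed from
  node co-occurrence under truncated random walks on ``A``, which
  up-weights pairs visited together far more often than chance and so
  encodes longer-range structure.

Both are symmetrically normalized with self-loops,
``D^{-1/2} (G + I) D^{-1/2}``, before graph convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import mmwrite
from scipy.sparse import csr_matrix
from scipy.spatial.distance import cdist


@dataclass
class WalkConfig:
    """Truncated random-walk settings for the co-occurrence estimate.

    `expected` mode computes the exact expectation — the average of the
    first `walk_length` powers of the row-normalized adjacency — and is
    the deterministic default; `sampled` mode simulates walks.
    """

    walk_length: int = 3
    mode: str = "expected"
    walks_per_node: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.walk_length < 1:
            raise ValueError("walk_length must be >= 1")
        if self.mode not in ("expected", "sampled"):
            raise ValueError(f"unknown walk mode {self.mode!r}")
        if self.mode == "sampled" and self.walks_per_node < 1:
            raise ValueError("walks_per_node must be >= 1 in sampled mode")


@dataclass
class SpatialGraph:
    """KNN and PPMI graphs of one slice plus their propagation matrices."""

    knn_adjacency: np.ndarray
    ppmi: np.ndarray | None
    knn_norm: np.ndarray
    ppmi_norm: np.ndarray | None
    k: int
    walk_cfg: WalkConfig = field(default_factory=WalkConfig)

    @property
    def n_spots(self) -> int:
        return self.knn_adjacency.shape[0]


def build_knn_adjacency(coords: np.ndarray, k: int) -> np.ndarray:
    """Binary symmetric k-NN adjacency over Euclidean spot distances.

    Each spot is linked to its k nearest neighbours (self excluded,
    distance ties broken toward the lower spot index) and the directed
    relation is symmetrized by logical OR.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be N x 2")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots")
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, N-1]; got k={k}, N={n}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords contain non-finite values")

    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)  # exclude self
    # stable sort: equal distances resolve to the lower column index
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    a = np.zeros((n, n), dtype=float)
    rows = np.repeat(np.arange(n), k)
    a[rows, nn.ravel()] = 1.0
    a = np.maximum(a, a.T)  # OR-symmetrize
    np.fill_diagonal(a, 0.0)
    return a


def cooccurrence(adjacency: np.ndarray, cfg: WalkConfig | None = None) -> np.ndarray:
    """Node co-occurrence frequencies under truncated random walks.

    Expected mode returns ``(1/T) * sum_{t=1..T} Pi^t`` with ``Pi`` the
    row-normalized adjacency: entry (i, j) is the probability that a walk
    started at i sits at j at a uniformly chosen step in 1..T, so rows are
    probability vectors.  Sampled mode estimates the same quantity from
    `walks_per_node` seeded walks per start node.
    """
    cfg = cfg or WalkConfig()
    a = np.asarray(adjacency, dtype=float)
    deg = a.sum(axis=1)
    if np.any(deg == 0):
        bad = np.flatnonzero(deg == 0)
        raise ValueError(
            f"isolated node(s) {bad[:10].tolist()} have no neighbours; increase k"
        )
    pi = a / deg[:, None]
    n = a.shape[0]
    if cfg.mode == "expected":
        f = np.zeros_like(pi)
        power = np.eye(n)
        for _ in range(cfg.walk_length):
            power = power @ pi
            f += power
        return f / cfg.walk_length

    rng = np.random.default_rng(cfg.seed)
    # flat neighbour lists so all walkers advance in one vectorized step
    nbrs = [np.flatnonzero(a[i] > 0) for i in range(n)]
    flat = np.concatenate(nbrs)
    offsets = np.concatenate([[0], np.cumsum([len(x) for x in nbrs])[:-1]])
    degs = np.array([len(x) for x in nbrs])
    starts = np.repeat(np.arange(n), cfg.walks_per_node)
    cur = starts.copy()
    counts = np.zeros((n, n), dtype=float)
    for _ in range(cfg.walk_length):
        u = rng.random(cur.size)
        cur = flat[offsets[cur] + (u * degs[cur]).astype(np.intp)]
        np.add.at(counts, (starts, cur), 1.0)
    return counts / (cfg.walks_per_node * cfg.walk_length)


def compute_ppmi(freq: np.ndarray) -> np.ndarray:
    """Positive pointwise mutual information of a co-occurrence matrix.

    The frequency matrix is symmetrized, turned into a joint distribution,
    and each cell becomes ``max(0, ln P(i,j) / (P(i) P(j)))`` with zeros
    where the joint is zero (no -inf) and a zeroed diagonal (self-affinity
    re-enters through the +I of normalization).
    """
    f = np.asarray(freq, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    total = f.sum()
    if total <= 0:
        raise ValueError("co-occurrence matrix is all zero")
    f = (f + f.T) / 2.0  # undirected tissue graph
    joint = f / f.sum()
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)
    denom = np.outer(pi, pj)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(np.where(joint > 0, joint, 1.0) / np.where(denom > 0, denom, 1.0))
    ppmi = np.where(joint > 0, np.maximum(pmi, 0.0), 0.0)
    np.fill_diagonal(ppmi, 0.0)
    return ppmi


def normalize_adjacency(graph_matrix: np.ndarray) -> np.ndarray:
    """Symmetric self-loop normalization ``D^{-1/2} (G + I) D^{-1/2}``."""
    g = np.asarray(graph_matrix, dtype=float)
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("graph matrix must be square")
    if np.any(g < 0):
        raise ValueError("graph weights must be non-negative")
    g_tilde = g + np.eye(g.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(g_tilde.sum(axis=1))
    return g_tilde * np.outer(d_inv_sqrt, d_inv_sqrt)


def build_spatial_graph(
    coords: np.ndarray,
    k: int = 6,
    walk_cfg: WalkConfig | None = None,
    include_ppmi: bool = True,
) -> SpatialGraph:
    """KNN + PPMI graphs and their propagation matrices for one slice.

    `include_ppmi=False` skips the random-walk step (KNN-only ablation).
    """
    walk_cfg = walk_cfg or WalkConfig()
    a = build_knn_adjacency(coords, k)
    p = compute_ppmi(cooccurrence(a, walk_cfg)) if include_ppmi else None
    return SpatialGraph(
        knn_adjacency=a,
        ppmi=p,
        knn_norm=normalize_adjacency(a),
        ppmi_norm=normalize_adjacency(p) if p is not None else None,
        k=k,
        walk_cfg=walk_cfg,
    )


def export_graph(graph: SpatialGraph, out_dir, spot_ids=None) -> None:
    """Write A and P as Matrix Market files plus a spot-id index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mmwrite(out_dir / "knn_adjacency.mtx", csr_matrix(graph.knn_adjacency))
    if graph.ppmi is not None:
        mmwrite(out_dir / "ppmi.mtx", csr_matrix(graph.ppmi))
    if spot_ids is not None:
        (out_dir / "spots.txt").write_text("\n".join(map(str, spot_ids)) + "\n")
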