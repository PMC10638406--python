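"""Person-to-Person Network (PPN) construction.

A PPN is a sample-by-sample similarity matrix: square over the training
set, or rectangular test-by-train when scoring unseen samples.  Node-level
PPNs are built directly from feature values (scaled-exponential affinity,
Gaussian kernel, or Spearman correlation between samples); edge-level PPNs
convert pairwise edge-difference distances between individual networks to
similarities (adaptive Gaussian by default; the scaled-exponential
affinity and a negative-distance option are also available).

The affinity kernel follows the scaled exponential similarity construction
used by similarity network fusion: for samples x, y at distance d,

    W(x, y) = exp(-d^2 / (2 * (sigma * eps_xy)^2))

with eps_xy = (mean distance of x to its K nearest neighbours
               + mean distance of y to its K nearest neighbours + d) / 3.
K enters only through this local bandwidth.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .io import FeatureMatrix, ValidationError
from .networks import IndividualNetwork


@dataclasses.dataclass
class PPNMatrix:
    """Similarity matrix between samples (square train or test-by-train)."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    kind: str = "node"  # node | edge | combined | fused

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError("PPN shape does not match ID lists")
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite PPN entry")
        if self.square and not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("square PPN not symmetric")

    @property
    def square(self) -> bool:
        return self.row_ids == self.col_ids

    def reindex(self, row_ids=None, col_ids=None) -> "PPNMatrix":
        """Reorder rows/columns by sample ID."""
        rid = self.row_ids if row_ids is None else list(row_ids)
        cid = self.col_ids if col_ids is None else list(col_ids)
        ri = [self.row_ids.index(r) for r in rid]
        ci = [self.col_ids.index(c) for c in cid]
        return PPNMatrix(rid, cid, self.values[np.ix_(ri, ci)], self.kind)


# ---------------------------------------------------------------------------
# scaled exponential affinity kernel
# ---------------------------------------------------------------------------

def _knn_mean_distance(dist: np.ndarray, K: int, exclude_self: bool) -> np.ndarray:
    """Per row, the mean distance to the K nearest (off-diagonal) entries."""
    d = np.sort(dist, axis=1)
    if exclude_self:
        d = d[:, 1:]  # drop the zero self-distance
    if K > d.shape[1]:
        raise ValidationError(f"K={K} exceeds available neighbours ({d.shape[1]})")
    return d[:, :K].mean(axis=1)


def affinity_from_distances(
    dist: np.ndarray,
    K: int = 20,
    sigma: float = 0.05,
    row_knn: np.ndarray | None = None,
    col_knn: np.ndarray | None = None,
) -> np.ndarray:
    """Scaled exponential similarity from a (possibly rectangular) distance matrix.

    ``row_knn``/``col_knn`` are per-sample mean K-nearest-neighbour
    distances; when omitted the matrix must be square and they are derived
    from it (excluding the self-distance).
    """
    dist = np.asarray(dist, dtype=float)
    if row_knn is None or col_knn is None:
        if dist.shape[0] != dist.shape[1]:
            raise ValidationError("rectangular affinity needs explicit bandwidths")
        knn = _knn_mean_distance(dist, K, exclude_self=True)
        row_knn = col_knn = knn
    eps = (row_knn[:, None] + col_knn[None, :] + dist) / 3.0
    eps = np.maximum(eps, np.finfo(float).eps)
    return np.exp(-(dist ** 2) / (2.0 * (sigma * eps) ** 2))


def affinity_ppn(
    m: FeatureMatrix,
    m_test: FeatureMatrix | None = None,
    K: int = 20,
    sigma: float = 0.05,
) -> PPNMatrix:
    """Euclidean-distance affinity PPN (square train or rectangular test-by-train)."""
    if K >= m.n_samples:
        raise ValidationError(f"K={K} must be < number of train samples ({m.n_samples})")
    train_vals = m.values.to_numpy()
    d_train = cdist(train_vals, train_vals)
    if m_test is None:
        w = affinity_from_distances(d_train, K=K, sigma=sigma)
        return PPNMatrix(m.sample_ids, m.sample_ids, w, kind="node")
    test_vals = m_test.values.loc[:, m.values.columns].to_numpy()
    d_tt = cdist(test_vals, train_vals)
    train_knn = _knn_mean_distance(d_train, K, exclude_self=True)
    test_knn = _knn_mean_distance(d_tt, K, exclude_self=False)
    w = affinity_from_distances(d_tt, K=K, sigma=sigma, row_knn=test_knn, col_knn=train_knn)
    return PPNMatrix(m_test.sample_ids, m.sample_ids, w, kind="node")


def gaussian_ppn(
    m: FeatureMatrix,
    m_test: FeatureMatrix | None = None,
    sigma: float | str = 1000.0,
) -> PPNMatrix:
    """Gaussian kernel k(x, y) = exp(-||v_x - v_y||^2 / sigma^2).

    The bandwidth is tied to the measurement scale of the data;
    ``sigma="auto"`` sets sigma^2 to the mean squared pairwise train
    distance (root-mean-square heuristic).
    """
    a = m.values.to_numpy()
    if sigma == "auto":
        sigma2 = cdist(a, a, metric="sqeuclidean").mean()
        if sigma2 <= 0:
            raise ValidationError("cannot auto-scale sigma: all samples identical")
    else:
        if sigma <= 0:
            raise ValidationError("sigma must be positive")
        sigma2 = float(sigma) ** 2
    if m_test is None:
        d2 = cdist(a, a, metric="sqeuclidean")
        return PPNMatrix(m.sample_ids, m.sample_ids, np.exp(-d2 / sigma2), "node")
    b = m_test.values.loc[:, m.values.columns].to_numpy()
    d2 = cdist(b, a, metric="sqeuclidean")
    return PPNMatrix(m_test.sample_ids, m.sample_ids, np.exp(-d2 / sigma2), "node")


def _rank_rows(vals: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    if vals.shape[1] < 3:
        raise ValidationError("Spearman PPN needs >= 3 features")
    const = vals.std(axis=1) == 0
    if const.any():
        bad = [ids[k] for k in np.where(const)[0][:5]]
        raise ValidationError(f"constant feature vector for sample(s) {bad}")
    return np.vstack([rankdata(row) for row in vals])


def spearman_ppn(m: FeatureMatrix, m_test: FeatureMatrix | None = None) -> PPNMatrix:
    """Spearman rank correlation between each pair of samples' feature vectors."""
    ra = _rank_rows(m.values.to_numpy(), m.sample_ids)
    if m_test is None:
        w = np.corrcoef(ra)
        np.fill_diagonal(w, 1.0)
        w = (w + w.T) / 2.0
        return PPNMatrix(m.sample_ids, m.sample_ids, w, "node")
    rb = _rank_rows(m_test.values.loc[:, m.values.columns].to_numpy(), m_test.sample_ids)
    za = (ra - ra.mean(axis=1, keepdims=True)) / ra.std(axis=1, keepdims=True)
    zb = (rb - rb.mean(axis=1, keepdims=True)) / rb.std(axis=1, keepdims=True)
    w = zb @ za.T / ra.shape[1]
    return PPNMatrix(m_test.sample_ids, m.sample_ids, w, "node")


# ---------------------------------------------------------------------------
# edge-level PPNs
# ---------------------------------------------------------------------------

def edge_difference_distance(a: IndividualNetwork, b: IndividualNetwork) -> float:
    """Frobenius norm of the difference of the full symmetric adjacencies.

    Each undirected edge appears twice in the adjacency, hence
    sqrt(2 * sum of squared weight differences).
    """
    if a.edge_set != b.edge_set:
        raise ValidationError("edge sets differ between networks")
    diff = a.weights - b.weights
    return float(np.sqrt(2.0 * np.dot(diff, diff)))


def _weight_matrix(nets: Sequence[IndividualNetwork]) -> np.ndarray:
    ref = nets[0].edge_set
    for net in nets[1:]:
        if net.edge_set != ref:
            raise ValidationError("all networks must share one edge set")
    return np.vstack([net.weights for net in nets])


def edge_ppn(
    train_nets: Sequence[IndividualNetwork],
    test_nets: Sequence[IndividualNetwork] | None = None,
    K: int = 20,
    sigma: float = 0.05,
    similarity: str = "gaussian",
) -> PPNMatrix:
    """Similarity between individuals from edge-difference distances.

    ``similarity`` chooses the distance-to-similarity conversion:

    * ``"gaussian"`` (default): exp(-d^2 / s^2) with the bandwidth s^2 set
      to the mean squared train distance.  Scale-adaptive and
      well-conditioned even when distances concentrate, as they do for
      high-dimensional edge-weight vectors.
    * ``"affinity"``: the scaled exponential kernel of the node level
      (local K-neighbour bandwidth, parameters ``K`` and ``sigma``).
    * ``"neg_distance"``: -d, an indefinite similarity left to the
      classifier's PSD repair (cannot be cosine-normalized).

    ``test_nets`` may be a list of (test network, refreshed train
    networks) pairs, as returned by the LIONESS test protocol, in which
    case each test row is computed against its own temporary panel.
    """
    if similarity not in ("gaussian", "affinity", "neg_distance"):
        raise ValidationError(f"unknown edge similarity {similarity!r}")
    w_train = _weight_matrix(list(train_nets))
    train_ids = [n.sample_id for n in train_nets]
    d_train = np.sqrt(2.0 * cdist(w_train, w_train, metric="sqeuclidean"))
    s2 = (d_train ** 2).mean() or 1.0  # train-derived bandwidth, reused on test
    if test_nets is None:
        if similarity == "gaussian":
            w = np.exp(-(d_train ** 2) / s2)
        elif similarity == "neg_distance":
            w = -d_train
        else:
            w = affinity_from_distances(d_train, K=K, sigma=sigma)
        return PPNMatrix(train_ids, train_ids, (w + w.T) / 2.0, kind="edge")

    train_knn = _knn_mean_distance(d_train, K, exclude_self=True)
    rows, test_ids = [], []
    for item in test_nets:
        if isinstance(item, tuple):
            net, panel = item
            w_panel = _weight_matrix(list(panel))
            if [p.sample_id for p in panel] != train_ids:
                raise ValidationError("refreshed panel does not match train IDs")
        else:
            net, w_panel = item, w_train
        if net.edge_set != train_nets[0].edge_set:
            raise ValidationError("edge sets differ between networks")
        d = np.sqrt(2.0 * ((w_panel - net.weights) ** 2).sum(axis=1))
        rows.append(d)
        test_ids.append(net.sample_id)
    d_tt = np.vstack(rows)
    if similarity == "gaussian":
        w = np.exp(-(d_tt ** 2) / s2)
    elif similarity == "neg_distance":
        w = -d_tt
    else:
        test_knn = _knn_mean_distance(d_tt, K, exclude_self=False)
        w = affinity_from_distances(
            d_tt, K=K, sigma=sigma, row_knn=test_knn, col_knn=train_knn
        )
    return PPNMatrix(test_ids, train_ids, w, kind="edge")


# ---------------------------------------------------------------------------
# combination and normalization
# ---------------------------------------------------------------------------

def combine_node_edge(ppn_n: PPNMatrix, ppn_e: PPNMatrix) -> PPNMatrix:
    """Elementwise mean of a node-level and an edge-level PPN."""
    if ppn_n.row_ids != ppn_e.row_ids or ppn_n.col_ids != ppn_e.col_ids:
        raise ValidationError("PPN sample IDs differ; align before combining")
    return PPNMatrix(
        ppn_n.row_ids, ppn_n.col_ids, (ppn_n.values + ppn_e.values) / 2.0, "combined"
    )


def normalize_ppn(
    ppn: PPNMatrix,
    self_sim_rows: np.ndarray | None = None,
    self_sim_cols: np.ndarray | None = None,
) -> PPNMatrix:
    """Cosine-style normalization PPN(x,y) / sqrt(PPN(x,x) * PPN(y,y)).

    Square PPNs use their diagonal; rectangular PPNs need the row samples'
    self-similarities (columns default to 1 when the column self-similarity
    is baked into a previously normalized train PPN).
    """
    if ppn.square:
        diag = np.diag(ppn.values).copy()
    else:
        if self_sim_rows is None:
            raise ValidationError("rectangular PPN needs row self-similarities")
        diag = None
    if ppn.square:
        if (diag <= 0).any():
            raise ValidationError("nonpositive self-similarity on the diagonal")
        scale = np.sqrt(diag)
        vals = ppn.values / scale[:, None] / scale[None, :]
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 1.0)
    else:
        rows = np.asarray(self_sim_rows, dtype=float)
        cols = (
            np.ones(len(ppn.col_ids))
            if self_sim_cols is None
            else np.asarray(self_sim_cols, dtype=float)
        )
        if (rows <= 0).any() or (cols <= 0).any():
            raise ValidationError("nonpositive self-similarity")
        vals = ppn.values / np.sqrt(rows)[:, None] / np.sqrt(cols)[None, :]
    return PPNMatrix(ppn.row_ids, ppn.col_ids, vals, ppn.kind)
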