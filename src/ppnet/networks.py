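"""Individual (per-sample) network construction.

Two constructions are provided.  *Node Product* sets the weight of edge
(i, j) in sample x's network to the product of the sample's min-max-scaled
values of features i and j.  *LIONESS* linearly interpolates an aggregate
co-expression model: with ``e_all`` the edge weight fitted on all N samples
and ``e_wo`` the weight fitted on all samples but x,

    e_x = N * (e_all - e_wo) + e_wo

which, for any aggregate that is a per-sample mean of a sample-level edge
statistic, recovers that sample's own statistic exactly.  The default
aggregate is the Pearson correlation between feature columns.

Edge weights of a set of individual networks are brought to [0, 1] by one
global affine map (shared min/max across all networks) so the ordering of
weights is preserved between individuals.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .io import FeatureMatrix, ValidationError


class EdgeSet:
    """Ordered list of unordered feature pairs (a, b) with a < b."""

    def __init__(self, pairs: Sequence[tuple[str, str]], nodes: Sequence[str] | None = None):
        canon = []
        seen = set()
        for a, b in pairs:
            if a == b:
                raise ValidationError(f"self-pair {a!r}")
            pair = (a, b) if a < b else (b, a)
            if pair in seen:
                raise ValidationError(f"duplicate edge {pair}")
            seen.add(pair)
            canon.append(pair)
        self.pairs: list[tuple[str, str]] = canon
        if nodes is None:
            nodes = sorted({n for p in canon for n in p})
        else:
            nodes = list(nodes)
            missing = [n for p in canon for n in p if n not in set(nodes)]
            if missing:
                raise ValidationError(f"edge endpoints not in node list: {missing[:5]}")
        self.nodes: list[str] = nodes
        self._node_index = {n: k for k, n in enumerate(self.nodes)}

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other) -> bool:
        return isinstance(other, EdgeSet) and self.pairs == other.pairs

    def __iter__(self):
        return iter(self.pairs)

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the edges into the node-ordered adjacency."""
        ii = np.array([self._node_index[a] for a, _ in self.pairs], dtype=int)
        jj = np.array([self._node_index[b] for _, b in self.pairs], dtype=int)
        return ii, jj


@dataclasses.dataclass
class IndividualNetwork:
    """Edge weights of one sample's network over a shared edge set."""

    sample_id: str
    edge_set: EdgeSet
    weights: np.ndarray
    scaled: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.edge_set),):
            raise ValidationError(
                f"{self.sample_id}: {self.weights.shape[0]} weights for "
                f"{len(self.edge_set)} edges"
            )
        if not np.isfinite(self.weights).all():
            raise ValidationError(f"{self.sample_id}: non-finite edge weight")
        if self.scaled and ((self.weights < -1e-12).any() or (self.weights > 1 + 1e-12).any()):
            raise ValidationError(f"{self.sample_id}: scaled weights outside [0, 1]")

    def adjacency(self) -> np.ndarray:
        """Full symmetric adjacency over ``edge_set.nodes``, zero diagonal."""
        p = len(self.edge_set.nodes)
        adj = np.zeros((p, p))
        ii, jj = self.edge_set.indices()
        adj[ii, jj] = self.weights
        adj[jj, ii] = self.weights
        return adj


@dataclasses.dataclass
class AggregateNetwork:
    """Cohort-level symmetric adjacency over a fixed node list."""

    nodes: list[str]
    adjacency: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.shape != (len(self.nodes), len(self.nodes)):
            raise ValidationError("adjacency shape does not match node list")
        if not np.isfinite(a).all():
            raise ValidationError("non-finite adjacency entry")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValidationError("adjacency not symmetric")
        np.fill_diagonal(a, 0.0)
        self.adjacency = a


# ---------------------------------------------------------------------------
# min-max scaling of feature values
# ---------------------------------------------------------------------------

def min_max_scale_features(m: FeatureMatrix):
    """Map every feature column to [0, 1] using its own min and max.

    Returns the scaled matrix and a (min, max) table indexed by feature, to
    be reused on test samples via :func:`apply_min_max`.
    """
    vals = m.values
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    const = hi <= lo
    if const.any():
        names = list(vals.columns[const])[:5]
        raise ValidationError(
            f"constant feature(s) {names}: remove them during node selection"
        )
    scaled = (vals - lo) / (hi - lo)
    table = np.vstack([lo.to_numpy(), hi.to_numpy()]).T
    import pandas as pd

    table = pd.DataFrame(table, index=vals.columns, columns=["min", "max"])
    return FeatureMatrix(scaled, m.modality), table


def apply_min_max(m: FeatureMatrix, table) -> FeatureMatrix:
    """Scale with stored (train) min/max and clip to [0, 1]."""
    missing = [f for f in m.feature_ids if f not in table.index]
    if missing:
        raise ValidationError(f"no scaling statistics for features {missing[:5]}")
    t = table.loc[m.values.columns]
    scaled = (m.values - t["min"]) / (t["max"] - t["min"])
    return FeatureMatrix(scaled.clip(0.0, 1.0), m.modality)


# ---------------------------------------------------------------------------
# Node Product networks
# ---------------------------------------------------------------------------

def node_product_network(sample_id: str, values, edges: EdgeSet) -> IndividualNetwork:
    """Edge weight = product of the two endpoints' scaled values."""
    v = np.asarray([values[n] for n in edges.nodes], dtype=float)
    if (v < -1e-12).any() or (v > 1 + 1e-12).any():
        raise ValidationError(f"{sample_id}: node values must be scaled to [0, 1]")
    ii, jj = edges.indices()
    return IndividualNetwork(sample_id, edges, v[ii] * v[jj], scaled=False)


def node_product_networks(m: FeatureMatrix, edges: EdgeSet) -> list[IndividualNetwork]:
    sub = m.values.loc[:, edges.nodes]
    ii, jj = edges.indices()
    vals = sub.to_numpy()
    if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
        raise ValidationError("node values must be scaled to [0, 1]")
    w = vals[:, ii] * vals[:, jj]
    return [
        IndividualNetwork(sid, edges, w[k], scaled=False)
        for k, sid in enumerate(m.sample_ids)
    ]


# ---------------------------------------------------------------------------
# aggregate model and LIONESS
# ---------------------------------------------------------------------------

def pearson_adjacency(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between feature columns; the default aggregate."""
    sd = values.std(axis=0)
    if (sd == 0).any():
        raise ValidationError("zero-variance feature in aggregate network")
    adj = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(adj, 0.0)
    return adj


AggregateFn = Callable[[np.ndarray], np.ndarray]


def aggregate_network(
    m: FeatureMatrix, edges: EdgeSet, aggregate: AggregateFn = pearson_adjacency
) -> AggregateNetwork:
    """Fit the aggregate co-expression model on all samples of ``m``."""
    if m.n_samples < 3:
        raise ValidationError("aggregate network needs >= 3 samples")
    vals = m.values.loc[:, edges.nodes].to_numpy()
    return AggregateNetwork(list(edges.nodes), aggregate(vals), m.n_samples)


def _edge_vector(adj: np.ndarray, edges: EdgeSet) -> np.ndarray:
    ii, jj = edges.indices()
    return adj[ii, jj]


def lioness_networks(
    train: FeatureMatrix, edges: EdgeSet, aggregate: AggregateFn = pearson_adjacency
) -> list[IndividualNetwork]:
    """One network per train sample via the linear interpolation identity."""
    n = train.n_samples
    if n < 4:
        raise ValidationError("LIONESS needs >= 4 samples")
    vals = train.values.loc[:, edges.nodes].to_numpy()
    e_all = _edge_vector(aggregate(vals), edges)
    nets = []
    for k, sid in enumerate(train.sample_ids):
        rest = np.delete(vals, k, axis=0)
        try:
            e_wo = _edge_vector(aggregate(rest), edges)
        except ValidationError as exc:
            raise ValidationError(f"leaving out sample {sid!r}: {exc}") from exc
        w = n * (e_all - e_wo) + e_wo
        nets.append(IndividualNetwork(sid, edges, w, scaled=False))
    return nets


def lioness_test_network(
    train: FeatureMatrix,
    test_sample_id: str,
    test_values,
    edges: EdgeSet,
    aggregate: AggregateFn = pearson_adjacency,
):
    """Network for one unseen sample via a temporary (N+1)-sample panel.

    The test sample is appended to the train panel, all N+1 networks are
    recomputed on the joint panel, and both the test sample's network and
    the refreshed train networks are returned — similarities of the test
    sample to the reference panel are computed within this panel.  Each
    test sample is processed independently so it cannot perturb another's
    panel.
    """
    missing = [f for f in edges.nodes if f not in train.values.columns]
    if missing:
        raise ValidationError(f"train panel lacks features {missing[:5]}")
    try:
        row = np.asarray([test_values[f] for f in train.feature_ids], dtype=float)
    except KeyError as exc:
        raise ValidationError(f"test sample missing feature {exc}") from exc
    if test_sample_id in train.sample_ids:
        raise ValidationError(f"test sample ID {test_sample_id!r} collides with train")
    import pandas as pd

    panel = pd.DataFrame(
        np.vstack([train.values.to_numpy(), row]),
        index=[*train.sample_ids, test_sample_id],
        columns=train.feature_ids,
    )
    nets = lioness_networks(FeatureMatrix(panel, train.modality), edges, aggregate)
    test_net = nets[-1]
    return test_net, nets[:-1]


# ---------------------------------------------------------------------------
# global edge-weight scaling
# ---------------------------------------------------------------------------

def scale_edge_weights_global(nets: Sequence[IndividualNetwork]):
    """One affine map over all weights of all networks onto [0, 1].

    Returns the scaled networks and the global (min, max) pair, reusable on
    test networks through :func:`apply_edge_scaling`.
    """
    if len(nets) == 0:
        raise ValidationError("no networks to scale")
    allw = np.concatenate([net.weights for net in nets])
    lo, hi = float(allw.min()), float(allw.max())
    if hi <= lo:
        raise ValidationError("all edge weights identical; cannot scale")
    scaled = [
        IndividualNetwork(
            net.sample_id, net.edge_set, (net.weights - lo) / (hi - lo), scaled=True
        )
        for net in nets
    ]
    return scaled, (lo, hi)


def apply_edge_scaling(
    nets: Sequence[IndividualNetwork], bounds: tuple[float, float]
) -> list[IndividualNetwork]:
    """Scale with stored (train) global bounds, clipping to [0, 1]."""
    lo, hi = bounds
    if hi <= lo:
        raise ValidationError("invalid scaling bounds")
    return [
        IndividualNetwork(
            net.sample_id,
            net.edge_set,
            np.clip((net.weights - lo) / (hi - lo), 0.0, 1.0),
            scaled=True,
        )
        for net in nets
    ]
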