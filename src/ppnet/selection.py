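"""Node and edge feature selection, and cross-validated tuning of both.

Nodes are ranked by standard deviation on the training data.  Edges are
ranked by the absolute difference between condition-specific (per-class)
aggregate networks: an edge is retained when its absolute difference
strictly exceeds the chosen quantile of all candidate differences, so a
lower threshold keeps more edges.  The threshold and the node count are
tuned jointly by stratified 5-fold cross-validation of the fast Node
Product pipeline, scored by macro F1.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io import FeatureMatrix, LabelVector, ValidationError
from .networks import (
    AggregateNetwork,
    EdgeSet,
    apply_min_max,
    min_max_scale_features,
    node_product_networks,
    pearson_adjacency,
    scale_edge_weights_global,
    apply_edge_scaling,
)

DEFAULT_NODE_GRID = tuple(range(100, 1500, 100))
DEFAULT_EDGE_GRID = (0.25, 0.5, 0.75)


@dataclasses.dataclass
class SelectionParams:
    """Chosen node count and edge-difference quantile threshold."""

    n_nodes: int
    t_edge: float

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValidationError("n_nodes must be >= 2")
        if not 0.0 < self.t_edge < 1.0:
            raise ValidationError("t_edge must lie in (0, 1)")


def select_top_nodes(train: FeatureMatrix, n_nodes: int) -> list[str]:
    """The ``n_nodes`` features with the largest standard deviation.

    Ties are broken by lexicographic feature ID so the choice is
    deterministic.
    """
    if n_nodes > train.n_features:
        raise ValidationError(
            f"n_nodes={n_nodes} exceeds available features ({train.n_features})"
        )
    sd = train.values.std(axis=0, ddof=1)
    order = sorted(train.feature_ids, key=lambda f: (-sd[f], f))
    return order[:n_nodes]


def condition_networks(
    train: FeatureMatrix,
    labels: LabelVector,
    nodes: list[str],
    method: str = "mean_node_product",
) -> dict[str, AggregateNetwork]:
    """One aggregate network per class, fitted on that class's samples only.

    ``mean_node_product`` (default) averages Node Product networks of the
    class after min-max scaling on the full training set; ``pearson`` uses
    the within-class Pearson correlation.
    """
    sub = train.subset_features(nodes)
    lab = labels.subset(train.sample_ids)
    if method == "mean_node_product":
        scaled, _ = min_max_scale_features(sub)
    out = {}
    for cls in labels.label_set:
        ids = [s for s in train.sample_ids if lab[s] == cls]
        if len(ids) < 3:
            raise ValidationError(f"class {cls!r} has fewer than 3 samples")
        if method == "mean_node_product":
            vals = scaled.values.loc[ids].to_numpy()
            adj = (vals.T @ vals) / len(ids)
            np.fill_diagonal(adj, 0.0)
        elif method == "pearson":
            adj = pearson_adjacency(sub.values.loc[ids].to_numpy())
        else:
            raise ValidationError(f"unknown condition-network method {method!r}")
        out[cls] = AggregateNetwork(list(nodes), adj, len(ids))
    return out


def select_edges(per_class: dict[str, AggregateNetwork], t_edge: float) -> EdgeSet:
    """Edges whose between-class absolute difference exceeds the t_edge quantile.

    Restricted to exactly two classes.  Ties at the quantile are excluded,
    which makes the retained sets nested across increasing thresholds.
    """
    if len(per_class) != 2:
        raise ValidationError("edge selection is defined for exactly two classes")
    (n1, a), (n2, b) = sorted(per_class.items())
    if a.nodes != b.nodes:
        raise ValidationError("condition networks have mismatched node sets")
    diff = np.abs(a.adjacency - b.adjacency)
    p = len(a.nodes)
    iu = np.triu_indices(p, k=1)
    d = diff[iu]
    cut = np.quantile(d, t_edge)
    keep = d > cut
    if not keep.any():
        raise ValidationError(
            "no edge exceeds the threshold (identical condition networks?); "
            "lower t_edge"
        )
    pairs = [
        (a.nodes[i], a.nodes[j])
        for i, j, k in zip(iu[0], iu[1], keep)
        if k
    ]
    return EdgeSet(pairs, nodes=a.nodes)


# ---------------------------------------------------------------------------
# cross-validated tuning
# ---------------------------------------------------------------------------

def _fast_path_score(
    train: FeatureMatrix,
    labels: LabelVector,
    params: SelectionParams,
    folds: int,
    seed: int,
    C: float,
    K: int,
    sigma: float,
) -> float:
    """Mean macro F1 of the Node Product edge pipeline over stratified folds."""
    from .fusion import macro_f1, train_svm, predict
    from .ppn import edge_ppn, normalize_ppn

    y = labels.subset(train.sample_ids)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    ids = np.array(train.sample_ids)
    for tr_idx, va_idx in skf.split(ids, y.to_numpy()):
        tr_ids, va_ids = list(ids[tr_idx]), list(ids[va_idx])
        tr = train.subset_samples(tr_ids)
        va = train.subset_samples(va_ids)
        nodes = select_top_nodes(tr, params.n_nodes)
        tr_sel, va_sel = tr.subset_features(nodes), va.subset_features(nodes)
        tr_scaled, mm = min_max_scale_features(tr_sel)
        va_scaled = apply_min_max(va_sel, mm)
        nets = condition_networks(tr, labels, nodes)
        edges = select_edges(nets, params.t_edge)
        tr_nets = node_product_networks(tr_scaled, edges)
        va_nets = node_product_networks(va_scaled, edges)
        tr_nets, bounds = scale_edge_weights_global(tr_nets)
        va_nets = apply_edge_scaling(va_nets, bounds)
        k_eff = min(K, len(tr_ids) - 1)
        ppn_tr = normalize_ppn(edge_ppn(tr_nets, K=k_eff, sigma=sigma))
        ppn_va = edge_ppn(tr_nets, va_nets, K=k_eff, sigma=sigma)
        ppn_va = normalize_ppn(ppn_va, self_sim_rows=np.ones(len(va_ids)))
        model = train_svm(
            ppn_tr, labels, C_grid=[C], folds=min(folds, 3), seed=seed
        )
        pred = predict(model, ppn_va)
        scores.append(macro_f1(labels.subset(va_ids), pred).macro_f1)
    return float(np.mean(scores))


def tune_selection(
    train: FeatureMatrix,
    labels: LabelVector,
    node_grid=DEFAULT_NODE_GRID,
    edge_grid=DEFAULT_EDGE_GRID,
    folds: int = 5,
    seed: int = 0,
    C: float = 100.0,
    K: int = 20,
    sigma: float = 0.05,
):
    """Choose (n_nodes, t_edge) maximizing inner-CV macro F1.

    The inner pipeline is always the computationally cheap Node Product
    edge path.  Ties are broken toward smaller n_nodes, then smaller
    t_edge.  Returns the chosen :class:`SelectionParams` and the full
    grid-score table.
    """
    node_grid = [n for n in node_grid if n <= train.n_features]
    if len(node_grid) == 0 or len(list(edge_grid)) == 0:
        raise ValidationError("empty selection grid")
    rows = []
    for n_nodes, t_edge in itertools.product(sorted(node_grid), sorted(edge_grid)):
        params = SelectionParams(n_nodes, t_edge)
        score = _fast_path_score(train, labels, params, folds, seed, C, K, sigma)
        rows.append({"n_nodes": n_nodes, "t_edge": t_edge, "mean_macro_f1": score})
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["mean_macro_f1", "n_nodes", "t_edge"], ascending=[False, True, True]
    ).iloc[0]
    return SelectionParams(int(best["n_nodes"]), float(best["t_edge"])), table
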