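"""Modality fusion, precomputed-kernel SVM classification and orchestration.

Fusion can happen at three stages: *early* (feature concatenation before
network construction), *intermediate* (averaging or similarity network
fusion of per-modality PPNs) or *late* (majority vote over per-modality
predictions, with seeded random tie-breaking).

Classification uses a support vector machine on the precomputed similarity
matrix.  Because some PPNs (Spearman, averages, fused) can be indefinite,
the training kernel is repaired to positive semidefinite by clipping
negative eigenvalues at zero; the same spectral filter is applied to test
rows so train and test live in one feature space.  The cost parameter C is
chosen from a grid by stratified cross-validation on the training kernel.
Performance is summarized by the macro F1 score, the unweighted mean of
per-class F1 — robust to the class imbalance typical of clinical cohorts.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io import (
    FeatureMatrix,
    LabelVector,
    ValidationError,
    write_metrics,
    write_ppn,
    write_predictions,
    write_run_log,
)
from .networks import (
    apply_edge_scaling,
    apply_min_max,
    lioness_networks,
    lioness_test_network,
    min_max_scale_features,
    node_product_networks,
    scale_edge_weights_global,
)
from .ppn import (
    PPNMatrix,
    affinity_ppn,
    combine_node_edge,
    edge_ppn,
    gaussian_ppn,
    normalize_ppn,
    spearman_ppn,
)
from .selection import SelectionParams, condition_networks, select_edges, select_top_nodes

DEFAULT_C_GRID = tuple(10.0 ** k for k in range(1, 6))

# libsvm can crawl at large C on noisy kernels; a generous iteration cap keeps
# fits deterministic and bounded without affecting well-posed problems
_SVC_MAX_ITER = 100_000


def _fit_svc(k, y, C):
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    svc = SVC(kernel="precomputed", C=C, max_iter=_SVC_MAX_ITER)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(k, y)
    return svc


class PipelineError(ValidationError):
    """Raised for workflow combinations that are not defined."""


# ---------------------------------------------------------------------------
# fusion primitives
# ---------------------------------------------------------------------------

def early_fusion(
    matrices: Mapping[str, FeatureMatrix],
    selections: Mapping[str, int] | None = None,
) -> FeatureMatrix:
    """Concatenate modalities column-wise with modality-tagged feature IDs.

    When ``selections`` maps modality name to a node count, per-modality
    top-variance selection is applied first.  Downstream edge selection on
    the result may pair features across modalities.
    """
    names = list(matrices)
    ref_ids = matrices[names[0]].sample_ids
    blocks = []
    for name in names:
        m = matrices[name]
        if set(m.sample_ids) != set(ref_ids):
            diff = set(m.sample_ids) ^ set(ref_ids)
            raise ValidationError(f"sample mismatch across modalities: {sorted(diff)[:5]}")
        if selections is not None and name in selections:
            m = m.subset_features(select_top_nodes(m, selections[name]))
        block = m.values.loc[ref_ids]
        block = block.rename(columns={f: f"{name}:{f}" for f in block.columns})
        blocks.append(block)
    fused = pd.concat(blocks, axis=1)
    return FeatureMatrix(fused, modality="+".join(names))


def intermediate_average(ppns: Sequence[PPNMatrix]) -> PPNMatrix:
    """Elementwise mean of aligned PPNs."""
    if len(ppns) < 1:
        raise ValidationError("nothing to average")
    ref = ppns[0]
    vals = np.zeros_like(ref.values)
    for p in ppns:
        if p.row_ids != ref.row_ids or p.col_ids != ref.col_ids:
            raise ValidationError("PPN sample IDs differ; align before averaging")
        vals += p.values
    return PPNMatrix(ref.row_ids, ref.col_ids, vals / len(ppns), kind="fused")


def _snf_row_normalize(w: np.ndarray) -> np.ndarray:
    """Full kernel P: off-diagonal mass 1/2 per row, diagonal 1/2."""
    off = w - np.diag(np.diag(w))
    rs = off.sum(axis=1)
    rs[rs == 0] = 1.0
    p = off / (2.0 * rs[:, None])
    np.fill_diagonal(p, 0.5)
    return p


def _snf_knn_kernel(w: np.ndarray, K: int) -> np.ndarray:
    """Sparse kernel S: row-normalized over the K most similar neighbours."""
    n = w.shape[0]
    s = np.zeros_like(w)
    for i in range(n):
        row = w[i].copy()
        row[i] = -np.inf
        nbrs = np.argsort(-row, kind="stable")[:K]
        mass = w[i, nbrs].sum()
        if mass == 0:
            mass = 1.0
        s[i, nbrs] = w[i, nbrs] / mass
    return s


def snf_fuse(
    ppns: Sequence[PPNMatrix],
    K: int = 20,
    iterations: int = 20,
    tol: float = 1e-8,
) -> PPNMatrix:
    """Similarity network fusion by iterative cross-diffusion.

    Per view v, the full kernel P_v is updated as
    ``P_v <- S_v @ mean(P_w, w != v) @ S_v.T`` where S_v is the view's
    K-nearest-neighbour kernel, with row renormalization and
    symmetrization after each step.  Stops early when the fused matrix
    changes by less than ``tol`` in max norm.  Output is the mean of the
    final P_v, symmetrized.
    """
    if len(ppns) < 2:
        raise ValidationError("SNF needs at least 2 views")
    ref = ppns[0]
    if not ref.square:
        raise ValidationError("SNF requires square PPNs")
    n = len(ref.row_ids)
    if K >= n:
        raise ValidationError(f"K={K} must be < number of samples ({n})")
    ws = []
    for p in ppns:
        if not p.square or p.row_ids != ref.row_ids:
            raise ValidationError("SNF views must be square over identical samples")
        ws.append((p.values + p.values.T) / 2.0)
    ps = [_snf_row_normalize(w) for w in ws]
    ss = [_snf_knn_kernel(w, K) for w in ws]
    v = len(ps)
    fused_prev = sum(ps) / v
    for _ in range(iterations):
        new = []
        for i in range(v):
            others = sum(ps[j] for j in range(v) if j != i) / (v - 1)
            pi = ss[i] @ others @ ss[i].T
            pi = _snf_row_normalize(pi)
            pi = (pi + pi.T) / 2.0
            new.append(pi)
        ps = new
        fused = sum(ps) / v
        if np.max(np.abs(fused - fused_prev)) < tol:
            break
        fused_prev = fused
    fused = sum(ps) / v
    fused = (fused + fused.T) / 2.0
    return PPNMatrix(ref.row_ids, ref.col_ids, fused, kind="fused")


# ---------------------------------------------------------------------------
# kernel SVM
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class KernelModel:
    """A fitted precomputed-kernel SVM plus everything needed to predict."""

    train_ids: list[str]
    classes: list[str]
    C: float
    svc: SVC
    spectral_filter: np.ndarray  # maps raw kernel rows into the repaired space
    cv_scores: dict


def _psd_repair(k: np.ndarray):
    """Clip negative eigenvalues at zero; return repaired kernel and filter.

    The filter T = U diag(lambda_clip / lambda) U' maps raw test kernel
    rows into the repaired space; it is the identity when the kernel is
    already PSD.
    """
    sym = (k + k.T) / 2.0
    lam, u = np.linalg.eigh(sym)
    lam_clip = np.clip(lam, 0.0, None)
    repaired = (u * lam_clip) @ u.T
    ratio = np.where(np.abs(lam) > 1e-12, lam_clip / np.where(lam == 0, 1.0, lam), 0.0)
    t = (u * ratio) @ u.T
    return (repaired + repaired.T) / 2.0, t


def train_svm(
    ppn_train: PPNMatrix,
    labels: LabelVector,
    C_grid=DEFAULT_C_GRID,
    folds: int = 5,
    seed: int = 0,
    repair: bool = True,
    selection: str = "cv",
) -> KernelModel:
    """Fit an SVM on a (normalized) square train PPN.

    C is selected from ``C_grid`` by stratified ``folds``-fold CV macro F1
    (``selection="cv"``), or by training-set macro F1
    (``selection="train"``); ties go to the smallest C.
    """
    if not ppn_train.square:
        raise ValidationError("training PPN must be square")
    y = labels.subset(ppn_train.row_ids)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValidationError("training labels contain a single class")
    k_raw = ppn_train.values
    if repair:
        k, t = _psd_repair(k_raw)
    else:
        k, t = (k_raw + k_raw.T) / 2.0, np.eye(k_raw.shape[0])
    yv = y.to_numpy()
    C_grid = sorted(float(c) for c in C_grid)

    cv_scores: dict = {}
    if len(C_grid) == 1:
        best_c = C_grid[0]
    elif selection == "train":
        for c in C_grid:
            svc = _fit_svc(k, yv, c)
            cv_scores[c] = float(
                f1_score(yv, svc.predict(k), average="macro", zero_division=0)
            )
        best_c = max(C_grid, key=lambda c: (cv_scores[c], -c))
    else:
        n_splits = min(folds, int(pd.Series(yv).value_counts().min()))
        if n_splits < 2:
            raise ValidationError("too few samples per class for CV")
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for c in C_grid:
            scores = []
            for tr, va in skf.split(k, yv):
                svc = _fit_svc(k[np.ix_(tr, tr)], yv[tr], c)
                pred = svc.predict(k[np.ix_(va, tr)])
                scores.append(f1_score(yv[va], pred, average="macro", zero_division=0))
            cv_scores[c] = float(np.mean(scores))
        best_c = max(C_grid, key=lambda c: (cv_scores[c], -c))

    svc = _fit_svc(k, yv, best_c)
    return KernelModel(
        train_ids=list(ppn_train.row_ids),
        classes=classes,
        C=best_c,
        svc=svc,
        spectral_filter=t,
        cv_scores=cv_scores,
    )


def predict(model: KernelModel, ppn_test_train: PPNMatrix) -> pd.Series:
    """Predict labels for the rows of a test-by-train PPN (matched by ID)."""
    missing = [c for c in model.train_ids if c not in ppn_test_train.col_ids]
    if missing:
        raise ValidationError(f"test PPN lacks train columns {missing[:5]}")
    aligned = ppn_test_train.reindex(col_ids=model.train_ids)
    k = aligned.values @ model.spectral_filter
    pred = model.svc.predict(k)
    return pd.Series(pred, index=aligned.row_ids, name="predicted")


# ---------------------------------------------------------------------------
# late fusion and scoring
# ---------------------------------------------------------------------------

def late_fusion_majority(
    prediction_sets: Mapping[str, pd.Series], seed: int = 0
):
    """Per-sample majority vote with seeded uniform tie-breaking.

    Returns the final labels and, per input set, the frequency with which
    its prediction matches the final one, excluding tied samples (the
    modality "contribution" statistic).
    """
    names = list(prediction_sets)
    if len(names) < 2:
        raise ValidationError("majority vote needs >= 2 prediction sets")
    ref_ids = list(prediction_sets[names[0]].index)
    for name in names[1:]:
        if set(prediction_sets[name].index) != set(ref_ids):
            raise ValidationError("prediction sets cover different samples")
    rng = np.random.default_rng(seed)
    final, tied = {}, {}
    for sid in ref_ids:
        votes = Counter(str(prediction_sets[n][sid]) for n in names)
        top = max(votes.values())
        winners = sorted(lab for lab, c in votes.items() if c == top)
        tied[sid] = len(winners) > 1
        final[sid] = winners[0] if len(winners) == 1 else rng.choice(winners)
    final = pd.Series(final, index=ref_ids, name="predicted")
    untied = [s for s in ref_ids if not tied[s]]
    contribution = {}
    for name in names:
        if untied:
            agree = np.mean(
                [str(prediction_sets[name][s]) == final[s] for s in untied]
            )
        else:
            agree = np.nan
        contribution[name] = float(agree)
    return final, contribution


@dataclasses.dataclass
class MetricsReport:
    per_class_f1: dict[str, float]
    macro_f1: float
    confusion: pd.DataFrame

    def __post_init__(self) -> None:
        assert abs(self.macro_f1 - np.mean(list(self.per_class_f1.values()))) < 1e-12


def macro_f1(truth: pd.Series | LabelVector, predicted: pd.Series) -> MetricsReport:
    """Per-class and macro F1 with the F1=0 convention for absent classes."""
    if isinstance(truth, LabelVector):
        truth = truth.labels
    truth = truth.astype(str)
    predicted = predicted.astype(str).loc[truth.index]
    label_set = sorted(truth.unique())
    per = f1_score(
        truth, predicted, labels=label_set, average=None, zero_division=0
    )
    per_class = {lab: float(v) for lab, v in zip(label_set, per)}
    conf = pd.crosstab(truth, predicted, dropna=False)
    return MetricsReport(per_class, float(np.mean(per)), conf)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

VALID_LEVELS = ("nodes", "edges", "nodes_and_edges")
VALID_NODE_SIMS = ("affinity", "gaussian", "spearman")
VALID_EDGE_METHODS = ("node_product", "lioness")
VALID_FUSIONS = ("none", "early", "intermediate_average", "intermediate_snf", "late")


@dataclasses.dataclass
class PipelineResult:
    predictions: pd.Series
    metrics: MetricsReport | None
    ppn_train: PPNMatrix | None
    ppn_test: PPNMatrix | None
    selection: dict
    contributions: dict | None
    chosen_C: float | None


def _node_level_ppns(train, test, node_similarity, K, sigma_affinity, sigma_gaussian):
    if node_similarity == "affinity":
        k_eff = min(K, train.n_samples - 1)
        tr = affinity_ppn(train, K=k_eff, sigma=sigma_affinity)
        te = affinity_ppn(train, test, K=k_eff, sigma=sigma_affinity)
    elif node_similarity == "gaussian":
        tr = gaussian_ppn(train, sigma=sigma_gaussian)
        te = gaussian_ppn(train, test, sigma=sigma_gaussian)
    elif node_similarity == "spearman":
        tr = spearman_ppn(train)
        te = spearman_ppn(train, test)
    else:
        raise PipelineError(f"unknown node similarity {node_similarity!r}")
    tr = normalize_ppn(tr)
    te = normalize_ppn(te, self_sim_rows=np.ones(len(te.row_ids)))
    return tr, te


def _edge_level_ppns(
    train, test, labels, sel: SelectionParams, edge_method, K, sigma, condition_net,
    edge_similarity="gaussian",
):
    nodes = select_top_nodes(train, sel.n_nodes)
    tr_sel = train.subset_features(nodes)
    te_sel = test.subset_features(nodes)
    cond = condition_networks(train, labels, nodes, method=condition_net)
    edges = select_edges(cond, sel.t_edge)
    k_eff = min(K, train.n_samples - 1)
    if edge_method == "node_product":
        tr_scaled, mm = min_max_scale_features(tr_sel)
        te_scaled = apply_min_max(te_sel, mm)
        tr_nets = node_product_networks(tr_scaled, edges)
        te_nets = node_product_networks(te_scaled, edges)
        tr_nets, bounds = scale_edge_weights_global(tr_nets)
        te_nets = apply_edge_scaling(te_nets, bounds)
        ppn_tr = edge_ppn(tr_nets, K=k_eff, sigma=sigma, similarity=edge_similarity)
        ppn_te = edge_ppn(tr_nets, te_nets, K=k_eff, sigma=sigma, similarity=edge_similarity)
    elif edge_method == "lioness":
        tr_nets = lioness_networks(tr_sel, edges)
        tr_nets, bounds = scale_edge_weights_global(tr_nets)
        pairs = []
        for sid in te_sel.sample_ids:
            net, panel = lioness_test_network(
                tr_sel, sid, te_sel.values.loc[sid], edges
            )
            net = apply_edge_scaling([net], bounds)[0]
            panel = apply_edge_scaling(panel, bounds)
            pairs.append((net, panel))
        ppn_tr = edge_ppn(tr_nets, K=k_eff, sigma=sigma, similarity=edge_similarity)
        ppn_te = edge_ppn(tr_nets, pairs, K=k_eff, sigma=sigma, similarity=edge_similarity)
    else:
        raise PipelineError(f"unknown edge method {edge_method!r}")
    ppn_tr = normalize_ppn(ppn_tr)
    ppn_te = normalize_ppn(ppn_te, self_sim_rows=np.ones(len(ppn_te.row_ids)))
    return ppn_tr, ppn_te, {"nodes": nodes, "edges": edges.pairs}


def _level_ppns(train, test, labels, level, opts):
    """Normalized (train, test) PPNs for one feature matrix at one level."""
    if level == "nodes":
        tr, te = _node_level_ppns(
            train, test, opts["node_similarity"], opts["K"],
            opts["sigma_affinity"], opts["sigma_gaussian"],
        )
        return tr, te, {}
    sel = opts["selection"]
    if level == "edges":
        return _edge_level_ppns(
            train, test, labels, sel, opts["edge_method"], opts["K"],
            opts["sigma_affinity"], opts["condition_net"], opts["edge_similarity"],
        )
    if level == "nodes_and_edges":
        n_tr, n_te = _node_level_ppns(
            train, test, opts["node_similarity"], opts["K"],
            opts["sigma_affinity"], opts["sigma_gaussian"],
        )
        e_tr, e_te, info = _edge_level_ppns(
            train, test, labels, sel, opts["edge_method"], opts["K"],
            opts["sigma_affinity"], opts["condition_net"], opts["edge_similarity"],
        )
        return combine_node_edge(n_tr, e_tr), combine_node_edge(n_te, e_te), info
    raise PipelineError(f"unknown level {level!r}")


def run_pipeline(
    train: Mapping[str, FeatureMatrix],
    test: Mapping[str, FeatureMatrix],
    labels_train: LabelVector,
    labels_test: LabelVector | None = None,
    level: str = "edges",
    node_similarity: str = "spearman",
    edge_method: str = "node_product",
    fusion: str = "none",
    selection: Mapping[str, SelectionParams] | SelectionParams | None = None,
    C_grid=DEFAULT_C_GRID,
    folds: int = 5,
    seed: int = 0,
    K: int = 20,
    sigma_affinity: float = 0.5,
    sigma_gaussian: float | str = "auto",
    condition_net: str = "mean_node_product",
    edge_similarity: str = "gaussian",
    out_dir=None,
) -> PipelineResult:
    """Execute one workflow variation end to end.

    ``train``/``test`` map modality name to feature matrix.  ``selection``
    gives per-modality :class:`SelectionParams` (or one shared instance);
    it is required whenever the level involves edges.  Undefined
    combinations (late fusion with a single modality, any fusion with one
    modality, late fusion at a pure node or edge level) raise
    :class:`PipelineError` before any output is written.
    """
    if level not in VALID_LEVELS:
        raise PipelineError(f"unknown level {level!r}")
    if fusion not in VALID_FUSIONS:
        raise PipelineError(f"unknown fusion {fusion!r}")
    names = list(train)
    if list(test) != names:
        raise PipelineError("train and test must cover the same modalities")
    if fusion == "none" and len(names) != 1:
        raise PipelineError("combination not defined: fusion='none' needs one modality")
    if fusion != "none" and len(names) < 2:
        raise PipelineError(f"combination not defined: {fusion} fusion needs >= 2 modalities")
    if fusion == "late" and level != "nodes_and_edges":
        raise PipelineError(
            "combination not defined: late fusion is only applied to the "
            "node-and-edge outcome quartet"
        )
    if level != "nodes" and selection is None:
        raise PipelineError("edge-based levels require selection parameters")

    def sel_for(name):
        if isinstance(selection, SelectionParams):
            return selection
        return selection[name] if selection is not None else None

    def opts_for(name):
        return {
            "node_similarity": node_similarity,
            "edge_method": edge_method,
            "K": K,
            "sigma_affinity": sigma_affinity,
            "sigma_gaussian": sigma_gaussian,
            "condition_net": condition_net,
            "edge_similarity": edge_similarity,
            "selection": sel_for(name),
        }

    contributions = None
    sel_info: dict = {}
    chosen_C = None

    if fusion == "late":
        preds, ppn_tr = {}, None
        for name in names:
            for lev, tag in (("nodes", "n"), ("edges", "e")):
                tr, te, info = _level_ppns(
                    train[name], test[name], labels_train, lev, opts_for(name)
                )
                model = train_svm(tr, labels_train, C_grid=C_grid, folds=folds, seed=seed)
                preds[f"{tag},{name}"] = predict(model, te)
                sel_info[f"{tag},{name}"] = {k: v for k, v in info.items() if k == "nodes"}
        final, contributions = late_fusion_majority(preds, seed=seed)
        predictions = final
        ppn_te = None
    else:
        if fusion == "none":
            name = names[0]
            ppn_tr, ppn_te, sel_info = _level_ppns(
                train[name], test[name], labels_train, level, opts_for(name)
            )
        elif fusion == "early":
            if level == "nodes":
                fused_tr = early_fusion(train)
                fused_te = early_fusion(test)
            else:
                counts = {n: sel_for(n).n_nodes for n in names}
                fused_tr = early_fusion(train, counts)
                fused_te = early_fusion(test, counts)
            opts = opts_for(names[0])
            # node selection already applied during concatenation
            p_fused = fused_tr.n_features
            if level != "nodes":
                opts["selection"] = SelectionParams(p_fused, sel_for(names[0]).t_edge)
            ppn_tr, ppn_te, sel_info = _level_ppns(
                fused_tr, fused_te, labels_train, level, opts
            )
        else:  # intermediate fusion
            trs, tes = [], []
            for name in names:
                tr, te, info = _level_ppns(
                    train[name], test[name], labels_train, level, opts_for(name)
                )
                trs.append(tr)
                tes.append(te)
                if info:
                    sel_info[name] = info
            if fusion == "intermediate_average":
                ppn_tr = intermediate_average(trs)
            else:
                k_eff = min(K, len(trs[0].row_ids) - 1)
                ppn_tr = normalize_ppn(snf_fuse(trs, K=k_eff))
            # the test side is fused by averaging the per-view normalized PPNs
            ppn_te = intermediate_average(tes)
        model = train_svm(ppn_tr, labels_train, C_grid=C_grid, folds=folds, seed=seed)
        chosen_C = model.C
        predictions = predict(model, ppn_te)

    metrics = None
    if labels_test is not None:
        metrics = macro_f1(labels_test.subset(list(predictions.index)), predictions)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        truth = (
            labels_test.subset(list(predictions.index)) if labels_test is not None else None
        )
        write_predictions(out / "predictions.tsv", predictions.index, predictions, truth)
        if metrics is not None:
            write_metrics(metrics, out / "metrics.tsv")
        if fusion != "late" and ppn_tr is not None:
            write_ppn(ppn_tr, out / "ppn_train.tsv")
            if ppn_te is not None:
                write_ppn(ppn_te, out / "ppn_test.tsv")
        write_run_log(
            out / "run_log.json",
            {
                "level": level,
                "node_similarity": node_similarity,
                "edge_method": edge_method,
                "fusion": fusion,
                "seed": seed,
                "C": chosen_C,
            },
            {
                "macro_f1": metrics.macro_f1 if metrics else None,
                "contributions": contributions,
            },
        )

    return PipelineResult(
        predictions=predictions,
        metrics=metrics,
        ppn_train=ppn_tr if fusion != "late" else None,
        ppn_test=ppn_te if fusion != "late" else None,
        selection=sel_info,
        contributions=contributions,
        chosen_C=chosen_C,
    )
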