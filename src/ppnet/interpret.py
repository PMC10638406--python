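"""Differential co-expression on edge matrices and gene-set enrichment.

Edges of individual networks are treated like expression features: for each
edge a linear model of weight on group membership is fitted, residual
variances are shrunk toward a common prior by empirical Bayes (moment
estimation of the prior degrees of freedom and variance on the log scale),
and moderated t-statistics with Benjamini-Hochberg adjusted p-values are
reported.  The same machinery applies unchanged to a gene-expression matrix
for node-level statistics.

Enrichment uses the classical weighted Kolmogorov-Smirnov running-sum
statistic on a signed gene ranking, with a gene-label permutation null,
sign-stratified normalized enrichment scores and the matching FDR
procedure.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats

from .io import GeneSetCollection, LabelVector, ValidationError
from .networks import IndividualNetwork

EDGE_SEP = "|"


# ---------------------------------------------------------------------------
# edge matrix
# ---------------------------------------------------------------------------

def edge_matrix(nets: Sequence[IndividualNetwork]) -> pd.DataFrame:
    """Edges x samples matrix of individual-network edge weights.

    Rows follow the shared edge-set order (IDs "a|b"); columns are sorted
    by sample ID so the result does not depend on input order.
    """
    if len(nets) == 0:
        raise ValidationError("no networks")
    ref = nets[0].edge_set
    for net in nets[1:]:
        if net.edge_set != ref:
            raise ValidationError("all networks must share one edge set")
    order = np.argsort([n.sample_id for n in nets], kind="stable")
    cols = {nets[k].sample_id: nets[k].weights for k in order}
    idx = [f"{a}{EDGE_SEP}{b}" for a, b in ref.pairs]
    return pd.DataFrame(cols, index=idx)


# ---------------------------------------------------------------------------
# moderated t statistics
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: int):
    """Moment estimation of the scaled inverse-chi-square variance prior.

    Under the hierarchical model the sample variances follow a scaled F
    distribution, so log s^2 has known digamma/trigamma moments; matching
    the observed mean and variance of log s^2 yields the prior degrees of
    freedom d0 and prior variance s0^2.  Returns ``(d0, s0^2)`` with
    ``d0 = inf`` when the observed spread is no larger than expected under
    equal variances.
    """
    s2 = np.asarray(s2, dtype=float)
    if (s2 <= 0).any():
        s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e_z = z.mean()
    var_z = z.var(ddof=1) if len(z) > 1 else 0.0
    excess = var_z - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        log_s0 = e_z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = (
            e_z
            - special.polygamma(0, df / 2.0)
            + special.polygamma(0, d0 / 2.0)
            - np.log(d0 / df)
        )
    return d0, float(np.exp(log_s0))


def moderated_t_stats(
    m1: pd.DataFrame,
    groups: LabelVector,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-row two-group linear model with empirical-Bayes moderated t.

    ``m1`` is features (edges or genes) x samples.  The coefficient is the
    second-group minus first-group mean (groups in lexicographic order).
    ``prior_df`` overrides the estimated prior degrees of freedom: 0 gives
    the ordinary t-statistic, ``inf`` full shrinkage to the common prior
    variance.  The adjusted p-value column uses Benjamini-Hochberg.
    Rows are sorted by decreasing |t|.
    """
    y = groups.subset([c for c in m1.columns])
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValidationError("moderated t requires exactly two groups")
    g1 = [c for c in m1.columns if y[c] == classes[0]]
    g2 = [c for c in m1.columns if y[c] == classes[1]]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs >= 2 samples")
    x1 = m1[g1].to_numpy(dtype=float)
    x2 = m1[g2].to_numpy(dtype=float)
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    beta = mean2 - mean1
    df_resid = n1 + n2 - 2
    rss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + (
        (x2 - mean2[:, None]) ** 2
    ).sum(axis=1)
    s2 = rss / df_resid
    v_unscaled = 1.0 / n1 + 1.0 / n2

    if prior_df is None:
        d0, s0_2 = estimate_variance_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s0_2 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_variance_prior(s2, df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(s2_post * v_unscaled)
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    adj = stats.false_discovery_control(p, method="bh")
    out = pd.DataFrame(
        {
            "coef": beta,
            "avg_weight": m1.to_numpy(dtype=float).mean(axis=1),
            "t": t,
            "p_value": p,
            "adj_p_value": adj,
            "df_total": df_total,
        },
        index=m1.index,
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_2
    out.attrs["residual_df"] = df_resid
    out.attrs["groups"] = classes
    return out.sort_values("t", key=lambda s: -s.abs(), kind="stable")


# ---------------------------------------------------------------------------
# top-edge networks
# ---------------------------------------------------------------------------

def top_edges_network(
    stats_table: pd.DataFrame,
    n: int = 50,
    node_stats: pd.DataFrame | None = None,
    node_t_threshold: float = 1.5,
) -> nx.Graph:
    """Graph of the genes touched by the top-n differential edges.

    Edge attributes: ``coef``, ``t``, ``sign`` ("up"/"down", the color
    key) and ``width`` (|coef|).  Node attribute ``t`` carries the
    node-level moderated t from a parallel expression analysis, set to 0
    (neutral color) when |t| is below ``node_t_threshold``.
    """
    if len(stats_table) < n:
        raise ValidationError(f"only {len(stats_table)} edges available, need {n}")
    g = nx.Graph()
    for edge_id, row in stats_table.head(n).iterrows():
        a, b = str(edge_id).split(EDGE_SEP)
        g.add_edge(
            a,
            b,
            coef=float(row["coef"]),
            t=float(row["t"]),
            sign="up" if row["coef"] >= 0 else "down",
            width=float(abs(row["coef"])),
        )
    for node in g.nodes:
        tval = 0.0
        if node_stats is not None and node in node_stats.index:
            tval = float(node_stats.loc[node, "t"])
            if abs(tval) < node_t_threshold:
                tval = 0.0
        g.nodes[node]["t"] = tval
    return g


def largest_component(g: nx.Graph) -> list[str]:
    """Sorted node list of the largest connected component.

    Size ties are broken toward the component with the lexicographically
    smallest member.
    """
    if g.number_of_nodes() == 0:
        raise ValidationError("empty network")
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps[0]


def export_network(g: nx.Graph, prefix) -> None:
    """Write edge-list + node-table TSVs and a GraphML file."""
    from pathlib import Path

    prefix = Path(prefix)
    edges = pd.DataFrame(
        [
            {"node_a": a, "node_b": b, **data}
            for a, b, data in sorted(g.edges(data=True))
        ]
    )
    edges.to_csv(prefix.with_suffix(".edges.tsv"), sep="\t", index=False)
    nodes = pd.DataFrame(
        [{"node": n, **g.nodes[n]} for n in sorted(g.nodes)]
    )
    nodes.to_csv(prefix.with_suffix(".nodes.tsv"), sep="\t", index=False)
    nx.write_graphml(g, prefix.with_suffix(".graphml"))


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _running_sum_es(order_w: np.ndarray, hit_mask: np.ndarray):
    """Enrichment score of one set: signed extremum of the running sum."""
    n = len(order_w)
    nh = int(hit_mask.sum())
    wsum = order_w[hit_mask].sum()
    if wsum == 0:
        wsum = 1.0
    inc = np.where(hit_mask, order_w / wsum, -1.0 / (n - nh))
    run = np.cumsum(inc)
    k = int(np.argmax(np.abs(run)))
    return float(run[k]), k


def _perm_es(order_w: np.ndarray, nh: int, n_perm: int, rng) -> np.ndarray:
    """Null enrichment scores for random hit sets of size nh.

    Extrema of the running sum occur only at hit positions (just after a
    hit for the maximum, just before for the minimum), so each permuted ES
    can be computed from the sorted hit positions alone.
    """
    n = len(order_w)
    miss_dec = 1.0 / (n - nh)
    out = np.empty(n_perm)
    for b in range(n_perm):
        pos = np.sort(rng.choice(n, size=nh, replace=False))
        w = order_w[pos]
        cum = np.cumsum(w)
        total = cum[-1] if cum[-1] > 0 else 1.0
        j = np.arange(1, nh + 1)
        dev_after = cum / total - (pos + 1 - j) * miss_dec
        dev_before = (cum - w) / total - (pos - (j - 1)) * miss_dec
        cand = np.concatenate([dev_after, dev_before])
        out[b] = cand[np.argmax(np.abs(cand))]
    return out


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection | Mapping[str, Sequence[str]],
    min_size: int = 10,
    n_perm: int = 5000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked gene-set enrichment with a gene-label permutation null.

    ``ranked`` maps gene to a signed statistic (e.g. moderated t); genes
    are walked in decreasing order and hits accumulate |stat|^weight.
    Sets with fewer than ``min_size`` genes after intersecting the ranking
    are dropped.  p-values and normalized enrichment scores are
    sign-stratified; the FDR q-value follows the normalized-ES procedure
    (ratio of permutation and observed tail frequencies, clipped to 1).
    """
    if len(ranked) == 0:
        raise ValidationError("empty ranking")
    if ranked.index.duplicated().any():
        raise ValidationError("duplicate genes in ranking")
    if n_perm < 100:
        raise ValidationError("need >= 100 permutations")
    ranked = ranked.astype(float)
    order = ranked.sort_values(ascending=False, kind="stable")
    genes = list(order.index)
    pos_of = {g: k for k, g in enumerate(genes)}
    order_w = np.abs(order.to_numpy()) ** weight
    rng = np.random.default_rng(seed)

    items = sets.items() if hasattr(sets, "items") else sets
    rows = []
    null_pool: list[np.ndarray] = []
    per_set_null: dict[str, np.ndarray] = {}
    for name, members in items:
        hit = np.zeros(len(genes), dtype=bool)
        for gname in members:
            if gname in pos_of:
                hit[pos_of[gname]] = True
        size = int(hit.sum())
        if size < min_size or size == len(genes):
            continue
        es, kmax = _running_sum_es(order_w, hit)
        null = _perm_es(order_w, size, n_perm, rng)
        per_set_null[name] = null
        null_pool.append(null)
        if es >= 0:
            same = null[null >= 0]
            p = (1 + (same >= es).sum()) / (1 + len(same))
            denom = np.abs(same).mean() if len(same) else 1.0
            leading = [g for g in genes[: kmax + 1] if hit[pos_of[g]]]
        else:
            same = null[null < 0]
            p = (1 + (same <= es).sum()) / (1 + len(same))
            denom = np.abs(same).mean() if len(same) else 1.0
            leading = [g for g in genes[kmax:] if hit[pos_of[g]]]
        nes = es / denom if denom > 0 else 0.0
        rows.append(
            {
                "set": name,
                "size": size,
                "es": es,
                "nes": nes,
                "p_value": float(p),
                "leading_edge": ",".join(leading),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set", "size", "es", "nes", "p_value", "fdr_q", "leading_edge"]
        ).set_index("set")

    table = pd.DataFrame(rows).set_index("set")
    # sign-stratified FDR on the NES scale
    null_nes = []
    for name, null in per_set_null.items():
        pos, neg = null[null >= 0], null[null < 0]
        pm = pos.mean() if len(pos) else 1.0
        nm = np.abs(neg).mean() if len(neg) else 1.0
        null_nes.append(np.where(null >= 0, null / pm, null / nm))
    null_nes = np.concatenate(null_nes)
    obs = table["nes"].to_numpy()
    q = np.empty(len(obs))
    for k, nes in enumerate(obs):
        if nes >= 0:
            num_pool = null_nes[null_nes >= 0]
            num = (num_pool >= nes).mean() if len(num_pool) else 1.0
            den_pool = obs[obs >= 0]
            den = (den_pool >= nes).mean() if len(den_pool) else 1.0
        else:
            num_pool = null_nes[null_nes < 0]
            num = (num_pool <= nes).mean() if len(num_pool) else 1.0
            den_pool = obs[obs < 0]
            den = (den_pool <= nes).mean() if len(den_pool) else 1.0
        q[k] = min(1.0, num / den) if den > 0 else 1.0
    table["fdr_q"] = q
    table = table[["size", "es", "nes", "p_value", "fdr_q", "leading_edge"]]
    return table.sort_values("p_value", kind="stable")
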