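"""Independent oracle implementations shared by the test suite.

Everything here is deliberately written as plain loops from the defining
formulas, independent of the package's vectorized code paths.
"""

import numpy as np


def pairwise_edge_distances(nets):
    """Edge-difference distances via full dense adjacency matrices."""
    n = len(nets)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.linalg.norm(nets[i].adjacency() - nets[j].adjacency(), "fro")
    return d


def snf_reference(ws, K, iterations):
    """Step-by-step transcription of the cross-diffusion update equations."""
    def full_kernel(w):
        n = w.shape[0]
        p = np.zeros_like(w)
        for i in range(n):
            denom = sum(w[i, k] for k in range(n) if k != i)
            for j in range(n):
                if i != j:
                    p[i, j] = w[i, j] / (2.0 * denom)
            p[i, i] = 0.5
        return p

    def knn_kernel(w, K):
        n = w.shape[0]
        s = np.zeros_like(w)
        for i in range(n):
            order = sorted(
                (k for k in range(n) if k != i), key=lambda k: (-w[i, k], k)
            )[:K]
            denom = sum(w[i, k] for k in order)
            for j in order:
                s[i, j] = w[i, j] / denom
        return s

    ws = [np.array(w, dtype=float) for w in ws]
    ps = [full_kernel(w) for w in ws]
    ss = [knn_kernel(w, K) for w in ws]
    v = len(ws)
    for _ in range(iterations):
        new = []
        for a in range(v):
            others = sum(ps[b] for b in range(v) if b != a) / (v - 1)
            pa = ss[a] @ others @ ss[a].T
            pa = full_kernel(pa)
            pa = (pa + pa.T) / 2.0
            new.append(pa)
        ps = new
    fused = sum(ps) / v
    return (fused + fused.T) / 2.0


def running_sum_es_oracle(stats, genes_in_set, weight=1.0):
    """O(N * |set|) running-sum enrichment score from the definitions.

    ``stats`` is a pandas Series gene -> signed statistic.
    """
    order = stats.sort_values(ascending=False, kind="stable")
    genes = list(order.index)
    hits = [g for g in genes if g in set(genes_in_set)]
    nr = sum(abs(order[g]) ** weight for g in hits)
    n = len(genes)
    nh = len(hits)
    run = 0.0
    best = 0.0
    for g in genes:
        if g in set(genes_in_set):
            run += abs(order[g]) ** weight / nr
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


def union_find_components(nodes, edges):
    """Connected components via a plain union-find."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return [sorted(c) for c in comps.values()]
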