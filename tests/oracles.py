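"""Independent brute-force oracles used to verify the implementation.

Everything here is written with explicit loops and elementary formulas,
deliberately avoiding the code paths (and vectorization) of the package
itself.
"""

from __future__ import annotations

import math
from itertools import combinations


def mi_plugin(x, y) -> float:
    """Plug-in mutual information (bits) by explicit triple loop."""
    n = len(x)
    total = 0.0
    for a in sorted(set(x)):
        for b in sorted(set(y)):
            pxy = sum(1 for i in range(n) if x[i] == a and y[i] == b) / n
            if pxy == 0:
                continue
            px = sum(1 for i in range(n) if x[i] == a) / n
            py = sum(1 for i in range(n) if y[i] == b) / n
            total += pxy * math.log2(pxy / (px * py))
    return total


def clr_scores(mi, genes):
    """CLR z-combination from a dense MI dict {(i, j): mi}, explicit loops."""
    background = {}
    for g in genes:
        vals = [mi[tuple(sorted((g, h)))] for h in genes if h != g]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / len(vals)
        background[g] = (mean, math.sqrt(var))
    scores = {}
    for g, h in combinations(genes, 2):
        m = mi[tuple(sorted((g, h)))]
        zs = []
        for node in (g, h):
            mean, sd = background[node]
            zs.append(0.0 if sd == 0 else max(0.0, (m - mean) / sd))
        scores[(g, h)] = math.sqrt(zs[0] ** 2 + zs[1] ** 2)
    return scores


def dpi_triangle(mi_ab, mi_bc, mi_ac, eps):
    """Which of the three triangle edges the DPI removes (enumeration)."""
    edges = {"ab": mi_ab, "bc": mi_bc, "ac": mi_ac}
    removed = set()
    for name, value in edges.items():
        others = [v for k, v in edges.items() if k != name]
        if value < min(others) * (1 - eps):
            removed.add(name)
    return removed


def consensus_ranks(lists):
    """Naive average-rank aggregation: lists is {method: {edge: rank}}.
    Returns edges ordered by (mean rank, edge)."""
    union = set()
    for ranks in lists.values():
        union |= set(ranks)
    means = {}
    for edge in union:
        total = 0.0
        for ranks in lists.values():
            worst = max(ranks.values()) if ranks else 0
            total += ranks.get(edge, worst + 1)
        means[edge] = total / len(lists)
    return sorted(union, key=lambda e: (means[e], e)), means


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not (a | b):
        return 0.0
    return len(a & b) / len(a | b)


def hypergeom_upper_tail(k, n_universe, n_set, n_draw) -> float:
    """P(X >= k) for a hypergeometric draw, by direct summation."""
    total = 0.0
    for x in range(k, min(n_set, n_draw) + 1):
        total += (
            math.comb(n_set, x)
            * math.comb(n_universe - n_set, n_draw - x)
            / math.comb(n_universe, n_draw)
        )
    return total


def bh_qvalues(pvals):
    """Benjamini-Hochberg step-up, naive implementation."""
    n = len(pvals)
    indexed = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    running_min = 1.0
    for pos in range(n - 1, -1, -1):
        i = indexed[pos]
        value = pvals[i] * n / (pos + 1)
        running_min = min(running_min, value)
        q[i] = min(running_min, 1.0)
    return q


def auc_pr(y, scores) -> float:
    """AUC-PR by enumerating every distinct threshold."""
    n_pos = sum(y)
    thresholds = sorted(set(scores), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        pred = [s >= t for s in scores]
        tp = sum(1 for p, label in zip(pred, y) if p and label)
        precision = tp / sum(pred)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def precision_recall_f1(pred, ref):
    pred, ref = set(pred), set(ref)
    tp = len(pred & ref)
    p = tp / len(pred) if pred else 0.0
    r = tp / len(ref)
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def connected_components(nodes, edges):
    """Plain union-find component oracle."""
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for u, v in edges:
        parent[find(u)] = find(v)
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return sorted(comps.values(), key=lambda c: sorted(c)[0])
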