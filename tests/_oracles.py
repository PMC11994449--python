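"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths of the package: the transport LP
solves the earth-mover problem directly with scipy.optimize.linprog, the
pair-level coclustering oracle enumerates every unordered pair, and the
relationship oracle walks the tree for every ordered pair.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import jensenshannon
from scipy.stats import pearsonr


def emd_lp(cps_a, masses_a, cps_b, masses_b) -> float:
    """First Wasserstein distance by the transport linear program."""
    a = np.asarray(masses_a, dtype=float)
    b = np.asarray(masses_b, dtype=float)
    a = a / a.sum()
    b = b / b.sum()
    x = np.asarray(cps_a, dtype=float)
    y = np.asarray(cps_b, dtype=float)
    n, m = x.size, y.size
    cost = np.abs(x[:, None] - y[None, :]).ravel()
    a_eq = []
    for i in range(n):  # row sums
        row = np.zeros(n * m)
        row[i * m : (i + 1) * m] = 1.0
        a_eq.append(row)
    for j in range(m):  # column sums
        col = np.zeros(n * m)
        col[j::m] = 1.0
        a_eq.append(col)
    res = linprog(
        cost,
        A_eq=np.vstack(a_eq),
        b_eq=np.concatenate([a, b]),
        bounds=(0, None),
        method="highs",
    )
    assert res.success
    return float(res.fun)


def aupr_by_threshold_enumeration(y_true, y_score) -> float:
    """Area under the precision-recall curve: sum of dR * P over distinct
    score thresholds in decreasing order (ties grouped)."""
    y_true = np.asarray(y_true, dtype=bool)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = y_true.sum()
    assert n_pos > 0
    area = 0.0
    prev_recall = 0.0
    for thr in sorted(np.unique(y_score), reverse=True):
        sel = y_score >= thr
        tp = (y_true & sel).sum()
        precision = tp / sel.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return float(area)


def ajsd_pairwise(pred_cc, truth_cc) -> float:
    """Mean Jensen-Shannon divergence (base 2) over unordered pairs, each pair
    treated as a Bernoulli distribution."""
    n = truth_cc.shape[0]
    vals = []
    for i, j in itertools.combinations(range(n), 2):
        p, q = pred_cc[i, j], truth_cc[i, j]
        vals.append(jensenshannon([p, 1 - p], [q, 1 - q], base=2) ** 2)
    return float(np.mean(vals))


def relation_of(tree: dict[int, int], a: int, b: int) -> str:
    """Relation of cluster a to cluster b in a {cluster: parent} tree."""
    if a == b:
        return "same"

    def ancestors(x):
        out = []
        while tree[x] != 0:
            x = tree[x]
            out.append(x)
        return out

    if a in ancestors(b):
        return "ancestor"
    if b in ancestors(a):
        return "descendant"
    return "cousin"


def relationship_matrices_by_enumeration(tree, labels):
    """Cocluster / ancestor-descendant / cousin matrices, one ordered pair at
    a time."""
    n = len(labels)
    cc = np.eye(n)
    ad = np.zeros((n, n))
    cz = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rel = relation_of(tree, labels[i], labels[j])
            if rel == "same":
                cc[i, j] = 1.0
            elif rel == "ancestor":
                ad[i, j] = 1.0
            elif rel == "cousin":
                cz[i, j] = 1.0
    return cc, ad, cz


def pcc_stacked(truth_mats, pred_mats) -> float:
    """Pearson correlation over the concatenated off-diagonal entries of the
    four relation matrices."""
    n = truth_mats[0].shape[0]
    mask = ~np.eye(n, dtype=bool)

    def stack(mats):
        cc, ad, cz = mats
        return np.concatenate([cc[mask], cz[mask], ad[mask], ad.T[mask]])

    return float(pearsonr(stack(truth_mats), stack(pred_mats))[0])


def best_two_partition(dist: np.ndarray):
    """Exhaustive search for the 2-partition minimizing the mean intra-cluster
    distance over all within-cluster pairs."""
    n = dist.shape[0]
    best, best_val = None, np.inf
    for mask in range(1, 2 ** (n - 1)):  # item 0 always in cluster 0
        groups = [[], []]
        for i in range(n):
            groups[((mask >> (i - 1)) & 1) if i > 0 else 0].append(i)
        if not groups[1]:
            continue
        vals = []
        for g in groups:
            for i, j in itertools.combinations(g, 2):
                vals.append(dist[i, j])
        val = np.mean(vals) if vals else 0.0
        if val < best_val:
            best_val = val
            best = tuple(tuple(g) for g in groups)
    return best, best_val
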