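"""The seven subchallenge metrics and truth/prediction reconciliation.

Subchallenges evaluate successively richer descriptions of a tumor:

* sc1A — tumor purity (scalar);
* sc1B — number of subclonal lineages (integer);
* sc1C — cluster profile: SNV counts and cellular prevalences per subclone;
* sc2A/sc2B — hard / probabilistic SNV coclustering;
* sc3A/sc3B — hard / probabilistic phylogenetic relations between SNVs.

Before scoring, predictions are reconciled to the truth SNV universe: false
negatives (truth SNVs the method never reported) are gathered into a single
cluster with cellular prevalence zero attached to the germline root, and false
positives (reported SNVs absent from the truth) are removed.  Missing outputs
are not penalized here; that policy lives downstream in the ranking layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import wasserstein_distance
from sklearn.metrics import average_precision_score

from hetbench.core import (
    GERMLINE,
    HardAssignment,
    InvalidInputError,
    PhylogenyTruth,
    RelationshipMatrices,
    SoftAssignment,
    build_cocluster,
    build_relationship_matrices,
)

__all__ = [
    "ClusterProfile",
    "SubcloneCountPair",
    "MetricBreakdown",
    "profile_from_truth",
    "reconcile_prediction",
    "reconcile_profile",
    "reconcile_hard",
    "reconcile_soft",
    "reconcile_cocluster",
    "reconcile_tree",
    "reconcile_relationship_matrices",
    "score_1a",
    "score_1b",
    "score_1c",
    "score_2",
    "score_3",
]

_EPS = 1e-12


@dataclass
class ClusterProfile:
    """Per-cluster SNV counts and cellular prevalences (the sc1C object).

    ``clusters`` is a list of ``(cluster_id, n_ssms, cp)`` tuples.  SNV mass is
    normalized to one before any distance computation, so only the relative
    cluster sizes matter.
    """

    clusters: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        if not self.clusters:
            raise InvalidInputError("cluster profile must contain at least one cluster")
        for cid, n, cp in self.clusters:
            if n < 0:
                raise InvalidInputError(f"cluster {cid}: negative SNV count")
            if not (-1e-9 <= cp <= 1 + 1e-9):
                raise InvalidInputError(f"cluster {cid}: cp {cp} outside [0, 1]")
        if self.total_ssms <= 0:
            raise InvalidInputError("cluster profile has zero total SNV mass")

    @property
    def total_ssms(self) -> int:
        return sum(n for _, n, _ in self.clusters)

    @property
    def cps(self) -> np.ndarray:
        return np.asarray([cp for _, _, cp in self.clusters], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        n = np.asarray([m for _, m, _ in self.clusters], dtype=float)
        return n / n.sum()


@dataclass(frozen=True)
class SubcloneCountPair:
    """True lineage count L, predicted count kappa, and the capped difference."""

    L: int
    kappa: int

    @property
    def d(self) -> int:
        return min(abs(self.kappa - self.L), self.L + 1)


@dataclass
class MetricBreakdown:
    """Final metric value plus its intermediate components.

    Only the components relevant to the metric at hand are populated: ``emd``
    for sc1C, the AUPR/AJSD quartet for sc2, ``pcc`` for sc3.  ``degenerate``
    flags scores that were pinned by a zero-variance or anchor-collapse rule.
    """

    score: float
    emd: float | None = None
    aupr_raw: float | None = None
    aupr_norm: float | None = None
    ajsd_raw: float | None = None
    ajsd_norm: float | None = None
    pcc: float | None = None
    degenerate: bool = False


def profile_from_truth(truth: PhylogenyTruth) -> ClusterProfile:
    """Cluster profile of a truth tree (cluster id, SNV count, CP per node)."""
    return ClusterProfile([(s.id, s.n_ssms, s.cp) for s in truth.subclones])


# ---------------------------------------------------------------------------
# reconciliation
# ---------------------------------------------------------------------------

def _split_ids(pred_snv_ids: Sequence, truth_snv_ids: Sequence):
    pred_set = set(pred_snv_ids)
    truth_list = list(truth_snv_ids)
    shared = [s for s in truth_list if s in pred_set]
    fn = [s for s in truth_list if s not in pred_set]
    if not shared:
        raise InvalidInputError("prediction covers none of the truth SNVs")
    pos = {s: i for i, s in enumerate(pred_snv_ids)}
    keep_idx = np.asarray([pos[s] for s in shared])
    return shared, fn, keep_idx


def reconcile_profile(
    profile: ClusterProfile,
    pred_snv_ids: Sequence,
    truth_snv_ids: Sequence,
    labels: Sequence | None = None,
) -> ClusterProfile:
    """Reconcile an sc1C profile to the truth SNV set.

    With per-SNV ``labels`` (aligned with ``pred_snv_ids``) false positives are
    removed from their own clusters; without labels the removed mass is spread
    across clusters proportionally (largest-remainder rounding).  All false
    negatives land in one new cluster at CP 0.
    """
    shared, fn, keep_idx = _split_ids(pred_snv_ids, truth_snv_ids)
    n_fp = len(pred_snv_ids) - len(shared)
    clusters = [list(c) for c in profile.clusters]
    if n_fp > 0:
        if labels is not None:
            labels = list(labels)
            kept = set(keep_idx.tolist())
            drop_per_cluster: dict = {}
            for i, lab in enumerate(labels):
                if i not in kept:
                    drop_per_cluster[lab] = drop_per_cluster.get(lab, 0) + 1
            for c in clusters:
                c[1] -= drop_per_cluster.get(c[0], 0)
        else:
            counts = np.asarray([c[1] for c in clusters], dtype=float)
            target = counts / counts.sum() * (counts.sum() - n_fp)
            floor = np.floor(target).astype(int)
            rem = int(round(target.sum() - floor.sum()))
            order = np.argsort(-(target - floor))
            floor[order[:rem]] += 1
            for c, new in zip(clusters, floor):
                c[1] = int(new)
        clusters = [c for c in clusters if c[1] > 0]
    if fn:
        new_id = max(c[0] for c in clusters) + 1 if clusters else 1
        clusters.append([new_id, len(fn), 0.0])
    return ClusterProfile([tuple(c) for c in clusters])


def reconcile_hard(
    pred: HardAssignment, pred_snv_ids: Sequence, truth_snv_ids: Sequence
) -> tuple[HardAssignment, int | None]:
    """Reconcile a hard assignment; returns the assignment over truth SNV
    order and the label of the zero-CP false-negative cluster (or None)."""
    shared, fn, keep_idx = _split_ids(pred_snv_ids, truth_snv_ids)
    kept = pred.labels[keep_idx]
    fn_label = None
    if fn:
        fn_label = int(np.max(kept)) + 1
    by_id = dict(zip(shared, kept))
    out = np.asarray(
        [by_id[s] if s in by_id else fn_label for s in truth_snv_ids]
    )
    return HardAssignment(out), fn_label


def reconcile_soft(
    pred: SoftAssignment, pred_snv_ids: Sequence, truth_snv_ids: Sequence
) -> SoftAssignment:
    """Reconcile a soft assignment: FN SNVs get probability 1 in a new column."""
    shared, fn, keep_idx = _split_ids(pred_snv_ids, truth_snv_ids)
    w = pred.weights[keep_idx]
    if fn:
        w = np.hstack([w, np.zeros((w.shape[0], 1))])
        fn_rows = np.zeros((len(fn), w.shape[1]))
        fn_rows[:, -1] = 1.0
        by_pos = {s: i for i, s in enumerate(shared)}
        rows = []
        j = 0
        for s in truth_snv_ids:
            if s in by_pos:
                rows.append(w[by_pos[s]])
            else:
                rows.append(fn_rows[j])
                j += 1
        w = np.vstack(rows)
    return SoftAssignment(w)


def reconcile_cocluster(
    mat: np.ndarray, pred_snv_ids: Sequence, truth_snv_ids: Sequence
) -> np.ndarray:
    """Reconcile a cocluster probability matrix to the truth SNV order.

    FP rows/columns are removed; FN SNVs form one new cluster: probability 1
    among themselves, 0 against everything else.
    """
    shared, fn, keep_idx = _split_ids(pred_snv_ids, truth_snv_ids)
    sub = np.asarray(mat, dtype=float)[np.ix_(keep_idx, keep_idx)]
    return _embed_blocks(sub, shared, fn, truth_snv_ids, fn_self=1.0)


def _embed_blocks(sub, shared, fn, truth_snv_ids, fn_self):
    n = len(truth_snv_ids)
    out = np.zeros((n, n))
    pos = {s: i for i, s in enumerate(truth_snv_ids)}
    sh = np.asarray([pos[s] for s in shared])
    out[np.ix_(sh, sh)] = sub
    if fn:
        fi = np.asarray([pos[s] for s in fn])
        out[np.ix_(fi, fi)] = fn_self
    np.fill_diagonal(out, 1.0)
    return out


def reconcile_tree(
    tree: dict[int, int],
    pred: HardAssignment,
    pred_snv_ids: Sequence,
    truth_snv_ids: Sequence,
) -> tuple[dict[int, int], HardAssignment]:
    """Reconcile an sc3A prediction (tree + hard assignment).

    The FN cluster is attached as a leaf child of the germline sentinel, so
    its SNVs are cousins of every somatic prediction.
    """
    assign, fn_label = reconcile_hard(pred, pred_snv_ids, truth_snv_ids)
    tree = dict(tree)
    if fn_label is not None:
        new_label = fn_label
        while new_label in tree:  # avoid clobbering an existing cluster id
            new_label += 1
        if new_label != fn_label:
            assign = HardAssignment(
                np.where(assign.labels == fn_label, new_label, assign.labels)
            )
            fn_label = new_label
        tree[fn_label] = GERMLINE
    return tree, assign


def reconcile_relationship_matrices(
    matrices: RelationshipMatrices, pred_snv_ids: Sequence, truth_snv_ids: Sequence
) -> RelationshipMatrices:
    """Reconcile submitted sc3B matrices: FN SNVs cocluster among themselves
    and are cousins of all other SNVs (their clone descends from the normal)."""
    shared, fn, keep_idx = _split_ids(pred_snv_ids, truth_snv_ids)
    ix = np.ix_(keep_idx, keep_idx)
    cc = _embed_blocks(matrices.cocluster[ix], shared, fn, truth_snv_ids, fn_self=1.0)
    n = len(truth_snv_ids)
    pos = {s: i for i, s in enumerate(truth_snv_ids)}
    sh = np.asarray([pos[s] for s in shared])
    ad = np.zeros((n, n))
    ad[np.ix_(sh, sh)] = matrices.ancestor_descendant[ix]
    cousin = np.zeros((n, n))
    cousin[np.ix_(sh, sh)] = matrices.cousin[ix]
    if fn:
        fi = np.asarray([pos[s] for s in fn])
        cousin[np.ix_(fi, sh)] = 1.0
        cousin[np.ix_(sh, fi)] = 1.0
    np.fill_diagonal(cousin, 0.0)
    np.fill_diagonal(ad, 0.0)
    return RelationshipMatrices(cc, ad, cousin)


def reconcile_prediction(pred, truth: PhylogenyTruth, pred_snv_ids: Sequence, labels=None):
    """Reconcile any subchallenge prediction to the truth SNV universe.

    Dispatches on the prediction type: cluster profiles, hard/soft
    assignments, cocluster matrices (2-D arrays), relationship-matrix
    bundles, or ``(tree, HardAssignment)`` pairs.
    """
    tids = truth.snv_ids
    if isinstance(pred, ClusterProfile):
        return reconcile_profile(pred, pred_snv_ids, tids, labels=labels)
    if isinstance(pred, HardAssignment):
        return reconcile_hard(pred, pred_snv_ids, tids)[0]
    if isinstance(pred, SoftAssignment):
        return reconcile_soft(pred, pred_snv_ids, tids)
    if isinstance(pred, RelationshipMatrices):
        return reconcile_relationship_matrices(pred, pred_snv_ids, tids)
    if isinstance(pred, np.ndarray) and pred.ndim == 2:
        return reconcile_cocluster(pred, pred_snv_ids, tids)
    if isinstance(pred, tuple) and len(pred) == 2:
        return reconcile_tree(pred[0], pred[1], pred_snv_ids, tids)
    raise InvalidInputError(f"cannot reconcile prediction of type {type(pred)!r}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def score_1a(rho: float, c: float) -> float:
    """Purity score: 1 - |rho - c|, both arguments in [0, 1]."""
    if not (0.0 <= rho <= 1.0) or not (0.0 <= c <= 1.0):
        raise InvalidInputError(f"purities must lie in [0, 1], got rho={rho}, c={c}")
    return 1.0 - abs(rho - c)


def score_1b(L: int, kappa: int) -> float:
    """Subclone-count score: (L - d + 1) / (L + 1), d = min(|kappa - L|, L + 1).

    The cap on d keeps the score non-negative for arbitrarily bad guesses.
    """
    if L < 1:
        raise InvalidInputError(f"true lineage count L must be >= 1, got {L}")
    if kappa < 0:
        raise InvalidInputError(f"predicted count must be >= 0, got {kappa}")
    d = SubcloneCountPair(L, kappa).d
    return (L - d + 1) / (L + 1)


def score_1c(truth: ClusterProfile, pred: ClusterProfile) -> MetricBreakdown:
    """Cluster-profile score: 1 - EMD between the SNV-mass distributions.

    EMD is the first Wasserstein distance between the two discrete
    distributions of SNV mass over cellular prevalence with ground distance
    |x - y| on [0, 1]; it equals the integrated absolute difference of the two
    CDFs and is bounded by 1 on the unit interval, so the score is in [0, 1].
    """
    emd = float(
        wasserstein_distance(truth.cps, pred.cps, truth.masses, pred.masses)
    )
    return MetricBreakdown(score=1.0 - emd, emd=emd)


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, 1.0)
    out = np.zeros_like(p)
    for q in (p, 1.0 - p):
        nz = q > 0
        out[nz] -= q[nz] * np.log2(q[nz])
    return out


def _pair_jsd(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Jensen-Shannon divergence (base 2) between Bernoulli(p) and Bernoulli(q)."""
    m = 0.5 * (p + q)
    return _binary_entropy(m) - 0.5 * (_binary_entropy(p) + _binary_entropy(q))


def _aupr(y_true: np.ndarray, y_score: np.ndarray) -> float:
    if y_true.all():
        return 1.0  # every pair is positive: any ranking attains precision 1
    if not y_true.any():
        # no positive pair exists; a prediction is perfect iff it claims none
        return 1.0 if np.all(y_score < _EPS) else 0.0
    return float(average_precision_score(y_true, y_score))


def score_2(
    truth: HardAssignment,
    pred: HardAssignment | SoftAssignment | np.ndarray,
) -> MetricBreakdown:
    """Coclustering score: mean of normalized AUPR and normalized AJSD.

    Both components are computed on the unordered off-diagonal SNV pairs of
    the predicted versus true cocluster matrices.  AUPR is the area under the
    precision-recall curve treating true copairings as positives; AJSD is the
    average per-pair Jensen-Shannon divergence (base 2) between the Bernoulli
    coclustering probabilities.  Each component is rescaled so that a perfect
    prediction maps to 1 and the worse of two extreme references — all SNVs in
    one cluster, and one SNV per cluster — maps to 0, clamped below at 0.
    """
    truth_cc = build_cocluster(truth)
    if isinstance(pred, (HardAssignment, SoftAssignment)):
        pred_cc = build_cocluster(pred)
    else:
        pred_cc = np.asarray(pred, dtype=float)
    n = truth_cc.shape[0]
    if pred_cc.shape != (n, n):
        raise InvalidInputError(
            f"prediction covers {pred_cc.shape[0]} SNVs but truth has {n}; reconcile first"
        )
    iu = np.triu(np.ones((n, n), dtype=bool), k=1)
    t = truth_cc[iu]
    p = np.clip(pred_cc[iu], 0.0, 1.0)
    y = t > 0.5

    aupr_raw = _aupr(y, p)
    ajsd_raw = float(np.mean(_pair_jsd(p, t)))

    # extreme references: one big cluster (all ones) and all singletons (all zeros)
    ones = np.ones_like(t)
    zeros = np.zeros_like(t)
    worst_aupr = min(_aupr(y, ones), _aupr(y, zeros))
    worst_ajsd = max(
        float(np.mean(_pair_jsd(ones, t))), float(np.mean(_pair_jsd(zeros, t)))
    )

    degenerate = False
    if worst_aupr >= 1.0 - _EPS:
        aupr_norm = 1.0 if aupr_raw >= 1.0 - _EPS else 0.0
        degenerate = True
    else:
        aupr_norm = max(0.0, (aupr_raw - worst_aupr) / (1.0 - worst_aupr))
    if worst_ajsd <= _EPS:
        ajsd_norm = 1.0 if ajsd_raw <= _EPS else 0.0
        degenerate = True
    else:
        ajsd_norm = max(0.0, (worst_ajsd - ajsd_raw) / worst_ajsd)

    return MetricBreakdown(
        score=0.5 * (aupr_norm + ajsd_norm),
        aupr_raw=aupr_raw,
        aupr_norm=aupr_norm,
        ajsd_raw=ajsd_raw,
        ajsd_norm=ajsd_norm,
        degenerate=degenerate,
    )


def score_3(
    truth: PhylogenyTruth | RelationshipMatrices,
    pred: RelationshipMatrices,
) -> MetricBreakdown:
    """Phylogeny score: one Pearson correlation over the stacked off-diagonal
    entries of the four relation matrices (cocluster, cousin,
    ancestor-descendant and its transpose) of prediction versus truth.

    Zero variance in either stacked vector yields a score of 0, flagged as
    degenerate.
    """
    truth_m = (
        build_relationship_matrices(truth)
        if isinstance(truth, PhylogenyTruth)
        else truth
    )
    if pred.n_snvs != truth_m.n_snvs:
        raise InvalidInputError(
            f"prediction covers {pred.n_snvs} SNVs but truth has {truth_m.n_snvs}; reconcile first"
        )
    n = truth_m.n_snvs
    # Pearson over the stacked off-diagonal entries of the four matrices,
    # accumulated by streaming sums: no giant concatenated vectors.  The
    # transposed ancestor-descendant block contributes the same entrywise
    # sums as the untransposed one, so it enters with weight 2.
    cnt = 4.0 * n * (n - 1)
    sx = sy = sxx = syy = sxy = 0.0
    blocks = [
        (truth_m.cocluster, pred.cocluster, 1.0),     # (X, Y, weight)
        (truth_m.cousin, pred.cousin, 1.0),
        (truth_m.ancestor_descendant, pred.ancestor_descendant, 2.0),
    ]
    for x_mat, y_mat, w in blocks:
        dx, dy = np.diag(x_mat), np.diag(y_mat)
        sx += w * (x_mat.sum() - dx.sum())
        sy += w * (y_mat.sum() - dy.sum())
        sxx += w * (np.einsum("ij,ij->", x_mat, x_mat) - dx @ dx)
        syy += w * (np.einsum("ij,ij->", y_mat, y_mat) - dy @ dy)
        sxy += w * (np.einsum("ij,ij->", x_mat, y_mat) - dx @ dy)
    var_x = sxx - sx * sx / cnt
    var_y = syy - sy * sy / cnt
    if var_x <= cnt * _EPS**2 or var_y <= cnt * _EPS**2:
        return MetricBreakdown(score=0.0, pcc=0.0, degenerate=True)
    pcc = float((sxy - sx * sy / cnt) / np.sqrt(var_x * var_y))
    pcc = max(-1.0, min(1.0, pcc))
    return MetricBreakdown(score=pcc, pcc=pcc)
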