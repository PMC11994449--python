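"""In-memory bundle of one algorithm's outputs across all seven subchallenges,
plus the convenience routine that reconciles and scores the whole bundle
against a truth tree."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hetbench.core import (
    GERMLINE,
    HardAssignment,
    PhylogenyTruth,
    RelationshipMatrices,
    SoftAssignment,
    build_relationship_matrices,
)
from hetbench import scoring

SUBCHALLENGES = ("1A", "1B", "1C", "2A", "2B", "3A", "3B")


@dataclass
class PredictionSet:
    """Outputs of one algorithm on one tumor.

    Any field may be None (a missing output); ``snv_ids`` gives the SNV
    universe the per-SNV outputs refer to, in file order.
    """

    snv_ids: list = field(default_factory=list)
    purity: float | None = None          # sc1A
    n_clusters: int | None = None        # sc1B
    profile: "scoring.ClusterProfile | None" = None  # sc1C
    assignment: HardAssignment | None = None         # sc2A (order = snv_ids)
    cocluster: np.ndarray | None = None              # sc2B probability matrix
    tree: dict[int, int] | None = None               # sc3A {cluster: parent}
    matrices: RelationshipMatrices | None = None     # sc3B
    #: derive the dense 2B/3B objects on demand from the hard outputs instead
    #: of storing O(N^2) arrays per prediction (memory: a cohort holds many)
    cocluster_from_assignment: bool = False
    matrices_from_tree: bool = False

    def get_cocluster(self) -> np.ndarray | None:
        if self.cocluster is not None:
            return self.cocluster
        if self.cocluster_from_assignment and self.assignment is not None:
            lab = self.assignment.labels
            return (lab[:, None] == lab[None, :]).astype(float)
        return None

    def get_matrices(self) -> RelationshipMatrices | None:
        if self.matrices is not None:
            return self.matrices
        if (
            self.matrices_from_tree
            and self.tree is not None
            and self.assignment is not None
        ):
            return build_relationship_matrices(self.tree, self.assignment)
        return None

    def available(self) -> list[str]:
        out = []
        if self.purity is not None:
            out.append("1A")
        if self.n_clusters is not None:
            out.append("1B")
        if self.profile is not None:
            out.append("1C")
        if self.assignment is not None:
            out.append("2A")
        if self.cocluster is not None or self.cocluster_from_assignment:
            out.append("2B")
        if self.tree is not None and self.assignment is not None:
            out.append("3A")
        if self.matrices is not None or (
            self.matrices_from_tree and self.tree is not None
        ):
            out.append("3B")
        return out


def score_prediction_set(
    truth: PhylogenyTruth, pred: PredictionSet
) -> dict[str, float]:
    """Reconcile and score one prediction bundle; returns subchallenge -> score.

    Missing outputs are simply absent from the result (not scored as zero).
    """
    out: dict[str, float] = {}
    tids = truth.snv_ids
    if pred.purity is not None:
        out["1A"] = scoring.score_1a(truth.purity, pred.purity)
    if pred.n_clusters is not None:
        out["1B"] = scoring.score_1b(truth.n_subclones, pred.n_clusters)
    if pred.profile is not None:
        labels = (
            list(pred.assignment.labels)
            if pred.assignment is not None and pred.assignment.n_snvs == len(pred.snv_ids)
            else None
        )
        rp = scoring.reconcile_profile(pred.profile, pred.snv_ids, tids, labels=labels)
        out["1C"] = scoring.score_1c(scoring.profile_from_truth(truth), rp).score
    truth_hard = truth.hard_assignment()
    if pred.assignment is not None:
        ra, _ = scoring.reconcile_hard(pred.assignment, pred.snv_ids, tids)
        out["2A"] = scoring.score_2(truth_hard, ra).score
    cc = pred.get_cocluster()
    if cc is not None:
        rc = scoring.reconcile_cocluster(cc, pred.snv_ids, tids)
        out["2B"] = scoring.score_2(truth_hard, rc).score
        del cc, rc
    want_3a = pred.tree is not None and pred.assignment is not None
    mats = pred.get_matrices()
    if want_3a or mats is not None:
        truth_m = build_relationship_matrices(truth)  # shared by 3A and 3B
        if want_3a:
            rt, rta = scoring.reconcile_tree(
                pred.tree, pred.assignment, pred.snv_ids, tids
            )
            out["3A"] = scoring.score_3(truth_m, build_relationship_matrices(rt, rta)).score
        if mats is not None:
            rm = scoring.reconcile_relationship_matrices(mats, pred.snv_ids, tids)
            out["3B"] = scoring.score_3(truth_m, rm).score
    return out


def perfect_prediction(truth: PhylogenyTruth) -> PredictionSet:
    """The truth re-expressed as a prediction bundle (scores 1 everywhere)."""
    return PredictionSet(
        snv_ids=list(truth.snv_ids),
        purity=truth.purity,
        n_clusters=truth.n_subclones,
        profile=scoring.profile_from_truth(truth),
        assignment=truth.hard_assignment(),
        tree=dict(truth.parent_map),
        cocluster_from_assignment=True,
        matrices_from_tree=True,
    )
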