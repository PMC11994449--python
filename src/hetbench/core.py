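"""Domain types for tumor phylogenies and the pairwise SNV relationship matrices.

A single-sample subclonal reconstruction is described by a rooted clone tree.
Each node (subclone) carries a cellular prevalence (CP): the fraction of all
sampled cells — tumor plus contaminating normal — that belong to the clone or
any of its descendants.  The germline "normal" root is a sentinel (id 0) that
never holds somatic SNVs; the clonal (truncal) node is its child and has
CP equal to the tumor purity.  Single-sample trees must obey the pigeonhole
principle: the CPs of a node's children cannot sum beyond the node's own CP.

Pairwise evaluation of mutation placements uses three SNV-by-SNV matrices:

* ``cocluster``            — probability two SNVs sit in the same subclone;
* ``ancestor_descendant``  — entry (i, j): probability the clone of SNV i is a
  strict ancestor of the clone of SNV j;
* ``cousin``               — probability the two clones are unrelated by
  descent (siblings or further removed).

For hard assignments the four relations (cocluster, ancestor, descendant,
cousin) partition every ordered off-diagonal pair, so the matrices sum to the
all-ones matrix off the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Sentinel cluster id for the germline root ("normal"); never holds SNVs.
GERMLINE = 0


class HetbenchError(Exception):
    """Base class for all package errors."""


class InvalidInputError(HetbenchError, ValueError):
    """An argument violates a documented precondition."""


class MalformedTreeError(HetbenchError, ValueError):
    """A clone tree has a cycle, an orphan cluster, or breaks pigeonhole."""


@dataclass(frozen=True)
class Subclone:
    """One node of a clone tree.

    Parameters
    ----------
    id : int
        Positive cluster label.
    parent_id : int
        Label of the parent node, or ``GERMLINE`` (0) for the clonal node.
    cp : float
        Cellular prevalence in [0, 1] (fraction of all sampled cells).
    n_ssms : int
        Number of somatic SNVs assigned to this node.
    """

    id: int
    parent_id: int
    cp: float
    n_ssms: int = 0

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise InvalidInputError(f"subclone id must be positive, got {self.id}")
        if not (0.0 <= self.cp <= 1.0 + 1e-12):
            raise InvalidInputError(f"cp must lie in [0, 1], got {self.cp}")
        if self.n_ssms < 0:
            raise InvalidInputError(f"n_ssms must be non-negative, got {self.n_ssms}")


@dataclass
class PhylogenyTruth:
    """Ground truth for one simulated tumor.

    Attributes
    ----------
    purity : float
        Fraction rho of sampled cells that are tumor cells, in (0, 1].
    subclones : list of Subclone
        Nodes of the rooted clone tree (germline sentinel excluded).
    assignment : dict
        SNV id -> subclone id; every SNV maps to exactly one node.
    """

    purity: float
    subclones: list[Subclone]
    assignment: dict[object, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure helpers ------------------------------------------------
    @property
    def ids(self) -> list[int]:
        return [s.id for s in self.subclones]

    @property
    def parent_map(self) -> dict[int, int]:
        return {s.id: s.parent_id for s in self.subclones}

    @property
    def clonal_id(self) -> int:
        """Id of the truncal node (the unique child of the germline root)."""
        roots = [s.id for s in self.subclones if s.parent_id == GERMLINE]
        return roots[0]

    @property
    def snv_ids(self) -> list:
        """SNV ids in insertion (file) order — the binding index for matrices."""
        return list(self.assignment)

    @property
    def n_snvs(self) -> int:
        return len(self.assignment)

    @property
    def n_subclones(self) -> int:
        return len(self.subclones)

    def children(self, node_id: int) -> list[int]:
        return [s.id for s in self.subclones if s.parent_id == node_id]

    def hard_assignment(self) -> "HardAssignment":
        """Per-SNV cluster labels in ``snv_ids`` order."""
        return HardAssignment(np.asarray([self.assignment[s] for s in self.snv_ids]))

    def validate(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise InvalidInputError(f"purity must lie in (0, 1], got {self.purity}")
        ids = self.ids
        if len(ids) != len(set(ids)):
            raise MalformedTreeError("duplicate subclone ids")
        idset = set(ids)
        by_id = {s.id: s for s in self.subclones}
        roots = [s for s in self.subclones if s.parent_id == GERMLINE]
        if len(roots) != 1:
            raise MalformedTreeError(
                f"expected exactly one clonal node under the germline root, got {len(roots)}"
            )
        if abs(roots[0].cp - self.purity) > 1e-6:
            raise MalformedTreeError(
                f"clonal CP {roots[0].cp} must equal purity {self.purity}"
            )
        for s in self.subclones:
            if s.parent_id != GERMLINE and s.parent_id not in idset:
                raise MalformedTreeError(f"subclone {s.id} has unknown parent {s.parent_id}")
        _check_acyclic({s.id: s.parent_id for s in self.subclones})
        # pigeonhole: children CPs cannot sum beyond the parent's CP
        for s in self.subclones:
            child_sum = sum(c.cp for c in self.subclones if c.parent_id == s.id)
            if child_sum > s.cp + 1e-6:
                raise MalformedTreeError(
                    f"pigeonhole violation at node {s.id}: children CP sum "
                    f"{child_sum:.6g} exceeds parent CP {s.cp:.6g}"
                )
        for snv, cl in self.assignment.items():
            if cl not in idset:
                raise MalformedTreeError(f"SNV {snv!r} assigned to unknown cluster {cl}")
        counted = {s.id: s.n_ssms for s in self.subclones}
        tallied: dict[int, int] = {i: 0 for i in idset}
        for cl in self.assignment.values():
            tallied[cl] += 1
        if self.assignment and any(counted[i] != tallied[i] for i in idset):
            raise MalformedTreeError("n_ssms fields disagree with the assignment map")
        del by_id


def _check_acyclic(parents: Mapping[int, int]) -> None:
    for start in parents:
        seen = {start}
        node = start
        while node != GERMLINE:
            node = parents[node]
            if node in seen:
                raise MalformedTreeError(f"cycle through node {start}")
            seen.add(node)


@dataclass
class HardAssignment:
    """Hard SNV-to-cluster assignment: one label per SNV."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise InvalidInputError("labels must be a non-empty 1-D vector")

    @property
    def n_snvs(self) -> int:
        return self.labels.size

    @property
    def n_clusters(self) -> int:
        return np.unique(self.labels).size

    def canonicalize(self) -> "HardAssignment":
        """Relabel clusters to 1-based contiguous ints, stable in first appearance."""
        mapping: dict = {}
        out = np.empty(self.labels.size, dtype=np.int64)
        for i, lab in enumerate(self.labels):
            if lab not in mapping:
                mapping[lab] = len(mapping) + 1
            out[i] = mapping[lab]
        return HardAssignment(out)


@dataclass
class SoftAssignment:
    """Soft SNV-to-cluster assignment: rows are per-SNV cluster probabilities."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.size == 0:
            raise InvalidInputError("weights must be a non-empty 2-D matrix")
        if np.any(self.weights < -1e-12) or np.any(self.weights > 1 + 1e-12):
            raise InvalidInputError("soft weights must lie in [0, 1]")
        rows = self.weights.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-8):
            raise InvalidInputError("soft assignment rows must sum to 1 (tol 1e-8)")

    @property
    def n_snvs(self) -> int:
        return self.weights.shape[0]


@dataclass
class RelationshipMatrices:
    """The cocluster / ancestor-descendant / cousin matrices for a set of SNVs.

    For hard inputs the off-diagonal identity
    ``cocluster + ad + ad.T + cousin == 1`` holds entrywise.
    """

    cocluster: np.ndarray
    ancestor_descendant: np.ndarray
    cousin: np.ndarray

    def __post_init__(self) -> None:
        n = self.cocluster.shape[0]
        for m in (self.cocluster, self.ancestor_descendant, self.cousin):
            if m.shape != (n, n):
                raise InvalidInputError("relationship matrices must share a square shape")

    @property
    def n_snvs(self) -> int:
        return self.cocluster.shape[0]

    def stacked_off_diagonal(self) -> np.ndarray:
        """Concatenated off-diagonal entries of the four relation matrices.

        Order: cocluster, cousin, ancestor-descendant, transposed
        ancestor-descendant.  The diagonal is excluded from scoring.
        """
        n = self.n_snvs
        mask = ~np.eye(n, dtype=bool)
        return np.concatenate(
            [
                self.cocluster[mask],
                self.cousin[mask],
                self.ancestor_descendant[mask],
                self.ancestor_descendant.T[mask],
            ]
        )

    @classmethod
    def from_soft(
        cls, cocluster: np.ndarray, ancestor_descendant: np.ndarray
    ) -> "RelationshipMatrices":
        """Build from submitted probability matrices, deriving the cousin matrix.

        The cousin probability is whatever mass the three descent relations do
        not account for, clamped to [0, 1].
        """
        cc = np.asarray(cocluster, dtype=float)
        ad = np.asarray(ancestor_descendant, dtype=float)
        cousin = np.clip(1.0 - cc - ad - ad.T, 0.0, 1.0)
        np.fill_diagonal(cousin, 0.0)
        return cls(cc, ad, cousin)


def build_cocluster(assignment: HardAssignment | SoftAssignment) -> np.ndarray:
    """Pairwise coclustering matrix of an assignment.

    Hard: entry (i, j) is 1 iff SNVs i and j share a label.  Soft: entry is
    the probability the two SNVs land in the same cluster, i.e. the dot
    product of their weight rows.  The diagonal is fixed at 1.
    """
    if isinstance(assignment, HardAssignment):
        lab = assignment.labels
        mat = (lab[:, None] == lab[None, :]).astype(float)
    elif isinstance(assignment, SoftAssignment):
        w = assignment.weights
        mat = np.clip(w @ w.T, 0.0, 1.0)
    else:
        raise InvalidInputError(f"unsupported assignment type {type(assignment)!r}")
    np.fill_diagonal(mat, 1.0)
    return mat


def _ancestor_table(parents: Mapping[int, int]) -> dict[int, set[int]]:
    """node id -> set of strict somatic ancestors (germline excluded)."""
    out: dict[int, set[int]] = {}
    for node in parents:
        anc: set[int] = set()
        p = parents[node]
        while p != GERMLINE:
            if p in anc:
                raise MalformedTreeError(f"cycle above node {node}")
            anc.add(p)
            p = parents[p]
        out[node] = anc
    return out


def build_relationship_matrices(
    truth_or_tree: PhylogenyTruth | Mapping[int, int],
    assignment: HardAssignment | None = None,
) -> RelationshipMatrices:
    """Relationship matrices of a clone tree plus a hard assignment.

    Parameters
    ----------
    truth_or_tree : PhylogenyTruth or mapping
        Either a full truth object, or a ``{cluster_id: parent_id}`` map using
        ``GERMLINE`` (0) for roots, paired with ``assignment``.
    assignment : HardAssignment, optional
        Per-SNV cluster labels; required with a bare tree mapping.

    Multi-root trees are accepted for predictions: every parentless cluster is
    treated as a child of the germline sentinel.
    """
    if isinstance(truth_or_tree, PhylogenyTruth):
        parents = truth_or_tree.parent_map
        labels = truth_or_tree.hard_assignment().labels
    else:
        if assignment is None:
            raise InvalidInputError("assignment required when passing a bare tree")
        parents = dict(truth_or_tree)
        labels = assignment.labels
    for lab in np.unique(labels):
        if lab not in parents:
            raise MalformedTreeError(f"SNV assigned to cluster {lab} absent from tree")
    anc = _ancestor_table(parents)

    clusters = sorted(parents)
    index = {c: k for k, c in enumerate(clusters)}
    k = len(clusters)
    is_anc = np.zeros((k, k), dtype=float)  # (a, b): a strict ancestor of b
    for b in clusters:
        for a in anc[b]:
            is_anc[index[a], index[b]] = 1.0

    li = np.asarray([index[l] for l in labels])
    same = (li[:, None] == li[None, :]).astype(float)
    ad = is_anc[li[:, None], li[None, :]]
    cousin = 1.0 - same - ad - ad.T
    np.fill_diagonal(same, 1.0)
    np.fill_diagonal(ad, 0.0)
    np.fill_diagonal(cousin, 0.0)
    if cousin.min() < -1e-9:
        raise MalformedTreeError("inconsistent tree: relation probabilities exceed 1")
    return RelationshipMatrices(same, ad, np.clip(cousin, 0.0, 1.0))
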