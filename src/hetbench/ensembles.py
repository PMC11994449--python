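"""Consensus subclonal reconstruction across multiple algorithm outputs.

Scalar outputs are combined by (floor-of-)medians.  Cluster profiles are
combined by WeMe: each profile becomes a CDF of SNV mass over cellular
prevalence, the consensus is the pointwise weighted median of the inverse
CDFs on a shared mass-quantile grid, and consensus clusters are read off the
steps of the resulting quantile function.  Hard assignments are combined by
CICC: average-linkage hierarchical clustering of the across-method
coassignment distance, cut at a target cluster count.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from hetbench.core import HardAssignment, InvalidInputError
from hetbench.scoring import ClusterProfile

__all__ = [
    "EnsembleRun",
    "ensemble_1a",
    "ensemble_1b",
    "weme_consensus",
    "cicc_consensus",
    "combination_protocol",
]


from dataclasses import dataclass


@dataclass
class EnsembleRun:
    """Book-keeping for one consensus computation: which methods went in,
    which combination id it was, and the consensus output."""

    inputs: list
    combination_id: tuple
    output: object = None

    def __post_init__(self) -> None:
        if not self.inputs:
            raise InvalidInputError("an ensemble run needs at least one input")


def ensemble_1a(purities: Sequence[float]) -> float:
    """Consensus purity: the sample median of the inputs."""
    if len(purities) == 0:
        raise InvalidInputError("no purities to combine")
    return float(np.median(purities))


def ensemble_1b(counts: Sequence[int]) -> int:
    """Consensus subclone count: the floor of the median."""
    if len(counts) == 0:
        raise InvalidInputError("no counts to combine")
    return int(math.floor(np.median(counts)))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median; an exact half-mass tie averages the bracketing values."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w)
    half = 0.5 * cum[-1]
    i = int(np.searchsorted(cum, half))
    if abs(cum[i] - half) < 1e-12 and i + 1 < len(v):
        return 0.5 * (v[i] + v[i + 1])
    return float(v[i])


def weme_consensus(
    profiles: Sequence[ClusterProfile],
    weights: Sequence[float] | None = None,
    n_quantiles: int = 1001,
    total_ssms: int | None = None,
) -> ClusterProfile:
    """Weighted-median consensus of cluster profiles (WeMe).

    Each profile's quantile function (CP at a given cumulative SNV-mass
    fraction) is evaluated on ``n_quantiles`` evenly spaced mass quantiles;
    the consensus quantile function is the pointwise weighted median across
    methods.  Its steps become the consensus clusters; per-cluster mass is
    converted back to SNV counts summing to ``total_ssms`` (default: the
    median of the input totals) by largest-remainder rounding.
    """
    if len(profiles) == 0:
        raise InvalidInputError("no profiles to combine")
    m = len(profiles)
    w = np.full(m, 1.0 / m) if weights is None else np.asarray(weights, dtype=float)
    if w.size != m or np.any(w < 0) or w.sum() <= 0:
        raise InvalidInputError("weights must be non-negative with positive sum")

    q = (np.arange(n_quantiles) + 0.5) / n_quantiles
    quantile_values = np.empty((m, n_quantiles))
    for j, prof in enumerate(profiles):
        order = np.argsort(prof.cps)
        cps = prof.cps[order]
        cum = np.cumsum(prof.masses[order])
        idx = np.searchsorted(cum, q, side="left")
        quantile_values[j] = cps[np.minimum(idx, cps.size - 1)]

    consensus = np.array(
        [_weighted_median(quantile_values[:, i], w) for i in range(n_quantiles)]
    )

    values, counts = np.unique(consensus, return_counts=True)
    masses = counts / counts.sum()
    if total_ssms is None:
        total_ssms = int(np.median([p.total_ssms for p in profiles]))
    target = masses * total_ssms
    floor = np.floor(target).astype(int)
    rem = total_ssms - floor.sum()
    order = np.argsort(-(target - floor))
    floor[order[:rem]] += 1
    clusters = [
        (i + 1, int(n), float(v))
        for i, (v, n) in enumerate(zip(values[::-1], floor[::-1]))  # clonal first
        if n > 0
    ]
    return ClusterProfile(clusters)


def cicc_consensus(
    assignments: Sequence[HardAssignment], k: int | None = None
) -> HardAssignment:
    """Consensus hard assignment (CICC).

    The coassignment distance between two SNVs is one minus the fraction of
    methods placing them in the same cluster; average-linkage agglomerative
    clustering of that distance is cut at ``k`` clusters (default: the
    floor-of-median of the input methods' cluster counts).
    """
    if len(assignments) == 0:
        raise InvalidInputError("no assignments to combine")
    n = assignments[0].n_snvs
    if any(a.n_snvs != n for a in assignments):
        raise InvalidInputError("all assignments must cover the same SNV set")
    if k is None:
        k = ensemble_1b([a.n_clusters for a in assignments])
    if k < 1:
        raise InvalidInputError("target cluster count must be >= 1")
    k = min(k, n)

    coassign = np.zeros((n, n))
    for a in assignments:
        lab = a.labels
        coassign += lab[:, None] == lab[None, :]
    coassign /= len(assignments)
    dist = 1.0 - coassign
    np.fill_diagonal(dist, 0.0)
    if k == n:
        return HardAssignment(np.arange(1, n + 1))
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    return HardAssignment(labels).canonicalize()


def combination_protocol(
    methods: Sequence, n: int, cap: int = 200, seed: int | None = None
) -> list[tuple]:
    """All size-``n`` subsets of ``methods``, or ``cap`` distinct subsets
    sampled without replacement when the number of combinations exceeds it."""
    m = len(methods)
    if not (1 <= n <= m):
        raise InvalidInputError(f"subset size {n} out of range for {m} methods")
    total = math.comb(m, n)
    if total <= cap:
        return [tuple(c) for c in itertools.combinations(methods, n)]
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    out: list[tuple] = []
    while len(out) < cap:
        idx = tuple(sorted(rng.choice(m, size=n, replace=False).tolist()))
        if idx not in seen:
            seen.add(idx)
            out.append(tuple(methods[i] for i in idx))
    return out
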