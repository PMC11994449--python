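"""Reference predictors: the five random methods and the one-cluster method.

The random methods draw predictions from fixed distributions with no regard
for the data and anchor the bottom of the leaderboard; the one-cluster method
places every SNV in a single clonal cluster at twice the variant allele
frequency (VAF) mode, the simplest data-driven strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from hetbench.core import GERMLINE, HardAssignment, InvalidInputError
from hetbench.predictions import PredictionSet
from hetbench.scoring import ClusterProfile

#: sc1B support and probabilities for the random subclone-count draw.
_1B_VALUES = np.array([1, 2, 3, 4])
_1B_PROBS = np.array([0.2, 0.3, 0.3, 0.2])


@dataclass
class RandomSpec:
    """Seed container for the random baselines; same seed, same outputs."""

    seed: int
    n_draws: int = 100

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def random_1a(spec: RandomSpec) -> float:
    """Random purity: a single uniform draw on [0.2, 0.99]."""
    return float(spec.rng().uniform(0.2, 0.99))


def random_1b(spec: RandomSpec) -> int:
    """Random subclone count: one of {1, 2, 3, 4} w.p. {0.2, 0.3, 0.3, 0.2}."""
    return int(spec.rng().choice(_1B_VALUES, p=_1B_PROBS))


def random_1c(spec: RandomSpec, n_clusters: int) -> ClusterProfile:
    """Random cluster profile in CCF space.

    One cluster sits at CCF 1 (clonal); any further clusters get CCF drawn
    uniformly on [0.2, 0.9].  Each cluster is given a uniform 1-10 SNV count.
    CCF-to-CP conversion happens at the I/O boundary, not here.
    """
    if n_clusters < 1:
        raise InvalidInputError("need at least one cluster")
    rng = spec.rng()
    ccfs = [1.0] + [float(rng.uniform(0.2, 0.9)) for _ in range(n_clusters - 1)]
    counts = rng.integers(1, 11, size=n_clusters)
    return ClusterProfile(
        [(i + 1, int(counts[i]), ccfs[i]) for i in range(n_clusters)]
    )


def _random_assignment(rng: np.random.Generator, n_snvs: int, k: int) -> np.ndarray:
    """Cluster proportions ~ uniform integers 1..10, then multinomial labels."""
    weights = rng.integers(1, 11, size=k).astype(float)
    return rng.choice(np.arange(1, k + 1), size=n_snvs, p=weights / weights.sum())


def random_2a(spec: RandomSpec, n_snvs: int, n_clusters: int | None = None) -> HardAssignment:
    """Random hard assignment: per-cluster weights uniform on {1..10}, then
    SNV labels drawn with those proportions."""
    if n_snvs < 1:
        raise InvalidInputError("need at least one SNV")
    rng = spec.rng()
    k = n_clusters if n_clusters is not None else int(rng.choice(_1B_VALUES, p=_1B_PROBS))
    return HardAssignment(_random_assignment(rng, n_snvs, k))


@dataclass
class Random2BResult:
    """Cocluster matrix averaged over the stored random assignment vectors."""

    matrix: np.ndarray
    vectors: np.ndarray  # (n_draws, n_snvs) assignment labels


def random_2b(spec: RandomSpec, n_snvs: int) -> Random2BResult:
    """Random cocluster probabilities: the coassignment fraction over
    ``spec.n_draws`` (default 100) random assignment vectors."""
    if n_snvs < 1:
        raise InvalidInputError("need at least one SNV")
    rng = spec.rng()
    vectors = np.empty((spec.n_draws, n_snvs), dtype=np.int64)
    acc = np.zeros((n_snvs, n_snvs))
    for i in range(spec.n_draws):
        k = int(rng.choice(_1B_VALUES, p=_1B_PROBS))
        v = _random_assignment(rng, n_snvs, k)
        vectors[i] = v
        acc += v[:, None] == v[None, :]
    mat = acc / spec.n_draws
    np.fill_diagonal(mat, 1.0)
    return Random2BResult(mat, vectors)


def random_prediction_set(spec: RandomSpec, n_snvs: int) -> PredictionSet:
    """Full seven-subchallenge random prediction for one tumor."""
    rng = spec.rng()
    purity = float(rng.uniform(0.2, 0.99))
    k = int(rng.choice(_1B_VALUES, p=_1B_PROBS))
    ccfs = [1.0] + [float(rng.uniform(0.2, 0.9)) for _ in range(k - 1)]
    cps = [min(1.0, c * purity) for c in ccfs]
    counts = rng.integers(1, 11, size=k)
    profile = ClusterProfile([(i + 1, int(counts[i]), cps[i]) for i in range(k)])
    labels = _random_assignment(rng, n_snvs, k)
    hard = HardAssignment(labels)
    tree = {1: GERMLINE, **{i: i - 1 for i in range(2, k + 1)}}  # linear guess
    return PredictionSet(
        snv_ids=list(range(1, n_snvs + 1)),
        purity=purity,
        n_clusters=k,
        profile=profile,
        assignment=hard,
        tree=tree,
        cocluster_from_assignment=True,
        matrices_from_tree=True,
    )


def vaf_mode(vafs: np.ndarray) -> float:
    """VAF mode by Gaussian kernel density (Silverman bandwidth) on [0, 1]."""
    vafs = np.asarray(vafs, dtype=float)
    if vafs.size == 0:
        raise InvalidInputError("empty VAF vector")
    if np.any((vafs < 0) | (vafs > 1)):
        raise InvalidInputError("VAFs must lie in [0, 1]")
    if np.ptp(vafs) < 1e-12 or vafs.size < 2:
        return float(vafs[0])
    kde = gaussian_kde(vafs, bw_method="silverman")
    grid = np.linspace(0.0, 1.0, 512)
    return float(grid[np.argmax(kde(grid))])


def onecluster_predict(vafs: np.ndarray, snv_ids: list | None = None) -> PredictionSet:
    """One-cluster baseline: all SNVs in a single clonal cluster.

    The cluster CP (and the purity guess) is twice the VAF mode clipped to 1,
    assuming diploid heterozygous SNVs.
    """
    vafs = np.asarray(vafs, dtype=float)
    cp = min(1.0, 2.0 * vaf_mode(vafs))
    n = vafs.size
    ids = list(snv_ids) if snv_ids is not None else list(range(1, n + 1))
    labels = np.ones(n, dtype=np.int64)
    return PredictionSet(
        snv_ids=ids,
        purity=cp,
        n_clusters=1,
        profile=ClusterProfile([(1, n, cp)]),
        assignment=HardAssignment(labels),
        tree={1: GERMLINE},
        cocluster_from_assignment=True,
        matrices_from_tree=True,
    )
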