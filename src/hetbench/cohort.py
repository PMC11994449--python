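"""Synthetic tumors with known truth plus noise-degraded predictions.

The generator emulates the benchmark's design space — number of subclones,
whole-genome doubling status, linear versus branching topologies, sequencing
depth (hence NRPCC), SNV burden and the fraction of subclonal SNVs — so the
scoring, ranking and ensemble machinery can be exercised end to end without
any external data.  A family of "algorithms" is emulated by degrading the
truth with controlled noise; larger noise must yield lower expected scores,
which is what the rank-recovery tests check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from hetbench.core import (
    GERMLINE,
    HardAssignment,
    HetbenchError,
    PhylogenyTruth,
    Subclone,
)
from hetbench.predictions import SUBCHALLENGES, PredictionSet, score_prediction_set
from hetbench.scoring import ClusterProfile

__all__ = [
    "CohortDesign",
    "NoiseSpec",
    "Cohort",
    "GenerationError",
    "simulate_tree",
    "simulate_reads",
    "degrade_truth",
    "generate_cohort",
    "score_cohort",
    "noise_ladder",
]

#: Minimum CP separation between parent/child and sibling clusters so that
#: generated truths are resolvable in principle.
MIN_CP_GAP = 0.05


class GenerationError(HetbenchError):
    """Tree generation failed after bounded retries."""


@dataclass
class CohortDesign:
    """Cohort parameter space.

    Defaults span the benchmark design ranges: 1-5 subclones, purity
    0.3-0.95, depths {8, 16, 32, 64, 128}x and 500-5,000 SNVs, with a
    balanced mix of linear and branching topologies.
    """

    n_tumors: int = 20
    subclone_range: tuple[int, int] = (1, 5)
    topology_mix: float = 0.5  # fraction branching
    purity_range: tuple[float, float] = (0.3, 0.95)
    depth_levels: tuple[int, ...] = (8, 16, 32, 64, 128)
    snv_range: tuple[int, int] = (500, 5000)
    wgd_probability: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise GenerationError("need at least one tumor")
        if not (0.0 <= self.topology_mix <= 1.0):
            raise GenerationError("topology_mix must lie in [0, 1]")
        if not (0.0 <= self.wgd_probability <= 1.0):
            raise GenerationError("wgd_probability must lie in [0, 1]")


@dataclass
class NoiseSpec:
    """Noise profile of one emulated algorithm; all rates in [0, 1]."""

    merge_prob: float = 0.0
    split_prob: float = 0.0
    cp_sd: float = 0.0
    misassign_rate: float = 0.0
    purity_sd: float = 0.0
    fn_rate: float = 0.0
    fp_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("merge_prob", "split_prob", "misassign_rate", "fn_rate", "fp_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise GenerationError(f"{name} must lie in [0, 1], got {v}")
        if self.cp_sd < 0 or self.purity_sd < 0:
            raise GenerationError("noise scales must be non-negative")


def noise_ladder(n_levels: int, base_seed: int = 0) -> list[NoiseSpec]:
    """A family of algorithms of strictly increasing noise; level 0 is the
    zero-noise oracle that reproduces the truth exactly."""
    specs = []
    for i in range(n_levels):
        f = i / max(1, n_levels - 1)
        specs.append(
            NoiseSpec(
                merge_prob=0.35 * f,
                split_prob=0.2 * f,
                cp_sd=0.12 * f,
                misassign_rate=0.45 * f,
                purity_sd=0.15 * f,
                fn_rate=0.1 * f,
                fp_rate=0.1 * f,
                seed=base_seed + i,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# truth simulation
# ---------------------------------------------------------------------------

def _draw_child_cp(
    rng: np.random.Generator, parent_cp: float, sibling_cps: list[float], budget: float
) -> float | None:
    upper = min(parent_cp - MIN_CP_GAP, budget)
    if upper < MIN_CP_GAP:
        return None
    for _ in range(50):
        cp = float(rng.uniform(MIN_CP_GAP, upper))
        if all(abs(cp - s) >= MIN_CP_GAP for s in sibling_cps):
            return cp
    return None


def simulate_tree(
    n_subclones: int,
    topology: str,
    purity: float,
    seed: int,
    n_snvs: int = 1000,
) -> PhylogenyTruth:
    """Simulate a pigeonhole-valid clone tree with SNV assignments.

    ``topology`` is "linear" (a chain) or "branching" (at least one node with
    two children when the size allows).  Cellular prevalences are drawn by
    stick-breaking within each parent's CP budget with a minimum separation
    of 0.05 between parent/child and sibling clusters.  The clonal node gets
    a larger share of SNVs (Dirichlet weight 3 versus 1) to mimic the typical
    dominance of truncal mutations; every node gets at least one SNV.
    """
    if n_subclones < 1:
        raise GenerationError("need at least one subclone")
    if topology not in ("linear", "branching"):
        raise GenerationError(f"unknown topology {topology!r}")
    if n_snvs < n_subclones:
        raise GenerationError("need at least one SNV per subclone")
    rng = np.random.default_rng(seed)

    for _ in range(200):
        cps = {1: purity}
        parents = {1: GERMLINE}
        ok = True
        for node in range(2, n_subclones + 1):
            if topology == "linear":
                candidates = [node - 1]
            else:
                candidates = list(rng.permutation(np.arange(1, node)))
            placed = False
            for p in candidates:
                p = int(p)
                siblings = [cps[c] for c in cps if parents.get(c) == p]
                budget = cps[p] - sum(siblings)
                cp = _draw_child_cp(rng, cps[p], siblings, budget)
                if cp is not None:
                    cps[node] = cp
                    parents[node] = p
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        if topology == "branching" and n_subclones >= 3:
            n_children = {p: list(parents.values()).count(p) for p in cps}
            if max(n_children.values()) < 2:
                continue  # came out as a chain; redraw

        alpha = np.ones(n_subclones)
        alpha[0] = 3.0
        weights = rng.dirichlet(alpha)
        extra = rng.multinomial(n_snvs - n_subclones, weights)
        counts = extra + 1
        labels = np.repeat(np.arange(1, n_subclones + 1), counts)
        rng.shuffle(labels)
        assignment = {i + 1: int(labels[i]) for i in range(n_snvs)}
        subclones = [
            Subclone(i, parents[i], cps[i], int(counts[i - 1]))
            for i in range(1, n_subclones + 1)
        ]
        return PhylogenyTruth(purity=purity, subclones=subclones, assignment=assignment)
    raise GenerationError(
        f"could not allocate CPs for {n_subclones} subclones at purity {purity}"
    )


def simulate_reads(
    truth: PhylogenyTruth, depth: float, seed: int, tumor_copies: int = 2
) -> pd.DataFrame:
    """Binomial read sampling at each SNV.

    Total coverage is Poisson(depth); alt counts are Binomial with expected
    VAF = cp * multiplicity / (rho * C_tumor + 2 * (1 - rho)) under the
    diploid heterozygous default (multiplicity 1), i.e. VAF = cp / 2 for a
    diploid tumor.
    """
    if depth <= 0:
        raise GenerationError("depth must be positive")
    rng = np.random.default_rng(seed)
    cp_by_cluster = {s.id: s.cp for s in truth.subclones}
    rho = truth.purity
    rows = []
    denom = rho * tumor_copies + 2.0 * (1.0 - rho)
    for snv, cl in truth.assignment.items():
        cp = cp_by_cluster[cl]
        evaf = cp / denom
        total = int(rng.poisson(depth))
        alt = int(rng.binomial(total, evaf)) if total > 0 else 0
        rows.append((snv, cl, cp, alt, total, alt / total if total > 0 else 0.0))
    return pd.DataFrame(
        rows, columns=["snv_id", "cluster", "cp", "alt", "total", "vaf"]
    )


# ---------------------------------------------------------------------------
# truth degradation (emulated algorithms)
# ---------------------------------------------------------------------------

def degrade_truth(truth: PhylogenyTruth, noise: NoiseSpec) -> PredictionSet:
    """Produce a full seven-subchallenge prediction by perturbing the truth.

    A zero-noise spec reproduces the truth exactly (all scores 1).  Merges
    collapse nodes into their parents, splits carve off child clusters, CP
    jitter perturbs cluster prevalences, misassignment relabels SNVs, and
    FN/FP rates drop truth SNVs or invent novel ones so that reconciliation
    is exercised.
    """
    rng = np.random.default_rng(noise.seed)
    if noise.purity_sd > 0:
        purity_pred = float(
            np.clip(truth.purity + rng.normal(0.0, noise.purity_sd), 0.01, 1.0)
        )
    else:
        purity_pred = truth.purity

    clusters: dict[int, dict] = {
        s.id: {"parent": s.parent_id, "cp": s.cp, "snvs": []} for s in truth.subclones
    }
    for snv, cl in truth.assignment.items():
        clusters[cl]["snvs"].append(snv)
    clonal = truth.clonal_id

    # merges: collapse a non-clonal node into its parent
    for cid in sorted(clusters):
        if cid == clonal or cid not in clusters:
            continue
        if rng.uniform() < noise.merge_prob:
            parent = clusters[cid]["parent"]
            target = parent if parent != GERMLINE else clonal
            if target == cid or target not in clusters:
                continue
            clusters[target]["snvs"].extend(clusters[cid]["snvs"])
            for other in clusters.values():
                if other["parent"] == cid:
                    other["parent"] = target
            del clusters[cid]

    # splits: carve a child cluster out of half of a node's SNVs
    next_id = max(clusters) + 1
    for cid in sorted(clusters):
        snvs = clusters[cid]["snvs"]
        if len(snvs) >= 2 and rng.uniform() < noise.split_prob:
            take = rng.choice(len(snvs), size=len(snvs) // 2, replace=False)
            moved = [snvs[i] for i in sorted(take)]
            clusters[cid]["snvs"] = [s for s in snvs if s not in set(moved)]
            clusters[next_id] = {
                "parent": cid,
                "cp": clusters[cid]["cp"] * float(rng.uniform(0.4, 0.9)),
                "snvs": moved,
            }
            next_id += 1

    # CP jitter
    if noise.cp_sd > 0:
        for c in clusters.values():
            c["cp"] = float(np.clip(c["cp"] + rng.normal(0.0, noise.cp_sd), 0.0, 1.0))

    # flatten to an SNV -> cluster map for the per-SNV perturbations
    assignment = {s: cid for cid in sorted(clusters) for s in clusters[cid]["snvs"]}
    ids = sorted(clusters)

    # misassignment: relabel SNVs to a random other cluster
    if noise.misassign_rate > 0 and len(ids) > 1:
        for snv in truth.snv_ids:
            if snv in assignment and rng.uniform() < noise.misassign_rate:
                current = assignment[snv]
                others = [c for c in ids if c != current]
                assignment[snv] = int(rng.choice(others))

    # false negatives: drop truth SNVs from the reported universe
    reported = []
    for snv in truth.snv_ids:
        if noise.fn_rate > 0 and rng.uniform() < noise.fn_rate:
            del assignment[snv]
        else:
            reported.append(snv)

    # false positives: invent novel SNVs in random clusters
    n_fp = int(round(noise.fp_rate * truth.n_snvs))
    nonempty = sorted({c for c in assignment.values()}) or ids[:1]
    for j in range(n_fp):
        fp_id = f"FP{j + 1}"
        assignment[fp_id] = int(rng.choice(nonempty))
        reported.append(fp_id)

    for c in clusters.values():
        c["snvs"] = []
    for snv, cid in assignment.items():
        clusters[cid]["snvs"].append(snv)
    clusters = {c: v for c, v in clusters.items() if v["snvs"]}
    # re-anchor parents whose nodes were emptied
    valid = set(clusters) | {GERMLINE}
    for c, v in clusters.items():
        while v["parent"] not in valid:
            v["parent"] = (
                truth.parent_map.get(v["parent"], GERMLINE)
                if v["parent"] in truth.parent_map
                else GERMLINE
            )

    label_of = {s: cid for cid in sorted(clusters) for s in clusters[cid]["snvs"]}
    labels = np.asarray([label_of[s] for s in reported])
    hard = HardAssignment(labels)
    tree = {cid: clusters[cid]["parent"] for cid in sorted(clusters)}
    profile = ClusterProfile(
        [(cid, len(clusters[cid]["snvs"]), clusters[cid]["cp"]) for cid in sorted(clusters)]
    )
    return PredictionSet(
        snv_ids=reported,
        purity=purity_pred,
        n_clusters=len(clusters),
        profile=profile,
        assignment=hard,
        tree=tree,
        cocluster_from_assignment=True,
        matrices_from_tree=True,
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Generated truths, per-tumor metadata and per-algorithm predictions."""

    design: CohortDesign
    truths: dict[str, PhylogenyTruth]
    meta: pd.DataFrame  # tumor, depth, titration_group, n_subclones, topology, wgd
    predictions: dict[tuple[str, str], PredictionSet]

    @property
    def tumors(self) -> list[str]:
        return list(self.truths)

    @property
    def algorithms(self) -> list[str]:
        return sorted({a for _, a in self.predictions})


def _subseed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def generate_cohort(
    design: CohortDesign,
    algorithms: dict[str, NoiseSpec] | Sequence[NoiseSpec],
) -> Cohort:
    """Generate truths and degraded predictions for every {tumor, algorithm}.

    The first tumor design is replicated across all depth levels as a
    titration series (one shared truth, one shared normalization group); the
    remaining tumors each get one random depth.
    """
    if not isinstance(algorithms, dict):
        algorithms = {f"alg{i:02d}": spec for i, spec in enumerate(algorithms)}
    rng = np.random.default_rng(design.seed)
    truths: dict[str, PhylogenyTruth] = {}
    rows = []

    def _make_truth(seed: int) -> tuple[PhylogenyTruth, str, bool]:
        for attempt in range(50):
            n_sub = int(rng.integers(design.subclone_range[0], design.subclone_range[1] + 1))
            topology = "branching" if (rng.uniform() < design.topology_mix and n_sub >= 3) else "linear"
            purity = float(rng.uniform(*design.purity_range))
            n_snvs = int(rng.integers(design.snv_range[0], design.snv_range[1] + 1))
            wgd = bool(rng.uniform() < design.wgd_probability)
            try:
                t = simulate_tree(n_sub, topology, purity, seed + attempt, n_snvs=n_snvs)
                return t, topology, wgd
            except GenerationError:
                continue
        raise GenerationError("could not generate a valid tumor design")

    # titration tumor: one truth across all depth levels
    t0, topo0, wgd0 = _make_truth(_subseed(design.seed, 0))
    for depth in design.depth_levels:
        tid = f"TS1_d{depth}"
        truths[tid] = t0
        rows.append((tid, depth, "TS1", t0.n_subclones, topo0, wgd0))
    for i in range(1, design.n_tumors):
        t, topo, wgd = _make_truth(_subseed(design.seed, i))
        tid = f"T{i:02d}"
        depth = int(rng.choice(design.depth_levels))
        truths[tid] = t
        rows.append((tid, depth, None, t.n_subclones, topo, wgd))

    meta = pd.DataFrame(
        rows,
        columns=["tumor", "depth", "titration_group", "n_subclones", "topology", "wgd"],
    )

    predictions: dict[tuple[str, str], PredictionSet] = {}
    for ti, tid in enumerate(truths):
        for ai, (name, spec) in enumerate(algorithms.items()):
            local = replace(spec, seed=_subseed(design.seed, spec.seed, ti, ai))
            predictions[(tid, name)] = degrade_truth(truths[tid], local)
    return Cohort(design=design, truths=truths, meta=meta, predictions=predictions)


def score_cohort(cohort: Cohort) -> pd.DataFrame:
    """Score every {tumor, algorithm, subchallenge}; returns a raw score table
    with the titration group carried through for joint normalization."""
    tg = dict(zip(cohort.meta["tumor"], cohort.meta["titration_group"]))
    rows = []
    for (tumor, alg), pred in cohort.predictions.items():
        scores = score_prediction_set(cohort.truths[tumor], pred)
        for sub in SUBCHALLENGES:
            if sub in scores:
                rows.append((tumor, alg, sub, scores[sub], tg.get(tumor)))
    return pd.DataFrame(
        rows, columns=["tumor", "algorithm", "subchallenge", "s_raw", "titration_group"]
    )
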