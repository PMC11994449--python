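"""Score normalization, leaderboard ranking, bootstrap rank significance and
the multicriteria decision-space analysis.

Raw metric values are min-max normalized within each {tumor, subchallenge}
group across methods so every tumor contributes on the same scale; a titration
series (the same tumor sequenced at several depths) is normalized jointly
across its depths.  Algorithms are ranked by the median normalized score over
the tumors they produced valid output for, with ties sharing the minimum rank.
Rank differences against the leaderboard best are tested by bootstrapping
tumors; entries with P > 0.1 are flagged statistically indistinguishable from
the best.  Finally, a PCA of the algorithm-by-subchallenge score matrix gives
a decision space in which a weighted-mean "decision axis" and its stability
under weight perturbation can be examined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from hetbench.core import InvalidInputError

__all__ = [
    "minmax_normalize",
    "rank_algorithms",
    "bootstrap_rank_pvalue",
    "DecisionSpace",
    "decision_projection",
    "weight_perturbation_study",
    "drop_correlated_algorithms",
]

#: Entries with bootstrap P above this are indistinguishable from the best.
INDISTINGUISHABLE_P = 0.1


def minmax_normalize(records: pd.DataFrame) -> pd.DataFrame:
    """Add an ``s_minmax`` column: min-max normalization within each
    {tumor, subchallenge} group across methods.

    If a ``titration_group`` column is present, rows sharing a group id are
    normalized jointly across depths (one shared min/max).  A degenerate group
    whose scores are all equal is set to 1 (everyone is equally best).
    Already-normalized groups are left unchanged (the map is idempotent).
    """
    df = records.copy()
    if "titration_group" in df.columns:
        gid = df["titration_group"].where(df["titration_group"].notna(), df["tumor"])
    else:
        gid = df["tumor"]
    df["_gid"] = gid

    def _norm(s: pd.Series) -> pd.Series:
        lo, hi = s.min(), s.max()
        if hi - lo <= 0:
            return pd.Series(1.0, index=s.index)
        return (s - lo) / (hi - lo)

    df["s_minmax"] = df.groupby(["_gid", "subchallenge"])["s_raw"].transform(_norm)
    return df.drop(columns="_gid")


def _median_scores(df: pd.DataFrame, zero_fill: bool) -> pd.Series:
    """Per-algorithm median normalized score; missing tumors are excluded
    unless ``zero_fill`` scores them as zero."""
    pivot = df.pivot_table(
        index="tumor", columns="algorithm", values="s_minmax", aggfunc="mean"
    )
    if zero_fill:
        pivot = pivot.fillna(0.0)
    return pivot.median(axis=0, skipna=True)


def rank_algorithms(
    records: pd.DataFrame, subchallenge: str, zero_fill: bool = False
) -> pd.DataFrame:
    """Leaderboard for one subchallenge: algorithms ranked by median
    normalized score (rank 1 = best; ties share the minimum rank)."""
    df = records[records["subchallenge"] == subchallenge]
    if df.empty:
        raise InvalidInputError(f"no records for subchallenge {subchallenge!r}")
    med = _median_scores(df, zero_fill)
    ranks = rankdata(-med.to_numpy(), method="min")
    out = pd.DataFrame(
        {"algorithm": med.index, "median_score": med.to_numpy(), "rank": ranks}
    )
    return out.sort_values(["rank", "algorithm"]).reset_index(drop=True)


def bootstrap_rank_pvalue(
    records: pd.DataFrame,
    subchallenge: str,
    n_boot: int = 10_000,
    seed: int | None = None,
    zero_fill: bool = False,
) -> pd.DataFrame:
    """Bootstrap test of rank differences against the leaderboard best.

    Tumors are resampled with replacement ``n_boot`` times; in each resample
    the per-algorithm medians and min-tie ranks are recomputed.  An entry's P
    value is the fraction of resamples in which its rank is <= the original
    best algorithm's recomputed rank, i.e. the null that the entry ranks at
    least as well as the best cannot be rejected when P is large.
    """
    if n_boot < 1:
        raise InvalidInputError("n_boot must be >= 1")
    df = records[records["subchallenge"] == subchallenge]
    pivot = df.pivot_table(
        index="tumor", columns="algorithm", values="s_minmax", aggfunc="mean"
    )
    if zero_fill:
        pivot = pivot.fillna(0.0)
    algs = list(pivot.columns)
    if len(algs) < 2 or pivot.shape[0] < 2:
        raise InvalidInputError("need >= 2 algorithms and >= 2 tumors")
    board = rank_algorithms(records, subchallenge, zero_fill)
    best = board.iloc[0]["algorithm"]
    best_j = algs.index(best)

    mat = pivot.to_numpy()  # (n_tumors, n_algs), NaN = missing
    rng = np.random.default_rng(seed)
    n_t = mat.shape[0]
    wins = np.zeros(len(algs))
    chunk = 500
    for start in range(0, n_boot, chunk):
        m = min(chunk, n_boot - start)
        idx = rng.integers(0, n_t, size=(m, n_t))
        sample = mat[idx]  # (m, n_t, n_algs)
        with np.errstate(all="ignore"):
            med = np.nanmedian(sample, axis=1)  # (m, n_algs)
        med = np.where(np.isnan(med), -np.inf, med)
        ranks = rankdata(-med, method="min", axis=1)
        wins += (ranks <= ranks[:, [best_j]]).sum(axis=0)
    p = wins / n_boot
    out = pd.DataFrame({"algorithm": algs, "p_value": p})
    out["indistinguishable_from_best"] = out["p_value"] > INDISTINGUISHABLE_P
    out["is_best"] = out["algorithm"] == best
    return out.sort_values("p_value", ascending=False).reset_index(drop=True)


@dataclass
class DecisionSpace:
    """PCA of the algorithm-by-subchallenge score matrix plus a decision axis."""

    score_matrix: pd.DataFrame            # algorithms x subchallenges
    components: np.ndarray                # (2, n_subchallenges) loadings
    explained_variance_ratio: np.ndarray
    algorithm_coords: pd.DataFrame        # algorithms x {pc1, pc2}
    subchallenge_coords: pd.DataFrame     # subchallenges x {pc1, pc2}
    decision_axis: np.ndarray             # (2,) unit vector in PC space
    ranking: pd.DataFrame                 # algorithm, decision_score, rank
    perturbed_axes: np.ndarray = field(default=None)  # (n_axes, 2)


def _score_matrix(
    records: pd.DataFrame, tumor_weights: pd.Series | None = None
) -> pd.DataFrame:
    """Algorithm x subchallenge matrix of tumor-weighted mean normalized scores."""
    df = records.copy()
    if tumor_weights is not None:
        w = df["tumor"].map(tumor_weights)
        df["_w"] = w / w.groupby([df["algorithm"], df["subchallenge"]]).transform("sum")
        df["_ws"] = df["s_minmax"] * df["_w"]
        mat = df.pivot_table(
            index="algorithm", columns="subchallenge", values="_ws", aggfunc="sum"
        )
    else:
        mat = df.pivot_table(
            index="algorithm", columns="subchallenge", values="s_minmax", aggfunc="mean"
        )
    return mat


def decision_projection(
    score_matrix: pd.DataFrame,
    subchallenge_weights: np.ndarray | None = None,
    n_perturbed_axes: int = 0,
    perturbation: float = 0.5,
    seed: int | None = None,
) -> DecisionSpace:
    """Project algorithms, subchallenge axes and a decision axis into the
    first two principal components of the score space.

    The decision axis is the direction of the (weighted) mean score across
    subchallenges; projecting algorithms onto it reproduces the weighted-mean
    ranking exactly (the ranking reported here is computed in the full space,
    not the 2-component truncation).  Optional perturbed axes re-draw each
    subchallenge weight by a uniform relative change in
    [-perturbation, +perturbation].
    """
    mat = score_matrix.to_numpy(dtype=float)
    if mat.shape[0] < 2:
        raise InvalidInputError("need at least two algorithms")
    if np.isnan(mat).any():
        col_mean = np.nanmean(mat, axis=0)
        mat = np.where(np.isnan(mat), col_mean[None, :], mat)
    k = mat.shape[1]
    w = (
        np.full(k, 1.0 / k)
        if subchallenge_weights is None
        else np.asarray(subchallenge_weights, dtype=float)
    )
    w = w / w.sum()

    pca = PCA(n_components=min(2, k, mat.shape[0]))
    coords = pca.fit_transform(mat)
    comps = pca.components_
    alg_coords = pd.DataFrame(
        coords[:, :2], index=score_matrix.index, columns=["pc1", "pc2"][: coords.shape[1]]
    )
    sub_coords = pd.DataFrame(
        comps[:2].T, index=score_matrix.columns, columns=["pc1", "pc2"][: comps.shape[0]]
    )

    def _axis(weights: np.ndarray) -> np.ndarray:
        v = comps[:2] @ weights
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    axis = _axis(w)
    decision_score = mat @ w
    ranks = rankdata(-decision_score, method="min")
    ranking = pd.DataFrame(
        {
            "algorithm": score_matrix.index,
            "decision_score": decision_score,
            "rank": ranks,
        }
    ).sort_values(["rank", "algorithm"]).reset_index(drop=True)

    perturbed = None
    if n_perturbed_axes > 0:
        rng = np.random.default_rng(seed)
        factors = 1.0 + rng.uniform(-perturbation, perturbation, size=(n_perturbed_axes, k))
        perturbed = np.stack([_axis(w * f / (w * f).sum()) for f in factors])

    return DecisionSpace(
        score_matrix=score_matrix,
        components=comps,
        explained_variance_ratio=pca.explained_variance_ratio_,
        algorithm_coords=alg_coords,
        subchallenge_coords=sub_coords,
        decision_axis=axis,
        ranking=ranking,
        perturbed_axes=perturbed,
    )


def weight_perturbation_study(
    records: pd.DataFrame,
    n_tumor_draws: int = 200,
    n_subchallenge_draws: int = 200,
    seed: int | None = None,
    subchallenges: list[str] | None = None,
) -> pd.DataFrame:
    """Rank distributions under random tumor and subchallenge weights.

    Draws ``n_tumor_draws`` tumor-weight vectors and ``n_subchallenge_draws``
    subchallenge-weight vectors from independent standard uniforms (each
    renormalized to sum 1) and derives one full ranking per pair —
    200 x 200 = 40,000 by default.  Returns per-algorithm rank quantiles and
    an ever-ranked-first flag.
    """
    df = records
    if subchallenges is not None:
        df = df[df["subchallenge"].isin(subchallenges)]
    tensor = df.pivot_table(
        index="tumor", columns=["algorithm", "subchallenge"], values="s_minmax"
    )
    tumors = tensor.index
    algs = tensor.columns.get_level_values(0).unique()
    subs = tensor.columns.get_level_values(1).unique()
    full = np.full((len(tumors), len(algs), len(subs)), np.nan)
    for j, a in enumerate(algs):
        for s_i, s in enumerate(subs):
            if (a, s) in tensor.columns:
                full[:, j, s_i] = tensor[(a, s)].to_numpy()
    # impute missing cells with the per-{tumor, subchallenge} mean across algorithms
    cell_mean = np.nanmean(full, axis=1, keepdims=True)
    full = np.where(np.isnan(full), cell_mean, full)
    full = np.nan_to_num(full)

    rng = np.random.default_rng(seed)
    tw = rng.uniform(size=(n_tumor_draws, len(tumors)))
    tw /= tw.sum(axis=1, keepdims=True)
    sw = rng.uniform(size=(n_subchallenge_draws, len(subs)))
    sw /= sw.sum(axis=1, keepdims=True)

    per_t = np.einsum("dt,tas->das", tw, full)  # (draws, algs, subs)
    scores = np.einsum("das,es->dea", per_t, sw)  # (tumor draws, sub draws, algs)
    flat = scores.reshape(-1, len(algs))
    ranks = rankdata(-flat, method="min", axis=1)
    out = pd.DataFrame(
        {
            "algorithm": algs,
            "n_rankings": len(flat),
            "rank_median": np.median(ranks, axis=0),
            "rank_q25": np.quantile(ranks, 0.25, axis=0),
            "rank_q75": np.quantile(ranks, 0.75, axis=0),
            "first_place_fraction": (ranks == 1).mean(axis=0),
            "ever_ranked_first": (ranks == 1).any(axis=0),
        }
    )
    return out


def drop_correlated_algorithms(
    records: pd.DataFrame, subchallenge: str, threshold: float = 0.75
) -> list[str]:
    """Documented filter utility: among pairs of algorithms whose scores
    correlate above ``threshold`` across tumors, keep the one with the higher
    median score.  Returns the retained algorithm names (no inferential claim
    attaches to this filter)."""
    df = records[records["subchallenge"] == subchallenge]
    pivot = df.pivot_table(index="tumor", columns="algorithm", values="s_minmax")
    med = pivot.median()
    keep = list(pivot.columns)
    corr = pivot.corr()
    for a in sorted(keep, key=lambda x: med[x]):
        for b in keep:
            if a != b and a in keep and corr.loc[a, b] > threshold and med[b] >= med[a]:
                keep.remove(a)
                break
    return keep
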