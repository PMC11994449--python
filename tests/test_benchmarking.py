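import numpy as np
import pandas as pd
import pytest

from hetbench.benchmarking import (
    bootstrap_rank_pvalue,
    decision_projection,
    drop_correlated_algorithms,
    minmax_normalize,
    rank_algorithms,
    weight_perturbation_study,
)


def table(rows):
    return pd.DataFrame(rows, columns=["tumor", "algorithm", "subchallenge", "s_raw"])


class TestMinMaxNormalize:
    def test_basic_group(self):
        df = table([("t1", "a", "1A", 0.2), ("t1", "b", "1A", 0.5), ("t1", "c", "1A", 0.8)])
        out = minmax_normalize(df)
        assert out["s_minmax"].tolist() == pytest.approx([0.0, 0.5, 1.0])

    def test_degenerate_group_all_ones(self):
        df = table([("t1", "a", "1A", 0.4), ("t1", "b", "1A", 0.4)])
        out = minmax_normalize(df)
        assert out["s_minmax"].tolist() == [1.0, 1.0]

    def test_titration_group_shares_minmax(self):
        df = table(
            [("t1_d8", "a", "1C", 0.2), ("t1_d8", "b", "1C", 0.4),
             ("t1_d64", "a", "1C", 0.6), ("t1_d64", "b", "1C", 1.0)]
        )
        df["titration_group"] = "t1"
        out = minmax_normalize(df)
        # one shared min (0.2) and max (1.0) across both depths
        assert out["s_minmax"].tolist() == pytest.approx([0.0, 0.25, 0.5, 1.0])

    def test_groups_normalized_independently(self):
        df = table([("t1", "a", "1A", 0.2), ("t1", "b", "1A", 0.8),
                    ("t2", "a", "1A", 0.5), ("t2", "b", "1A", 0.9),
                    ("t1", "a", "1B", 0.1), ("t1", "b", "1B", 0.3)])
        out = minmax_normalize(df)
        for _, grp in out.groupby(["tumor", "subchallenge"]):
            assert grp["s_minmax"].min() == 0.0
            assert grp["s_minmax"].max() == 1.0

    def test_idempotent(self):
        df = table([("t1", "a", "1A", 0.2), ("t1", "b", "1A", 0.5), ("t1", "c", "1A", 0.9)])
        once = minmax_normalize(df)
        twice = minmax_normalize(once.assign(s_raw=once["s_minmax"]))
        assert np.allclose(once["s_minmax"], twice["s_minmax"])

    def test_invariant_to_monotone_transform(self):
        df = table([("t1", "a", "1A", 0.2), ("t1", "b", "1A", 0.5), ("t1", "c", "1A", 0.9),
                    ("t2", "a", "1A", 0.1), ("t2", "b", "1A", 0.6), ("t2", "c", "1A", 0.7)])
        r1 = rank_algorithms(minmax_normalize(df), "1A")
        df2 = df.assign(s_raw=np.exp(df["s_raw"]))  # monotone within each group
        r2 = rank_algorithms(minmax_normalize(df2), "1A")
        assert r1["algorithm"].tolist() == r2["algorithm"].tolist()


class TestRanking:
    def test_tied_algorithms_share_min_rank(self):
        df = minmax_normalize(table(
            [("t1", "a", "1A", 0.5), ("t1", "b", "1A", 0.5), ("t1", "c", "1A", 0.1),
             ("t2", "a", "1A", 0.7), ("t2", "b", "1A", 0.7), ("t2", "c", "1A", 0.2)]
        ))
        board = rank_algorithms(df, "1A")
        ranks = dict(zip(board["algorithm"], board["rank"]))
        assert ranks["a"] == ranks["b"] == 1
        assert ranks["c"] == 3

    def test_dominating_algorithm_ranks_first(self):
        df = minmax_normalize(table(
            [(t, a, "1C", s) for t in ("t1", "t2", "t3")
             for a, s in (("good", 0.9), ("mid", 0.5), ("bad", 0.1))]
        ))
        board = rank_algorithms(df, "1C")
        assert board.iloc[0]["algorithm"] == "good"

    def test_missing_excluded_unless_zero_filled(self):
        rows = [("t1", "a", "1A", 0.9), ("t2", "a", "1A", 0.9),
                ("t1", "b", "1A", 0.8), ("t2", "c", "1A", 0.1),
                ("t1", "c", "1A", 0.1)]  # b missing on t2
        df = minmax_normalize(table(rows))
        default = rank_algorithms(df, "1A")
        filled = rank_algorithms(df, "1A", zero_fill=True)
        med = dict(zip(filled["algorithm"], filled["median_score"]))
        med_default = dict(zip(default["algorithm"], default["median_score"]))
        assert med["b"] < med_default["b"]


class TestBootstrap:
    @staticmethod
    def scores(n_tumors=12, margin=0.3, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_tumors):
            base = rng.uniform(0.3, 0.6)
            rows.append((f"t{i}", "best", "1C", base + margin))
            rows.append((f"t{i}", "dup", "1C", base + margin))
            rows.append((f"t{i}", "worse", "1C", base))
        return minmax_normalize(table(rows))

    def test_best_vs_itself_is_one(self):
        df = self.scores()
        pv = bootstrap_rank_pvalue(df, "1C", n_boot=200, seed=1)
        p = dict(zip(pv["algorithm"], pv["p_value"]))
        best = pv[pv["is_best"]]["algorithm"].iloc[0]
        assert p[best] == 1.0

    def test_duplicate_of_best_is_one(self):
        df = self.scores()
        pv = bootstrap_rank_pvalue(df, "1C", n_boot=200, seed=1)
        p = dict(zip(pv["algorithm"], pv["p_value"]))
        assert p["dup"] == 1.0

    def test_strictly_dominated_is_zero(self):
        df = self.scores()
        pv = bootstrap_rank_pvalue(df, "1C", n_boot=500, seed=2)
        p = dict(zip(pv["algorithm"], pv["p_value"]))
        assert p["worse"] == 0.0

    def test_p_nonincreasing_in_margin(self):
        def p_of(margin, noise):
            rng = np.random.default_rng(3)
            rows = []
            for i in range(10):
                base = rng.uniform(0.3, 0.5)
                rows.append((f"t{i}", "best", "1C", base + margin + rng.normal(0, noise)))
                rows.append((f"t{i}", "entry", "1C", base + rng.normal(0, noise)))
                rows.append((f"t{i}", "floor", "1C", 0.0))
            df = minmax_normalize(table(rows))
            pv = bootstrap_rank_pvalue(df, "1C", n_boot=400, seed=4)
            return dict(zip(pv["algorithm"], pv["p_value"]))["entry"]

        ps = [p_of(m, noise=0.1) for m in (0.0, 0.1, 0.3)]
        assert ps[0] >= ps[1] >= ps[2]

    def test_invalid_n_boot(self):
        with pytest.raises(Exception):
            bootstrap_rank_pvalue(self.scores(), "1C", n_boot=0)


class TestDecision:
    @staticmethod
    def matrix():
        return pd.DataFrame(
            {"1A": [0.9, 0.5, 0.1], "1C": [0.8, 0.6, 0.2]},
            index=["good", "mid", "bad"],
        )

    def test_equal_weight_ranking_equals_mean_ranking(self):
        mat = self.matrix()
        space = decision_projection(mat)
        mean_order = mat.mean(axis=1).sort_values(ascending=False).index.tolist()
        assert space.ranking["algorithm"].tolist() == mean_order

    def test_identical_algorithms_project_to_one_point(self):
        mat = pd.DataFrame({"1A": [0.5, 0.5], "1C": [0.7, 0.7]}, index=["a", "b"])
        space = decision_projection(mat)
        assert np.allclose(space.algorithm_coords.iloc[0], space.algorithm_coords.iloc[1])

    def test_projection_matches_closed_form_eigendecomposition(self):
        mat = self.matrix()
        x = mat.to_numpy() - mat.to_numpy().mean(axis=0)
        cov = x.T @ x / (x.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        v1 = evecs[:, np.argmax(evals)]
        space = decision_projection(mat)
        proj = x @ v1
        # same axis up to sign
        got = space.algorithm_coords["pc1"].to_numpy()
        assert np.allclose(np.abs(got), np.abs(proj), atol=1e-10)

    def test_zero_perturbation_keeps_axis(self):
        space = decision_projection(self.matrix(), n_perturbed_axes=10,
                                    perturbation=0.0, seed=0)
        for ax in space.perturbed_axes:
            assert np.allclose(ax, space.decision_axis)

    def test_fewer_than_two_algorithms_rejected(self):
        with pytest.raises(Exception):
            decision_projection(self.matrix().iloc[:1])


class TestWeightPerturbation:
    @staticmethod
    def records():
        rows = []
        for t in ("t1", "t2", "t3"):
            for s in ("1A", "1C"):
                rows.append((t, "dom", s, 1.0))
                rows.append((t, "sub", s, 0.3))
        df = table(rows)
        df["s_minmax"] = df["s_raw"]
        return df

    def test_dominating_algorithm_always_first(self):
        out = weight_perturbation_study(self.records(), 20, 20, seed=0)
        row = out[out["algorithm"] == "dom"].iloc[0]
        assert row["first_place_fraction"] == 1.0
        assert row["ever_ranked_first"]
        sub = out[out["algorithm"] == "sub"].iloc[0]
        assert not sub["ever_ranked_first"]

    def test_ranking_count(self):
        out = weight_perturbation_study(self.records(), 15, 13, seed=0)
        assert out["n_rankings"].iloc[0] == 15 * 13


class TestCorrelationFilter:
    def test_keeps_higher_median_of_correlated_pair(self):
        rng = np.random.default_rng(5)
        rows = []
        base = rng.uniform(0, 1, size=10)
        for i in range(10):
            rows.append((f"t{i}", "hi", "1C", base[i] + 0.1))
            rows.append((f"t{i}", "lo", "1C", base[i]))         # r = 1 with hi
            rows.append((f"t{i}", "ind", "1C", rng.uniform()))  # independent
        df = table(rows)
        df["s_minmax"] = df["s_raw"]
        keep = drop_correlated_algorithms(df, "1C", threshold=0.75)
        assert "hi" in keep and "lo" not in keep and "ind" in keep
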