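from collections import Counter

import numpy as np
import pandas as pd
import pytest

from egse.ensemble import (comparative_scores, ensemble_scores, rank_by_method,
                           top_sets)
from egse.methods import MethodResultMatrix
from egse.simulate import make_rank_fixture


def mrm_from_p(p, contrast="c1", valid=None, direction=None):
    p = np.asarray(p, dtype=float)
    n, k = p.shape
    return MethodResultMatrix(
        set_names=[f"S{i}" for i in range(n)],
        method_names=[f"m{j}" for j in range(k)],
        contrast=contrast,
        p=p,
        direction=np.ones((n, k), dtype=int) if direction is None else direction,
        valid=np.ones((n, k), dtype=bool) if valid is None else valid,
    )


class TestRankByMethod:
    def test_ties_share_minimum_rank(self):
        ranks = rank_by_method(mrm_from_p([[0.1], [0.1], [0.5]]))
        assert ranks["m0"].tolist() == [1, 1, 3]

    def test_sorted_column_ranks_one_to_n(self):
        ranks = rank_by_method(mrm_from_p([[0.1], [0.2], [0.3], [0.9]]))
        assert ranks["m0"].tolist() == [1, 2, 3, 4]

    def test_invalid_entries_rank_below_all_valid(self):
        valid = np.array([[True], [False], [True]])
        ranks = rank_by_method(mrm_from_p([[0.5], [0.01], [0.1]], valid=valid))
        assert ranks["m0"].tolist() == [2, 3, 1]

    def test_matches_bruteforce_sort_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=(50, 6))
        ranks = rank_by_method(mrm_from_p(p)).to_numpy()
        for j in range(6):
            col = p[:, j]
            brute = np.array([1 + int(np.sum(col < v)) for v in col])
            assert np.array_equal(ranks[:, j], brute)


class FakeGls:
    """Minimal gene-level stand-in for rank-aggregation tests."""

    def __init__(self, n_genes, rng):
        self.logfc = rng.normal(size=(n_genes, 1))
        self.contrast_names = ["c1"]

    def contrast_column(self, contrast):
        return 0


class FakeIndexSet:
    def __init__(self, name, idx):
        self.name = name
        self.index = idx


def fake_index(names, n_genes, rng):
    return [FakeIndexSet(n, list(rng.choice(n_genes, size=5, replace=False)))
            for n in names]


class TestEnsembleScores:
    def make_table(self, p, rng=None, **kwargs):
        rng = rng or np.random.default_rng(1)
        mrm = mrm_from_p(p)
        gls = FakeGls(100, rng)
        index = fake_index(mrm.set_names, 100, rng)
        return ensemble_scores(mrm, gls, index, **kwargs)

    def test_identical_rankings_collapse_aggregates(self):
        p_col = np.array([0.001, 0.01, 0.2, 0.5, 0.9])
        table = self.make_table(np.tile(p_col[:, None], (1, 7)))
        expected = [1, 2, 3, 4, 5]
        assert table["avg.rank"].tolist() == expected
        assert table["med.rank"].tolist() == expected
        assert table["min.rank"].tolist() == expected
        assert table["vote.rank"].tolist() == [5 * int(np.ceil(r / 5)) for r in expected]

    def test_vote_rank_multiples_of_bin(self):
        rng = np.random.default_rng(2)
        table = self.make_table(rng.uniform(size=(40, 11)), rng=rng)
        assert (table["vote.rank"] % 5 == 0).all()

    def test_aggregates_match_bruteforce_on_rank_fixture(self):
        frame, answers = make_rank_fixture(n_sets=60, n_methods=11, seed=3)
        # feed ranks through p-values that sort identically per column
        p = (frame.to_numpy() - 0.5) / 60.0
        table = self.make_table(p)
        assert np.allclose(table["med.rank"], answers["med.rank"])
        assert np.allclose(table["avg.rank"], answers["avg.rank"])
        assert np.allclose(table["min.rank"], answers["min.rank"])
        assert np.allclose(table["vote.rank"], answers["vote.rank"])

    def test_even_method_count_uses_lower_median(self):
        p = np.array([[0.1, 0.2, 0.3, 0.4],
                      [0.2, 0.1, 0.4, 0.3],
                      [0.3, 0.4, 0.1, 0.2],
                      [0.4, 0.3, 0.2, 0.1]])
        table = self.make_table(p)
        # each set holds ranks {1,2,3,4} permuted; lower median = 2
        assert (table["med.rank"] == 2).all()

    def test_method_column_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=(30, 8))
        t1 = self.make_table(p, rng=np.random.default_rng(9))
        t2 = self.make_table(p[:, rng.permutation(8)], rng=np.random.default_rng(9))
        for col in ("med.rank", "vote.rank", "avg.rank", "min.pvalue"):
            assert np.allclose(t1[col], t2[col])

    def test_significance_invariant_to_affine_sigma_transforms(self):
        rng = np.random.default_rng(5)
        table = self.make_table(rng.uniform(size=(25, 6)), rng=rng)
        sig = table["significance"]
        assert sig.min() == pytest.approx(0.0) and sig.max() == pytest.approx(100.0)
        sigma = table["avg.logfc"].abs() * (-np.log10(table["p.adj"]))
        rescaled = 100 * (3 * sigma + 7 - (3 * sigma + 7).min()) / \
            ((3 * sigma + 7).max() - (3 * sigma + 7).min())
        assert np.allclose(sig, rescaled, atol=1e-9)

    def test_sets_with_no_valid_method_dropped_with_warning(self):
        p = np.array([[0.1, 0.2], [0.3, 0.4], [0.5, 0.6]])
        valid = np.array([[True, True], [False, False], [True, False]])
        mrm = mrm_from_p(p, valid=valid)
        rng = np.random.default_rng(6)
        gls = FakeGls(100, rng)
        index = fake_index(mrm.set_names, 100, rng)
        with pytest.warns(UserWarning, match="failed every base method"):
            table = ensemble_scores(mrm, gls, index)
        assert list(table.index) == ["S0", "S2"]
        assert table.loc["S2", "n_methods"] == 1


class TestComparativeScores:
    def test_single_contrast_comparison_is_identity(self):
        rng = np.random.default_rng(7)
        mrm = mrm_from_p(rng.uniform(size=(20, 5)))
        gls = FakeGls(100, rng)
        index = fake_index(mrm.set_names, 100, rng)
        single = ensemble_scores(mrm, gls, index)
        comp = comparative_scores([mrm], gls, index)
        for col in ("p.value", "p.adj", "med.rank", "vote.rank", "avg.logfc",
                    "direction", "significance"):
            assert np.allclose(single[col], comp[col]), col

    def test_two_identical_contrasts_sharpen_wilkinson_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.05, 0.95, size=(15, 4))
        mrm = mrm_from_p(p)

        class G(FakeGls):
            contrast_names = ["c1", "c1b"]

        gls = G(100, rng)
        index = fake_index(mrm.set_names, 100, rng)
        mrm2 = mrm_from_p(p, contrast="c1b")
        comp = comparative_scores([mrm, mrm2], gls, index)
        # per-method comparison p = 1-(1-p)^2 < p, propagated through the
        # ensemble combine step
        single = ensemble_scores(mrm, gls, index)
        assert (comp["p.value"].to_numpy() <=
                1 - (1 - single["p.value"].to_numpy()) ** 2 + 1e-9).all()

    def test_consistent_enrichment_outranks_single_contrast_hit(self):
        # a set enriched in 2 of 3 contrasts should beat one enriched in 1 of 3
        from egse.linmod import gene_level_stats
        from egse.gmt import build_index
        from egse.methods import run_base_methods
        from egse.simulate import make_dataset

        # reference-based contrasts so each planted effect touches exactly the
        # intended contrast; a sum-based combiner (fisher) is what rewards
        # consistency across contrasts (a min-p combiner cannot see the second
        # enriched contrast)
        contr = pd.DataFrame({"B-A": [-1., 1., 0., 0.], "C-A": [-1., 0., 1., 0.],
                              "D-A": [-1., 0., 0., 1.]}, index=list("ABCD"))
        wins = 0
        for seed in range(10):
            exp = make_dataset(
                n_genes=600, groups={"A": 4, "B": 4, "C": 4, "D": 4}, n_sets=40,
                set_size=15,
                planted=[("set001", "B-A", 1.0, 0.5), ("set001", "C-A", 1.0, 0.5),
                         ("set002", "B-A", 1.0, 0.5)],
                seed=100 + seed, contrasts=contr)
            gls = gene_level_stats(exp.expression, exp.design, exp.contrasts)
            ci = build_index(exp.sets, exp.expression.gene_ids)
            mrms = [run_base_methods(gls, exp.expression, ci, c,
                                     methods=("camera", "fry", "gage", "zscore", "ssgsea"),
                                     seed=seed)
                    for c in gls.contrast_names]
            comp = comparative_scores(mrms, gls, ci, combine_method="fisher")
            if comp.loc["set001", "med.rank"] <= comp.loc["set002", "med.rank"]:
                wins += 1
        assert wins >= 9


class TestTopSets:
    def make_lim_table(self):
        """The published luminal-signature score rows (med.rank sorting demo)."""
        rows = {
            "LIM_MAMMARY_LUMINAL_MATURE_DN": (1.646053e-29, 36, 5),
            "LIM_MAMMARY_STEM_CELL_DN": (6.082053e-43, 37, 5),
            "LIM_MAMMARY_LUMINAL_MATURE_UP": (2.469061e-22, 92, 5),
            "LIM_MAMMARY_STEM_CELL_UP": (3.154132e-103, 134, 5),
            "LIM_MAMMARY_LUMINAL_PROGENITOR_UP": (3.871536e-30, 180, 5),
            "LIM_MAMMARY_LUMINAL_PROGENITOR_DN": (2.033005e-06, 636, 115),
        }
        return pd.DataFrame(
            {"p.adj": [v[0] for v in rows.values()],
             "med.rank": [v[1] for v in rows.values()],
             "vote.rank": [v[2] for v in rows.values()]},
            index=list(rows))

    def test_med_rank_sorting_reproduces_published_order(self):
        table = self.make_lim_table()
        out = top_sets(table, "med.rank", 6)
        assert list(out.index) == [
            "LIM_MAMMARY_LUMINAL_MATURE_DN",
            "LIM_MAMMARY_STEM_CELL_DN",
            "LIM_MAMMARY_LUMINAL_MATURE_UP",
            "LIM_MAMMARY_STEM_CELL_UP",
            "LIM_MAMMARY_LUMINAL_PROGENITOR_UP",
            "LIM_MAMMARY_LUMINAL_PROGENITOR_DN",
        ]
        # rank under med.rank is not the p.adj order: the smallest p.adj sits
        # at position 4 here, not position 1
        assert out.index[np.argmin(out["p.adj"].to_numpy())] == "LIM_MAMMARY_STEM_CELL_UP"
        assert out.loc["LIM_MAMMARY_STEM_CELL_UP", "Rank"] == 4

    def test_n_larger_than_table_returns_whole_table(self):
        table = self.make_lim_table()
        assert len(top_sets(table, "p.adj", 100)) == 6

    def test_sort_matches_bruteforce_and_descending_keys(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame({
            "p.adj": rng.uniform(size=30),
            "significance": rng.uniform(0, 100, size=30),
            "direction": rng.choice([-1, 1], size=30),
        }, index=[f"S{i:02d}" for i in range(30)])
        out = top_sets(table, "p.adj", 30)
        assert list(out["p.adj"]) == sorted(table["p.adj"])
        out_sig = top_sets(table, "significance", 30)
        assert list(out_sig["significance"]) == sorted(table["significance"],
                                                       reverse=True)

    def test_unknown_sort_key_rejected(self):
        with pytest.raises(KeyError, match="unknown sort key"):
            top_sets(self.make_lim_table(), "banana", 3)
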