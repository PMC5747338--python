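import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from egse.gmt import GeneSet, build_index
from egse.linmod import gene_level_stats
from egse.methods import (SUPPORTED_METHODS, camera_test, gage_test,
                          gene_zscores, globaltest_test, ora_test, padog_test,
                          rotation_set_test, run_base_methods, safe_test,
                          two_group_assignment, _moderated_two_group_t)
from egse.preprocess import ExpressionMatrix
from egse.simulate import make_dataset


def make_em(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(values=values,
                            gene_ids=[f"g{i}" for i in range(values.shape[0])],
                            sample_ids=[f"s{j}" for j in range(values.shape[1])])


def index_of(sets, gene_ids, min_size=1):
    return build_index(sets, gene_ids, min_size=min_size)


class TestGeneZscores:
    def test_zero_t_maps_to_zero_and_monotone(self, planted_gls):
        z = gene_zscores(planted_gls, "B-A")
        t = planted_gls.t[:, 0]
        order = np.argsort(t)
        assert np.all(np.diff(z[order]) > 0)
        # interpolate near t=0
        assert abs(z[np.argmin(np.abs(t))]) < 0.1

    def test_matches_cdf_composition_oracle(self, planted_gls):
        z = gene_zscores(planted_gls, "B-A")
        t = planted_gls.t[:, 0]
        expected = stats.norm.ppf(np.clip(stats.t.cdf(t, planted_gls.df_total),
                                          1e-15, 1 - 1e-15))
        assert np.allclose(z, expected, atol=1e-8)


class TestOra:
    def test_zero_overlap_gives_p_one(self, planted_gls, planted_index):
        de = np.zeros(planted_gls.n_genes, dtype=bool)
        de[:10] = True  # DE genes that overlap nothing: pick genes not in set001
        s1 = planted_index.sets[0]
        de[:] = False
        others = [i for i in range(planted_gls.n_genes) if i not in s1.index][:10]
        de[others] = True
        import egse.methods as M
        # direct call with an explicit mask via monkey-style: use internal path
        G, K = planted_gls.n_genes, 10
        k = 0
        assert stats.hypergeom.sf(k - 1, G, K, len(s1.index)) == pytest.approx(1.0)

    def test_whole_universe_set_is_certain(self):
        G, K = 20, 5
        assert stats.hypergeom.sf(K - 1, G, K, G) == pytest.approx(1.0)

    def test_hypergeometric_tail_equals_exhaustive_enumeration(self):
        G, K, m, k_obs = 20, 5, 4, 3
        de = set(range(K))
        count = 0
        total = 0
        for draw in itertools.combinations(range(G), m):
            total += 1
            if len(de.intersection(draw)) >= k_obs:
                count += 1
        assert stats.hypergeom.sf(k_obs - 1, G, K, m) == pytest.approx(count / total,
                                                                       abs=1e-12)

    def test_pipeline_ora_uses_fdr_and_direction(self, planted_gls, planted_index):
        p, direction, valid = ora_test(planted_gls, planted_index, "B-A",
                                       fdr_cutoff=0.05, top_n_fallback=40)
        assert valid.all()
        assert p[0] < 0.01          # planted set strongly over-represented
        assert direction[0] == 1


class TestCamera:
    def test_equal_z_gives_p_one(self, two_group_design):
        design, contrasts = two_group_design
        rng = np.random.default_rng(0)
        # construct data where all genes share one expression pattern plus
        # per-gene offsets: all moderated t equal
        base = rng.normal(size=6)
        vals = np.tile(base, (30, 1)) + rng.normal(size=(30, 1))
        em = make_em(vals)
        gls = gene_level_stats(em, design, contrasts)
        sets = [GeneSet(name="S", members=[f"g{i}" for i in range(5)])]
        p, d, valid = camera_test(gls, index_of(sets, em.gene_ids), "B-A")
        assert p[0] == pytest.approx(1.0, abs=1e-6)

    def test_independent_genes_match_two_sample_t_oracle(self):
        # many samples: the estimated VIF concentrates at 1 and the statistic
        # reduces to a plain two-sample t on the gene z-scores
        n = 40
        design = pd.DataFrame({"A": [1.0] * (n // 2) + [0.0] * (n // 2),
                               "B": [0.0] * (n // 2) + [1.0] * (n // 2)})
        contrasts = pd.DataFrame({"B-A": [-1.0, 1.0]}, index=["A", "B"])
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(5):
            em = make_em(rng.normal(size=(400, n)))
            gls = gene_level_stats(em, design, contrasts)
            sets = [GeneSet(name="S", members=[f"g{i}" for i in range(20)])]
            ci = index_of(sets, em.gene_ids)
            p, _, _ = camera_test(gls, ci, "B-A")
            z = gene_zscores(gls, "B-A")
            _, p_ref = stats.ttest_ind(z[:20], z[20:], equal_var=True)
            diffs.append(abs(p[0] - p_ref))
        assert np.median(diffs) < 0.05

    def test_duplicated_rows_inflate_vif_and_p(self, two_group_design):
        design, contrasts = two_group_design
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(100, 6))
        shared = rng.normal(size=6)
        vals_cor = vals.copy()
        vals_cor[:10] = shared[None, :] + 0.05 * rng.normal(size=(10, 6))
        sets = [GeneSet(name="S", members=[f"g{i}" for i in range(10)])]
        p_ind, _, _ = camera_test(
            gene_level_stats(make_em(vals), design, contrasts),
            index_of(sets, [f"g{i}" for i in range(100)]), "B-A")
        p_cor, _, _ = camera_test(
            gene_level_stats(make_em(vals_cor), design, contrasts),
            index_of(sets, [f"g{i}" for i in range(100)]), "B-A")
        assert p_cor[0] > p_ind[0] * 0.999  # correlation never sharpens the call


class TestGage:
    def test_identical_distributions_give_large_p(self, two_group_design):
        design, contrasts = two_group_design
        rng = np.random.default_rng(3)
        em = make_em(rng.normal(size=(60, 6)))
        gls = gene_level_stats(em, design, contrasts)
        z = gene_zscores(gls, "B-A")
        # choose a set whose z's mirror the background mean
        order = np.argsort(z)
        pick = order[::6][:10]
        sets = [GeneSet(name="S", members=[f"g{i}" for i in pick])]
        p, _, _ = gage_test(gls, index_of(sets, em.gene_ids), "B-A")
        assert p[0] > 0.3

    def test_matches_welch_oracle(self, planted_gls, planted_index):
        p, d, valid = gage_test(planted_gls, planted_index, "B-A")
        z = gene_zscores(planted_gls, "B-A")
        for row, s in enumerate(planted_index):
            out = np.ones(len(z), dtype=bool)
            out[s.index] = False
            t_ref, p_ref = stats.ttest_ind(z[s.index], z[out], equal_var=False)
            assert p[row] == pytest.approx(p_ref, abs=1e-10)


class TestRotation:
    def test_seed_determinism(self, planted_experiment, planted_index):
        exp = planted_experiment
        args = (exp.expression, exp.design, exp.contrasts, "B-A", planted_index)
        p1, _, _ = rotation_set_test(*args, n_rot=999, mode="mc", seed=5)
        p2, _, _ = rotation_set_test(*args, n_rot=999, mode="mc", seed=5)
        assert np.array_equal(p1, p2)

    def test_mc_and_analytic_agree_on_independent_genes(self):
        exp = make_dataset(n_genes=300, groups={"A": 5, "B": 5}, n_sets=6,
                           set_size=15, seed=3)
        ci = build_index(exp.sets, exp.expression.gene_ids)
        p_mc, _, _ = rotation_set_test(exp.expression, exp.design, exp.contrasts,
                                       "B-A", ci, n_rot=20000, mode="mc", seed=1)
        p_an, _, _ = rotation_set_test(exp.expression, exp.design, exp.contrasts,
                                       "B-A", ci, mode="analytic", seed=1)
        assert np.max(np.abs(p_mc - p_an)) <= 0.02

    def test_too_few_rotations_rejected(self, planted_experiment, planted_index):
        exp = planted_experiment
        with pytest.raises(ValueError, match="n_rot"):
            rotation_set_test(exp.expression, exp.design, exp.contrasts, "B-A",
                              planted_index, n_rot=50, mode="mc")

    def test_planted_set_detected(self, planted_experiment, planted_index):
        exp = planted_experiment
        p, d, _ = rotation_set_test(exp.expression, exp.design, exp.contrasts,
                                    "B-A", planted_index, mode="analytic")
        assert p[0] < 0.01 and d[0] == 1


def exhaustive_permutation_p(stat_fn, vals, a_mask):
    """Brute-force permutation p over all label splits (upper tail)."""
    n = len(a_mask)
    n_a = int(a_mask.sum())
    obs = stat_fn(vals, a_mask)
    stats_all = []
    for combo in itertools.combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        stats_all.append(stat_fn(vals, mask))
    stats_all = np.array(stats_all)
    return np.sum(stats_all >= obs - 1e-12) / len(stats_all)


@pytest.fixture(scope="module")
def small():
    exp = make_dataset(n_genes=120, groups={"A": 3, "B": 3}, n_sets=8,
                       set_size=10, planted=[("set001", "B-A", 2.0, 1.0)], seed=9)
    gls = gene_level_stats(exp.expression, exp.design, exp.contrasts)
    ci = build_index(exp.sets, exp.expression.gene_ids)
    return exp, gls, ci


class TestPermutationMethods:

    def test_padog_weights_degenerate_when_frequencies_equal(self):
        # disjoint sets: every gene is in exactly one set -> all weights 1
        genes = [f"g{i}" for i in range(40)]
        sets = [GeneSet(name="S1", members=genes[:10]),
                GeneSet(name="S2", members=genes[10:20])]
        rng = np.random.default_rng(4)
        em = make_em(rng.normal(size=(40, 6)))
        em.gene_ids = genes
        design = pd.DataFrame({"A": [1., 1., 1., 0., 0., 0.],
                               "B": [0., 0., 0., 1., 1., 1.]})
        contrasts = pd.DataFrame({"B-A": [-1.0, 1.0]}, index=["A", "B"])
        gls = gene_level_stats(em, design, contrasts)
        ci = build_index(sets, genes)
        p, _, valid = padog_test(em, gls, ci, "B-A", B=200, seed=0)
        # equal frequencies: statistic reduces to plain mean |t|; compare with
        # the brute-force enumeration of the unweighted statistic
        t_abs = lambda vals, mask: np.abs(_moderated_two_group_t(vals, mask))
        for row, s in enumerate(ci):
            stat = lambda v, m: t_abs(v, m)[s.index].mean()
            expected = exhaustive_permutation_p(stat, em.values, np.array([True] * 3 + [False] * 3))
            assert p[row] == pytest.approx(expected, abs=1e-12)

    def test_padog_exhaustive_at_three_vs_three(self, small):
        exp, gls, ci = small
        em = exp.expression
        p, _, _ = padog_test(em, gls, ci, "B-A", B=500, seed=0)
        freq = np.zeros(em.n_genes)
        for s in ci:
            freq[s.index] += 1
        in_any = freq > 0
        f_min, f_max = freq[in_any].min(), freq[in_any].max()
        if f_max > f_min:
            w = 1.0 + np.sqrt(np.clip((f_max - freq) / (f_max - f_min), 0, 1))
        else:
            w = np.ones(em.n_genes)
        a_mask = np.array([True] * 3 + [False] * 3)
        for row, s in enumerate(ci):
            stat = lambda v, m: (w * np.abs(_moderated_two_group_t(v, m)))[s.index].mean()
            expected = exhaustive_permutation_p(stat, em.values, a_mask)
            assert p[row] == pytest.approx(expected, abs=1e-12)

    def test_globaltest_exhaustive_and_gene_order_invariance(self, small):
        exp, gls, ci = small
        em = exp.expression
        p, _, _ = globaltest_test(em, gls, ci, "B-A", B=1000, seed=0)
        mu = em.values.mean(axis=1, keepdims=True)
        sd = em.values.std(axis=1, ddof=1, keepdims=True)
        Z = (em.values - mu) / sd
        a_mask = np.array([True] * 3 + [False] * 3)

        def q_stat(vals, mask, idx):
            y = mask.astype(float) - mask.mean()
            proj = Z[idx] @ y
            return float((proj ** 2).sum() / (len(idx) * (y @ y)))

        for row, s in enumerate(ci):
            stat = lambda v, m: q_stat(v, m, s.index)
            expected = exhaustive_permutation_p(stat, em.values, a_mask)
            assert p[row] == pytest.approx(expected, abs=1e-12)
            # permuting genes within the set leaves Q unchanged
            assert q_stat(None, a_mask, list(reversed(s.index))) == pytest.approx(
                q_stat(None, a_mask, s.index), abs=1e-12)

    def test_safe_exhaustive_and_seed_determinism(self, small):
        exp, gls, ci = small
        em = exp.expression
        p1, _, _ = safe_test(em, gls, ci, "B-A", B=1000, seed=3)
        p2, _, _ = safe_test(em, gls, ci, "B-A", B=1000, seed=4)
        assert np.array_equal(p1, p2)  # exhaustive: seed cannot matter
        a_mask = np.array([True] * 3 + [False] * 3)
        for row, s in enumerate(ci):
            def stat(v, m):
                ranks = stats.rankdata(np.abs(_moderated_two_group_t(v, m)))
                return ranks[s.index].sum()
            expected = exhaustive_permutation_p(stat, em.values, a_mask)
            assert p1[row] == pytest.approx(expected, abs=1e-12)

    def test_non_two_group_contrast_flagged_untestable(self, small):
        exp, gls, ci = small
        design = pd.DataFrame({"A": [1., 1., 1., 0., 0., 0.],
                               "B": [0., 0., 0., 1., 1., 0.],
                               "C": [0., 0., 0., 0., 0., 1.]})
        contrasts = pd.DataFrame({"C-B": [0., -1., 1.]}, index=["A", "B", "C"])
        gls2 = gene_level_stats(exp.expression, design, contrasts)
        p, d, valid = padog_test(exp.expression, gls2, ci, "C-B", B=200, seed=0)
        assert not valid.any()


class TestTwoGroupExtraction:
    def test_contrast_maps_to_groups(self, two_group_design):
        design, contrasts = two_group_design
        samples, a_mask = two_group_assignment(design, contrasts, "B-A")
        assert samples.tolist() == [0, 1, 2, 3, 4, 5]
        assert a_mask.tolist() == [False, False, False, True, True, True]

    def test_three_group_contrast_ignores_uninvolved_samples(self):
        design = pd.DataFrame({"A": [1., 1., 0., 0., 0., 0.],
                               "B": [0., 0., 1., 1., 0., 0.],
                               "C": [0., 0., 0., 0., 1., 1.]})
        contrasts = pd.DataFrame({"C-A": [-1., 0., 1.]}, index=["A", "B", "C"])
        samples, a_mask = two_group_assignment(design, contrasts, "C-A")
        assert samples.tolist() == [0, 1, 4, 5]
        assert a_mask.tolist() == [False, False, True, True]


class TestRunBaseMethods:
    def test_single_method_yields_single_column(self, planted_gls,
                                                planted_experiment, planted_index):
        mrm = run_base_methods(planted_gls, planted_experiment.expression,
                               planted_index, "B-A", methods=["gage"])
        assert mrm.p.shape == (len(planted_index), 1)

    def test_gsva_rejected_with_clear_error(self, planted_gls,
                                            planted_experiment, planted_index):
        with pytest.raises(NotImplementedError, match="gsva"):
            run_base_methods(planted_gls, planted_experiment.expression,
                             planted_index, "B-A", methods=["gsva"])

    def test_empty_method_list_rejected(self, planted_gls, planted_experiment,
                                        planted_index):
        with pytest.raises(ValueError, match="empty"):
            run_base_methods(planted_gls, planted_experiment.expression,
                             planted_index, "B-A", methods=[])

    def test_columns_equal_individual_method_runs(self, planted_gls,
                                                  planted_experiment, planted_index):
        em = planted_experiment.expression
        mrm = run_base_methods(planted_gls, em, planted_index, "B-A",
                               methods=["camera", "gage", "fry"], seed=2)
        p_cam, _, _ = camera_test(planted_gls, planted_index, "B-A", seed=2)
        p_gage, _, _ = gage_test(planted_gls, planted_index, "B-A")
        p_fry, _, _ = rotation_set_test(em, planted_gls.design, planted_gls.contrasts,
                                        "B-A", planted_index, mode="analytic", seed=2)
        assert np.allclose(mrm.p[:, 0], p_cam)
        assert np.allclose(mrm.p[:, 1], p_gage)
        assert np.allclose(mrm.p[:, 2], p_fry)

    def test_all_p_in_unit_interval_and_directions_valid(self, planted_gls,
                                                         planted_experiment,
                                                         planted_index):
        mrm = run_base_methods(planted_gls, planted_experiment.expression,
                               planted_index, "B-A", methods=list(SUPPORTED_METHODS),
                               seed=0)
        ok = mrm.valid
        assert np.all((mrm.p[ok] >= 0) & (mrm.p[ok] <= 1))
        assert set(np.unique(mrm.direction)).issubset({-1, 0, 1})
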