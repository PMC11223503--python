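"""Generators: determinism, planted structure, statistical contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.sparse.csgraph import connected_components

from pathodyn.synthetic_data import (GroundTruth, generate_celltype_specificity,
                                     generate_cohort, generate_connectome,
                                     generate_drug_signature_library,
                                     generate_expression_matrix,
                                     generate_observed_falff,
                                     generate_probe_table, generate_term_sets)


class TestConnectome:
    def test_structure_and_density(self):
        conn = generate_connectome(66, density=0.3, seed=0)
        C = conn.matrix
        assert C.shape == (66, 66)
        assert np.allclose(C, C.T)
        assert np.all(np.diag(C) == 0)
        assert C.min() >= 0 and C.max() <= 1
        off = C[np.triu_indices(66, k=1)]
        assert np.mean(off > 0) == pytest.approx(0.3, abs=0.05)
        n_comp, _ = connected_components(C > 0, directed=False)
        assert n_comp == 1

    def test_two_regions_full_density(self):
        conn = generate_connectome(2, density=1.0, seed=1)
        C = conn.matrix
        assert C[0, 1] == C[1, 0] > 0
        assert C[0, 0] == C[1, 1] == 0

    def test_seeded_determinism(self):
        a = generate_connectome(20, 0.2, seed=5)
        b = generate_connectome(20, 0.2, seed=5)
        assert np.array_equal(a.matrix, b.matrix)

    @pytest.mark.parametrize("n,density", [(1, 0.5), (5, 0.0), (5, 1.2)])
    def test_invalid_arguments(self, n, density):
        with pytest.raises(ValueError):
            generate_connectome(n, density, seed=0)


class TestCohort:
    def test_study_group_sizes(self, small_connectome):
        cohort, truth = generate_cohort(small_connectome, n_cu=47, n_ad=16,
                                        theta_scale=0.8, seed=0)
        assert len(cohort) == 63
        assert sum(r.group == "AD" for r in cohort) == 16
        assert set(truth.true_thetas) == {r.subject_id for r in cohort}

    def test_zero_scale_gives_zero_thetas(self, small_connectome):
        cohort, _ = generate_cohort(small_connectome, n_cu=3, n_ad=3,
                                    theta_scale=0.0, seed=1)
        for rec in cohort:
            assert rec.true_thetas == (0.0, 0.0, 0.0)

    def test_ad_tau_exceeds_cu_tau(self, small_connectome):
        cohort, _ = generate_cohort(small_connectome, seed=2)
        ad = np.mean([r.tau_suvr.mean() for r in cohort if r.group == "AD"])
        cu = np.mean([r.tau_suvr.mean() for r in cohort if r.group == "CU"])
        assert ad > cu

    def test_suvr_strictly_positive(self, small_connectome):
        cohort, _ = generate_cohort(small_connectome, n_cu=5, n_ad=5, seed=3)
        for rec in cohort:
            assert rec.abeta_suvr.min() > 0 and rec.tau_suvr.min() > 0

    def test_cu_thetas_zero_ad_bounded(self, small_connectome):
        cohort, _ = generate_cohort(small_connectome, n_cu=4, n_ad=4,
                                    theta_scale=0.6, seed=4)
        for rec in cohort:
            t = np.array(rec.true_thetas)
            if rec.group == "CU":
                assert np.all(t == 0)
            else:
                assert np.all(np.abs(t) <= 0.6)
                assert np.all(np.abs(t) > 0)


class TestObservedFalff:
    def test_no_noise_matches_forward_model(self, small_connectome,
                                            fast_config):
        from pathodyn.fitting import forward_falff, subject_profile
        from pathodyn.neurodynamics import ThetaTriplet
        cohort, _ = generate_cohort(small_connectome, n_cu=1, n_ad=1, seed=5)
        out = generate_observed_falff(cohort, small_connectome, fast_config,
                                      noise_sd=0.0, seed=0)
        for rec in out:
            direct = forward_falff(ThetaTriplet(*rec.true_thetas),
                                   subject_profile(rec), small_connectome,
                                   fast_config)
            assert np.array_equal(rec.falff, np.clip(direct, 0, 1))

    def test_values_in_unit_interval(self, small_connectome, fast_config):
        cohort, _ = generate_cohort(small_connectome, n_cu=1, n_ad=1, seed=6)
        out = generate_observed_falff(cohort, small_connectome, fast_config,
                                      noise_sd=0.2, seed=1)
        for rec in out:
            assert rec.falff.min() >= 0 and rec.falff.max() <= 1

    def test_identical_subjects_identical_falff(self, small_connectome,
                                                fast_config):
        cohort, _ = generate_cohort(small_connectome, n_cu=1, n_ad=1, seed=7)
        twin_a = cohort[1]
        import copy
        twin_b = copy.deepcopy(twin_a)
        out = generate_observed_falff([twin_a, twin_b], small_connectome,
                                      fast_config, noise_sd=0.0, seed=2)
        assert np.array_equal(out[0].falff, out[1].falff)


class TestExpression:
    def test_planted_genes_correlate(self):
        rng = np.random.default_rng(0)
        pattern = rng.standard_normal(66)
        X, genes, planted = generate_expression_matrix(
            50, 66, pattern, n_planted=20, planted_rho=0.99, seed=1)
        assert planted == genes[:20]
        for row in X[:20]:
            assert stats.spearmanr(pattern, row).statistic > 0.8

    def test_seeded_determinism(self):
        pattern = np.arange(30.0)
        a, _, _ = generate_expression_matrix(40, 30, pattern, 5, 0.9, seed=9)
        b, _, _ = generate_expression_matrix(40, 30, pattern, 5, 0.9, seed=9)
        assert np.array_equal(a, b)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            generate_expression_matrix(10, 20, np.arange(20.0), 2, 1.0)

    def test_all_values_finite(self):
        X, _, _ = generate_expression_matrix(30, 20, np.arange(20.0), 10,
                                             0.5, seed=3)
        assert np.all(np.isfinite(X))


class TestProbeTable:
    def test_planted_best_probe_is_lowest_noise(self):
        table, coords, best = generate_probe_table(
            5, 3, 40, noise_per_probe=[0.01, 1.0, 1.0], seed=0)
        assert all(b.endswith("_P0") for b in best.values())
        assert coords.shape == (40, 3)
        assert len(table) == 15

    def test_single_probe_rejected(self):
        with pytest.raises(ValueError):
            generate_probe_table(3, 1, 10, noise_per_probe=[0.1], seed=0)

    def test_noise_vector_length_checked(self):
        with pytest.raises(ValueError):
            generate_probe_table(3, 3, 10, noise_per_probe=[0.1, 0.2], seed=0)

    def test_seeded_determinism(self):
        a, ca, _ = generate_probe_table(4, 2, 20, [0.05, 1.0], seed=4)
        b, cb, _ = generate_probe_table(4, 2, 20, [0.05, 1.0], seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert np.array_equal(ca, cb)


class TestSpecificity:
    def test_rows_sum_to_one(self):
        spec, _, _ = generate_celltype_specificity(
            100, 6, [f"G{i:05d}" for i in range(10)], "CT00", boost=5.0,
            seed=0)
        assert np.allclose(spec.sum(axis=1), 1.0, atol=1e-12)

    def test_identity_boost_changes_nothing(self):
        planted = [f"G{i:05d}" for i in range(10)]
        a, _, _ = generate_celltype_specificity(50, 4, planted, "CT01",
                                                boost=1.0, seed=1)
        b, _, _ = generate_celltype_specificity(50, 4, [], "CT01",
                                                boost=5.0, seed=1)
        assert np.allclose(a, b)

    def test_planted_mean_exceeds_background(self):
        planted = [f"G{i:05d}" for i in range(20)]
        spec, genes, cts = generate_celltype_specificity(
            200, 8, planted, "CT03", boost=5.0, seed=2)
        col = cts.index("CT03")
        assert spec[:20, col].mean() > spec[20:, col].mean()

    def test_invalid_boost_rejected(self):
        with pytest.raises(ValueError):
            generate_celltype_specificity(10, 2, [], "CT00", boost=0.0)


class TestDrugLibrary:
    UNIVERSE = [f"G{i:05d}" for i in range(200)]
    QUERY = UNIVERSE[:20]

    def test_each_column_is_permutation(self):
        lib = generate_drug_signature_library(self.UNIVERSE, 10, ["D000"],
                                              ["D001"], self.QUERY, seed=0)
        for ranking in lib.values():
            assert sorted(ranking) == sorted(self.UNIVERSE)

    def test_full_strength_puts_query_on_top(self):
        lib = generate_drug_signature_library(self.UNIVERSE, 5, ["D000"],
                                              ["D001"], self.QUERY,
                                              strength=1.0, seed=1)
        assert set(lib["D000"][:20]) == set(self.QUERY)
        assert set(lib["D001"][-20:]) == set(self.QUERY)

    def test_unplanted_mean_rank_central(self):
        """Mean query rank in unplanted drugs ~ (|universe|+1)/2."""
        means = []
        for seed in range(100):
            lib = generate_drug_signature_library(self.UNIVERSE, 1, [], [],
                                                  self.QUERY, seed=seed)
            ranking = lib["D000"]
            ranks = [ranking.index(g) + 1 for g in self.QUERY]
            means.append(np.mean(ranks))
        assert np.mean(means) == pytest.approx((200 + 1) / 2, rel=0.05)

    def test_up_down_overlap_rejected(self):
        with pytest.raises(ValueError, match="both"):
            generate_drug_signature_library(self.UNIVERSE, 5, ["D000"],
                                            ["D000"], self.QUERY)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            generate_drug_signature_library(self.UNIVERSE, 5, [], [],
                                            ["NOPE"])


def test_cohort_separability_across_seeds(fast_config):
    """AD and CU observed fALFF separate in at least one region (rank-sum
    p < 0.05) for nearly every generator seed."""
    from scipy import stats
    from dataclasses import replace
    cfg = replace(fast_config, duration=65.0)  # 50 s retained window
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        conn = generate_connectome(16, 0.3, seed=1000 + seed)
        # generator-default (study-sized) groups: 47 CU vs 16 AD
        cohort, _ = generate_cohort(conn, theta_scale=0.5, seed=2000 + seed)
        cohort = generate_observed_falff(cohort, conn, cfg,
                                         noise_sd=0.02, seed=3000 + seed)
        ad = np.array([r.falff for r in cohort if r.group == "AD"])
        cu = np.array([r.falff for r in cohort if r.group == "CU"])
        ps = [stats.ranksums(ad[:, k], cu[:, k]).pvalue
              for k in range(ad.shape[1])]
        hits += min(ps) < 0.05
    assert hits / n_seeds >= 0.95


def test_term_sets_contain_planted():
    genes = [f"G{i:05d}" for i in range(100)]
    terms = generate_term_sets(genes, genes[:10], n_terms=5, term_size=20,
                               seed=0)
    assert set(genes[:10]) <= set(terms["T000"])
    assert len(terms) == 5


def test_ground_truth_roundtrip(tmp_path):
    truth = GroundTruth(true_thetas={"AD000": (0.1, -0.2, 0.3)},
                        planted_genes=["G00001"],
                        planted_celltypes=["CT00"],
                        planted_drugs={"D000": "up"}, seed=7)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    assert GroundTruth.from_json(path) == truth
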