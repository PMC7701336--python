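"""Validation battery: PCA, Welch/Mann-Whitney, Huber regression, reference comparison."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.api as sm

from cardioclust.simulate import SimConfig, simulate_cohort
from cardioclust.validation import (
    DegenerateTestError,
    compare_to_ground_truth,
    huber_fit,
    mann_whitney_u,
    pairwise_cluster_tests,
    pca_project,
    percent_mean_difference,
    welch_t_test,
)


class TestPCA:
    def test_rank2_data_explains_everything(self, rng):
        basis = rng.normal(size=(2, 8))
        scores = rng.normal(size=(100, 2))
        X = scores @ basis
        proj = pca_project(X, centers=X[:3], standardize=False)
        assert proj.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_loadings_match_eigendecomposition(self, rng):
        X = rng.normal(size=(20, 4)) @ rng.normal(size=(4, 4))
        proj = pca_project(X, centers=X[:2])
        Z = (X - proj.mean_) / proj.scale_
        evals, evecs = np.linalg.eigh(np.cov(Z.T, bias=True))
        order = np.argsort(evals)[::-1]
        for i in range(2):
            v = evecs[:, order[i]]
            got = proj.components_[i]
            assert abs(abs(v @ got)) == pytest.approx(1.0, abs=1e-8)

    def test_score_variance_equals_top_eigenvalues(self, rng):
        X = rng.normal(size=(300, 5)) @ rng.normal(size=(5, 5))
        proj = pca_project(X, centers=X[:1])
        Z = (X - proj.mean_) / proj.scale_
        evals = np.sort(np.linalg.eigvalsh(np.cov(Z.T, bias=True)))[::-1]
        score_var = proj.case_scores.var(axis=0)
        np.testing.assert_allclose(score_var, evals[:2], rtol=1e-8)
        np.testing.assert_allclose(proj.case_scores.mean(axis=0), 0, atol=1e-9)

    def test_orthonormal_loadings_and_center_transform(self, rng):
        X = rng.normal(size=(50, 4))
        centers = rng.normal(size=(3, 4))
        proj = pca_project(X, centers)
        np.testing.assert_allclose(proj.components_ @ proj.components_.T, np.eye(2), atol=1e-10)
        manual = ((centers - proj.mean_) / proj.scale_) @ proj.components_.T
        np.testing.assert_allclose(proj.center_scores, manual, atol=1e-12)

    def test_pathological_centers_far_from_centroid(self, features, latent, screening_report):
        """Planted rare-subgroup centers project farther from the score
        centroid than the median normal-subgroup center does."""
        sel = screening_report.selected
        X = features[sel].to_numpy(float)
        groups = latent["subgroup"].to_numpy()
        names = sorted(set(groups))
        centers = np.vstack([X[groups == g].mean(axis=0) for g in names])
        proj = pca_project(X, centers)
        dist = np.linalg.norm(proj.center_scores, axis=1)
        d = dict(zip(names, dist))
        med_normal = np.median([d[f"NOR_{i}"] for i in range(1, 8)])
        assert d["RVA"] > med_normal
        assert d["DCM"] > med_normal

    def test_input_validation(self, rng):
        X = rng.normal(size=(30, 3))
        with pytest.raises(ValueError):
            pca_project(X, X[:2], n_components=4)


class TestWelch:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = welch_t_test(a, a.copy())
        assert t == 0.0 and p == 1.0

    def test_textbook_instance_matches_scipy(self):
        a = [19.8, 20.4, 19.6, 17.8, 18.5]
        b = [28.2, 26.6, 20.1, 23.3, 25.2]
        t, p = welch_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_separated_normals_tiny_p(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        _, p = welch_t_test(a, b)
        assert p < 1e-7

    def test_random_instances_match_scipy(self, rng):
        for _ in range(50):
            a = rng.normal(size=rng.integers(5, 40))
            b = rng.normal(loc=rng.normal(), size=rng.integers(5, 40))
            t, p = welch_t_test(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


class TestMannWhitney:
    def test_complete_separation_3v3_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 arrangements

    def test_identical_samples_exact_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_all_tied_degenerate(self):
        with pytest.raises(DegenerateTestError):
            mann_whitney_u([2.0, 2.0], [2.0, 2.0])

    def test_exact_matches_scipy_no_ties(self, rng):
        for _ in range(25):
            a = rng.normal(size=int(rng.integers(3, 8)))
            b = rng.normal(size=int(rng.integers(3, 8)))
            u, p = mann_whitney_u(a, b, method="exact")
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_asymptotic_matches_scipy_with_ties(self, rng):
        for _ in range(25):
            a = rng.integers(0, 6, size=40).astype(float)
            b = rng.integers(1, 7, size=35).astype(float)
            u, p = mann_whitney_u(a, b, method="asymptotic")
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_normal_approximation_close_to_exact_all_4v4(self):
        """Tie-free 4v4 instances: the continuity-corrected normal
        approximation tracks the exact enumeration tightly in the
        decision-relevant tail (within 0.0075 whenever exact p <= 0.2) and
        within 0.035 everywhere (U is integer-valued with sd ~3.5 at this n,
        so mid-range p cannot be approximated more closely)."""
        vals = np.arange(8, dtype=float)
        for a_idx in combinations(range(8), 4):
            a = vals[list(a_idx)]
            b = vals[[i for i in range(8) if i not in a_idx]]
            _, p_exact = mann_whitney_u(a, b, method="exact")
            _, p_approx = mann_whitney_u(a, b, method="asymptotic")
            assert abs(p_exact - p_approx) <= 0.035
            if p_exact <= 0.2:
                assert abs(p_exact - p_approx) <= 0.0075


class TestPairwiseBattery:
    def test_cell_count_seven_clusters_eight_features(self, rng):
        n = 7 * 30
        table = pd.DataFrame(
            rng.normal(size=(n, 8)), columns=[f"f{i}" for i in range(8)]
        )
        assign = np.repeat(np.arange(7), 30)
        rep = pairwise_cluster_tests(table, assign, list(range(7)), list(table.columns))
        assert rep.n_cells == 168  # 21 pairs x 8 features
        counts = rep.counts()
        assert counts["welch_p"]["below_alpha"] + counts["welch_p"]["at_or_above_alpha"] == 168

    def test_single_pair_single_feature(self, rng):
        table = pd.DataFrame({"f": rng.normal(size=40)})
        assign = np.repeat([0, 1], 20)
        rep = pairwise_cluster_tests(table, assign, [0, 1], ["f"])
        assert rep.n_cells == 1

    def test_type_one_error_calibration(self):
        """Two clusters drawn from one distribution: fraction of Welch cells
        below 0.05 is ~0.05 over 200 replicates."""
        hits = 0
        total = 0
        for seed in range(200):
            r = np.random.default_rng(3000 + seed)
            table = pd.DataFrame({"f": r.normal(size=120)})
            assign = np.repeat([0, 1], 60)
            rep = pairwise_cluster_tests(table, assign, [0, 1], ["f"])
            hits += int((rep.cells["welch_p"] < 0.05).sum())
            total += 1
        assert abs(hits / total - 0.05) < 0.03

    def test_undersized_cluster_rejected(self, rng):
        table = pd.DataFrame({"f": rng.normal(size=10)})
        assign = np.array([0] * 9 + [1])
        with pytest.raises(ValueError):
            pairwise_cluster_tests(table, assign, [0, 1], ["f"])


class TestHuber:
    def test_noiseless_line_recovered(self, rng):
        x = rng.uniform(20, 120, 500)
        y = 1.002 * x + 3.373
        fit = huber_fit(x, y)
        assert fit.slope == pytest.approx(1.002, abs=1e-6)
        assert fit.intercept == pytest.approx(3.373, abs=1e-6)

    def test_outlier_resistance_beats_ols(self, rng):
        x = rng.uniform(0, 10, 1000)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.3, 1000)
        out = rng.choice(1000, 100, replace=False)
        y[out] += rng.uniform(20, 60, 100)
        fit = huber_fit(x, y)
        ols = np.polyfit(x, y, 1)
        assert abs(fit.slope - 2.0) < 0.02 or abs(fit.slope - 2.0) < abs(ols[0] - 2.0)
        assert abs(ols[0] - 2.0) + abs(ols[1] - 1.0) > abs(fit.slope - 2.0) + abs(
            fit.intercept - 1.0
        )

    def test_constant_y(self, rng):
        x = rng.uniform(size=50)
        fit = huber_fit(x, np.full(50, 7.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-10)
        assert fit.intercept == pytest.approx(7.0, abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            huber_fit(np.ones(10), np.arange(10.0))

    def test_matches_statsmodels_rlm(self, rng):
        """IRLS Huber fit agrees with the statsmodels RLM reference on
        contaminated random instances."""
        for i in range(10):
            r = np.random.default_rng(500 + i)
            x = r.uniform(0, 50, 300)
            y = 0.9 * x + 5 + r.normal(0, 2, 300)
            y[r.choice(300, 15, replace=False)] *= 3
            fit = huber_fit(x, y)
            rlm = sm.RLM(
                y, sm.add_constant(x), M=sm.robust.norms.HuberT(t=1.345)
            ).fit(scale_est="mad")
            assert fit.intercept == pytest.approx(rlm.params[0], abs=0.15)
            assert fit.slope == pytest.approx(rlm.params[1], abs=0.01)

    def test_recovers_generative_line_from_default_reference_channel(self):
        """The reference channel's generative line (slope 1.002, intercept
        3.373 for EDV) is recovered within 0.03 / 1.5 despite the planted
        outlier contamination, over 10 cohort seeds."""
        for seed in range(10):
            _, feats, gt = simulate_cohort(SimConfig(seed=600 + seed))
            esv = feats["V_LV_ES"].to_numpy()
            edv = esv / (1 - feats["EF_LV"].to_numpy())
            fit = huber_fit(edv, gt["gt_V_LV_ED"].to_numpy())
            assert abs(fit.slope - 1.002) < 0.03
            assert abs(fit.intercept - 3.373) < 1.5


class TestGroundTruthComparison:
    def test_identity_reference(self, features):
        esv = features["V_LV_ES"].to_numpy()
        edv = esv / (1 - features["EF_LV"].to_numpy())
        gt = pd.DataFrame(
            {
                "case_id": features["case_id"],
                "gt_V_LV_ED": edv,
                "gt_V_LV_ES": esv,
                "gt_EF_LV": features["EF_LV"],
                "is_outlier": False,
            }
        )
        cmp_res = compare_to_ground_truth(features, gt)
        row = cmp_res.measures.set_index("measure")
        assert row.loc["LV_EDV", "pct_mean_diff"] == pytest.approx(0.0, abs=1e-12)
        assert cmp_res.huber_fits["LV_EDV"].slope == pytest.approx(1.0, abs=1e-6)
        assert cmp_res.huber_fits["LV_EDV"].intercept == pytest.approx(0.0, abs=1e-4)

    def test_percent_difference_formula(self):
        # printed cohort means: 75.48 vs 70.56 -> +7.0%; 33.87 vs 24.06 -> +40.8%
        assert round(100 * percent_mean_difference(75.48, 70.56), 1) == 7.0
        assert round(100 * percent_mean_difference(33.87, 24.06), 1) == 40.8

    def test_unmatched_ids_raise(self, features, ground_truth):
        with pytest.raises(ValueError, match="unmatched"):
            compare_to_ground_truth(features.head(100), ground_truth)

    def test_default_channel_inflates_reference_moments(self, features, ground_truth):
        cmp_res = compare_to_ground_truth(features, ground_truth)
        row = cmp_res.measures.set_index("measure")
        assert row.loc["LV_EDV", "pct_mean_diff"] > 0
        assert row.loc["LV_ESV", "pct_mean_diff"] > 0
        assert row.loc["LV_EDV", "gt_sd"] > row.loc["LV_EDV", "pipeline_sd"]
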