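import numpy as np
import pandas as pd
import pytest

from heteropattern.data_model_io import AnalysisConfig, genotype_means
from heteropattern.pattern_predictor import (build_virtual_profiles,
                                             compare_modes, fit_pls,
                                             permutation_test, pls_scan,
                                             plsda_q2, vip_matrix)


class TestVirtualProfiles:
    def test_formulas(self, two_parent_design):
        parent_means = pd.DataFrame({"A": [20.0], "B": [10.0]}, index=["f"])
        prof = build_virtual_profiles(parent_means, two_parent_design)
        got = {m: prof[m].loc["H_A_B", "f"] for m in prof}
        assert got == pytest.approx({"additive": 15.0, "PD_low": 13.0,
                                     "PD_high": 17.0, "dominant_female": 20.0,
                                     "dominant_male": 10.0})

    def test_equal_parents_degenerate(self, two_parent_design):
        parent_means = pd.DataFrame({"A": [7.0], "B": [7.0]}, index=["f"])
        prof = build_virtual_profiles(parent_means, two_parent_design)
        vals = {m: prof[m].loc["H_A_B", "f"] for m in prof}
        assert len(set(vals.values())) == 1

    def test_zero_noise_additive_world_matches_actual(self):
        """In a noise-free fully additive study the additive virtual matrix
        equals the measured hybrid matrix exactly (generator oracle)."""
        from heteropattern.synthetic_data import SimulationConfig, simulate_study
        cfg = SimulationConfig(n_parents=3, n_features=50, noise_cv=0.0,
                               pattern_mixture={"additive": 1.0}, seed=8)
        study = simulate_study(cfg)
        means = genotype_means(study.matrix, study.meta)
        parents = list(study.parent_true_means.columns)
        f1_meas = pd.DataFrame({
            p: means[study.design.members_of(p)].mean(axis=1)
            for p in study.design.pooled_ids})
        prof = build_virtual_profiles(means[parents], study.design,
                                      f1_means=f1_meas)
        np.testing.assert_allclose(prof["additive"].to_numpy(),
                                   prof["actual_F1"].to_numpy(), rtol=1e-10)


class TestPlsScan:
    def test_exact_linear_response_one_factor(self, rng):
        X = rng.normal(size=(30, 10))
        y = X @ rng.normal(size=10)  # exactly linear, no noise
        res = pls_scan(X, y)
        assert res.adj_r2_curve[0] >= 0.999 or res.best_adj_r2 >= 0.999

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            pls_scan(rng.normal(size=(10, 3)), np.ones(10))

    def test_factor_cap_respected(self, rng):
        cfg = AnalysisConfig(max_latent_regression=3)
        res = pls_scan(rng.normal(size=(20, 10)), rng.normal(size=20), cfg)
        assert len(res.adj_r2_curve) == 3

    def test_null_response_honesty(self, rng):
        """Independent response: the adjusted R^2 of the real labels stays
        within the spread of label-permuted fits (no systematic optimism)."""
        X = rng.normal(size=(40, 50))
        y = rng.normal(size=40)
        cfg = AnalysisConfig(max_latent_regression=5)
        observed = pls_scan(X, y, cfg).best_adj_r2
        permuted = [pls_scan(X, rng.permutation(y), cfg).best_adj_r2
                    for _ in range(20)]
        lo, hi = np.quantile(permuted, [0.0, 1.0])
        assert observed <= hi + 0.15


class TestPlsDA:
    def test_separated_classes_high_q2(self, rng):
        X = np.vstack([rng.normal(0, 1, (15, 8)), rng.normal(5, 1, (15, 8))])
        labels = ["a"] * 15 + ["b"] * 15
        res = plsda_q2(X, labels)
        assert res.q2 > 0.9
        assert res.q2 <= 1.0

    def test_duplicated_column_invariance(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 1)), rng.normal(4, 1, (10, 1))])
        labels = ["a"] * 10 + ["b"] * 10
        single = plsda_q2(X, labels, AnalysisConfig(seed=3)).q2
        doubled = plsda_q2(np.hstack([X, X]), labels, AnalysisConfig(seed=3)).q2
        assert doubled == pytest.approx(single, abs=0.05)

    def test_small_class_rejected(self, rng):
        with pytest.raises(ValueError, match="3 members"):
            plsda_q2(rng.normal(size=(5, 3)), ["a", "a", "a", "b", "b"])

    def test_permuted_labels_low_q2(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 5)), rng.normal(5, 1, (10, 5))])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        q2s = [plsda_q2(X, rng.permutation(labels), AnalysisConfig(seed=i)).q2
               for i in range(20)]
        assert np.mean(q2s) <= 0.1


class TestPermutationTest:
    def test_perfect_separation_minimum_p(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (6, 4)), rng.normal(10, 0.5, (6, 4))])
        labels = ["a"] * 6 + ["b"] * 6
        p = permutation_test(X, labels, AnalysisConfig(seed=0),
                             n_permutations=200)
        assert p == pytest.approx(1 / 201)

    def test_relabeling_symmetry(self, rng):
        X = rng.normal(size=(16, 5))
        labels = np.array(["a"] * 8 + ["b"] * 8)
        swapped = np.where(labels == "a", "b", "a")
        p1 = permutation_test(X, labels, AnalysisConfig(seed=4),
                              n_permutations=100)
        p2 = permutation_test(X, swapped, AnalysisConfig(seed=4),
                              n_permutations=100)
        assert p1 == p2

    def test_all_components_variant_runs(self, rng):
        X = np.vstack([rng.normal(0, 1, (8, 4)), rng.normal(3, 1, (8, 4))])
        labels = ["a"] * 8 + ["b"] * 8
        p = permutation_test(X, labels, AnalysisConfig(seed=1),
                             n_permutations=50, all_components=True)
        assert 0 < p <= 1


class TestVIPIdentity:
    @pytest.mark.parametrize("n,p,k", [(30, 12, 5), (25, 6, 2), (40, 3, 3)])
    def test_sum_of_squares_equals_feature_count(self, rng, n, p, k):
        """VIP normalization: per factor count, the squared VIPs sum to the
        number of predictors."""
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(n, 1))
        vips = vip_matrix(fit_pls(X, Y, k))
        np.testing.assert_allclose((vips ** 2).sum(axis=0), p, atol=1e-8)


class TestCompareModes:
    def test_identical_modes_identical_curves(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 6)),
                         index=[f"h{i}" for i in range(20)])
        y = pd.Series(rng.normal(size=20), index=X.index)
        table = compare_modes({"m1": X, "m2": X.copy()}, y)
        r2 = table.set_index("mode")["best_adj_r2"]
        assert r2["m1"] == pytest.approx(r2["m2"], rel=1e-9)

    def test_single_mode_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError, match="two modes"):
            compare_modes({"m1": X}, pd.Series(rng.normal(size=10)))
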