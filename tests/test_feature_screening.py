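import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heteropattern.data_model_io import (AnalysisConfig, OmicsMatrix,
                                         SampleMeta)
from heteropattern.feature_screening import (differential_features,
                                             exclude_specific,
                                             phenotype_correlation_screen,
                                             run_screen, two_way_anova_filter,
                                             vip_screen)
from heteropattern.synthetic_data import simulate_screen_study


def _matrix(arrays: dict, samples: list) -> OmicsMatrix:
    return OmicsMatrix(pd.DataFrame(arrays, index=samples).T)


class TestDifferential:
    def test_eightfold_feature_passes(self, rng):
        samples = [f"s{i}" for i in range(6)]
        base = rng.normal(100, 0.1, 3)
        mat = _matrix({"hit": np.concatenate([base * 8, base]),
                       "flat": rng.normal(100, 0.1, 6)}, samples)
        keep, table = differential_features(mat, samples[:3], samples[3:])
        assert keep == ["hit"]
        assert table.loc["hit", "log2fc"] == pytest.approx(3.0, abs=0.05)

    def test_identical_groups_empty(self):
        samples = [f"s{i}" for i in range(6)]
        mat = _matrix({"f": np.ones(6) * 5}, samples)
        keep, table = differential_features(mat, samples[:3], samples[3:])
        assert keep == []
        assert table.loc["f", "p"] == 1.0

    def test_null_features_controlled(self, rng):
        """Pure-noise features: the stringent differential thresholds admit
        essentially nothing."""
        samples = [f"s{i}" for i in range(6)]
        mat = _matrix({f"f{i}": rng.normal(100, 5, 6) for i in range(500)},
                      samples)
        keep, _ = differential_features(mat, samples[:3], samples[3:])
        assert len(keep) <= 5


class TestTwoWayAnova:
    @staticmethod
    def _design(n_geno=2, n_stage=2, n_rep=3):
        rows = []
        for g in range(n_geno):
            for s in range(n_stage):
                for r in range(n_rep):
                    rows.append({"sample_id": f"g{g}s{s}r{r}",
                                 "genotype_id": f"G{g}", "role": "parent",
                                 "stage": f"S{s}", "replicate": r + 1})
        return SampleMeta(pd.DataFrame(rows))

    def test_balanced_2x2_matches_closed_form(self, rng):
        """Type-I F statistics of a balanced 2x2 design equal the textbook
        sums-of-squares decomposition."""
        meta = self._design()
        y = rng.normal(size=12)
        mat = _matrix({"f": y}, list(meta.table["sample_id"]))
        _, table = two_way_anova_filter(mat, meta, AnalysisConfig())
        arr = y.reshape(2, 2, 3)  # genotype x stage x rep
        grand = arr.mean()
        ss_a = 6 * ((arr.mean(axis=(1, 2)) - grand) ** 2).sum()
        ss_b = 6 * ((arr.mean(axis=(0, 2)) - grand) ** 2).sum()
        cell = arr.mean(axis=2)
        ss_ab = 3 * ((cell - arr.mean(axis=(1, 2))[:, None]
                      - arr.mean(axis=(0, 2))[None, :] + grand) ** 2).sum()
        ss_e = ((arr - cell[:, :, None]) ** 2).sum()
        mse = ss_e / 8
        for name, ss, df in [("genotype", ss_a, 1), ("stage", ss_b, 1),
                             ("interaction", ss_ab, 1)]:
            f_stat = (ss / df) / mse
            p = stats.f.sf(f_stat, df, 8)
            assert table.loc["f", f"p_{name}"] == pytest.approx(p, rel=1e-9)

    def test_planted_effects_retained(self, rng):
        meta = self._design(n_geno=3, n_stage=2, n_rep=3)
        effects = {}
        for row in meta.table.itertuples():
            g = int(row.genotype_id[1]); s = int(row.stage[1])
            effects[row.sample_id] = 10 + 5 * g + 3 * s + 4 * g * s
        y = np.array([effects[s] for s in meta.table["sample_id"]])
        vals = {"hit": y + rng.normal(0, 0.3, len(y)),
                "null": rng.normal(10, 0.3, len(y))}
        mat = _matrix(vals, list(meta.table["sample_id"]))
        keep, _ = two_way_anova_filter(mat, meta, AnalysisConfig())
        assert keep == ["hit"]

    def test_needs_two_levels(self, rng):
        meta = self._design(n_geno=1)
        mat = _matrix({"f": rng.normal(size=6)}, list(meta.table["sample_id"]))
        with pytest.raises(ValueError, match="2 genotypes"):
            two_way_anova_filter(mat, meta)


class TestSpecificity:
    @staticmethod
    def _study(f1_level, pf_level=80.0, pm_level=10.0, recip_delta=0.0,
               noise=0.2, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for geno, role, fem, male in [("A", "parent", "", ""),
                                      ("B", "parent", "", ""),
                                      ("AxB", "F1", "A", "B"),
                                      ("BxA", "F1", "B", "A")]:
            for r in range(3):
                rows.append({"sample_id": f"{geno}_r{r}", "genotype_id": geno,
                             "role": role, "female_parent_id": fem,
                             "male_parent_id": male, "stage": "S1",
                             "replicate": r + 1})
        meta = SampleMeta(pd.DataFrame(rows))
        from heteropattern.data_model_io import CrossDesign
        design = CrossDesign(pd.DataFrame({
            "hybrid_id": ["AxB", "BxA"], "female_parent_id": ["A", "B"],
            "male_parent_id": ["B", "A"], "pooled_id": ["H", "H"]}))
        levels = {"A": pf_level, "B": pm_level, "AxB": f1_level,
                  "BxA": f1_level + recip_delta}
        vals = {}
        for s in meta.table["sample_id"]:
            geno = s.rsplit("_", 1)[0]
            vals[s] = levels[geno] + noise * rng.standard_normal()
        mat = OmicsMatrix(pd.DataFrame({"f": vals}).T[list(meta.table["sample_id"])])
        return mat, meta, design

    def test_parent_only_signal_excluded(self):
        """Parents differ sharply but the noisy hybrid is distinguishable
        from neither parent: the signal is parental-specific and the
        feature is dropped."""
        mat, meta, design = self._study(f1_level=45.0)
        # overwrite with a hand-built configuration: tight parents far
        # apart, hybrid replicates wildly spread around the middle
        values = {"A_r0": 100.0, "A_r1": 100.1, "A_r2": 99.9,
                  "B_r0": 0.0, "B_r1": 0.1, "B_r2": -0.1,
                  "AxB_r0": 50.0, "AxB_r1": 250.0, "AxB_r2": -150.0,
                  "BxA_r0": 150.0, "BxA_r1": -50.0, "BxA_r2": 50.0}
        mat = OmicsMatrix(pd.DataFrame({"f": values}).T[list(values)])
        keep, table = exclude_specific(["f"], mat, meta, design)
        assert keep == []
        assert table.loc["f", "parent_only"]

    def test_hybrid_signal_retained(self):
        mat, meta, design = self._study(f1_level=45.0)
        keep, table = exclude_specific(["f"], mat, meta, design)
        assert keep == ["f"]
        assert not table.loc["f", "reciprocal_divergent"]

    def test_reciprocal_divergence_flagged(self):
        mat, meta, design = self._study(f1_level=45.0, recip_delta=30.0)
        keep, table = exclude_specific(["f"], mat, meta, design)
        assert keep == []
        assert table.loc["f", "reciprocal_divergent"]


class TestPhenotypeCorrelation:
    def test_identical_and_orthogonal(self, toy_meta, rng):
        pheno = pd.Series({"A": 1.0, "B": 3.0, "C": 2.0, "D": 5.0})
        meta = SampleMeta(pd.DataFrame({
            "sample_id": list("abcd"), "genotype_id": list("ABCD"),
            "role": ["parent"] * 4, "stage": ["S1"] * 4, "replicate": [1] * 4}))
        mat = _matrix({"same": [1.0, 3.0, 2.0, 5.0],
                       "orth": [1.0, 1.0, 2.0, -1.3]}, list("abcd"))
        keep, table = phenotype_correlation_screen(["same", "orth"], mat,
                                                   meta, pheno, alpha=0.05)
        assert "same" in keep
        assert table.loc["same", "r"] == pytest.approx(1.0)
        assert "orth" not in keep


class TestVIP:
    def test_informative_feature_has_max_vip(self, rng):
        n = 40
        X = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"f{i}" for i in range(10)])
        y = 3 * X["f0"] + 0.1 * rng.normal(size=n)
        keep, table = vip_screen(list(X.columns), X, y)
        assert table["mean_vip"].idxmax() == "f0"
        assert "f0" in keep

    def test_single_feature_warns(self, rng):
        X = pd.DataFrame({"f0": rng.normal(size=20)})
        y = X["f0"] * 2 + 0.01 * rng.normal(size=20)
        with pytest.warns(UserWarning, match="single-feature"):
            vip_screen(["f0"], X, y)

    def test_permuted_response_scrambles_ranking(self, rng):
        """With the response permuted, VIP ranking is uninformative about
        the truly linked feature (mean rank correlation near 0)."""
        n = 30
        X = pd.DataFrame(rng.normal(size=(n, 8)),
                         columns=[f"f{i}" for i in range(8)])
        truth = np.zeros(8); truth[0] = 1
        corrs = []
        for _ in range(50):
            y = rng.permutation(3 * X["f0"].to_numpy() + 0.1 * rng.normal(size=n))
            _, table = vip_screen(list(X.columns), X, pd.Series(y))
            corrs.append(stats.spearmanr(truth, table["mean_vip"]).statistic)
        assert abs(np.mean(corrs)) < 0.2


class TestCascade:
    def test_nested_and_monotone(self):
        st_ = simulate_screen_study(n_features=100, seed=1)
        report = run_screen(st_["matrix"], st_["meta"], st_["design"],
                            st_["group_a_samples"], st_["group_b_samples"],
                            st_["trait_values"], st_["hybrid_response"])
        counts = list(report.stage_counts.values())
        assert counts == sorted(counts, reverse=True)
        flags = report.flags
        stages = list(flags.columns)
        for earlier, later in zip(stages, stages[1:]):
            assert (flags[later] <= flags[earlier]).all()  # nested sets
        assert set(report.final_features) <= set(flags.index[flags[stages[0]]])
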