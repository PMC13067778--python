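"""Multi-stage screen for heterosis-associated features (HAG/HAM analogue).

The cascade turns a raw omics matrix into a short list of features whose
levels track trait heterosis:

1. differential features between two sample groups at |log2FC| >= 2 and
   BH-adjusted p <= 1e-4 (per-feature Welch t-test on log2 values; the
   thresholds, not the test engine, define the stage);
2. two-way genotype x stage ANOVA (sequential type-I sums of squares,
   genotype entered first): keep features significant for genotype AND
   stage AND their interaction after BH-FDR per effect;
3. specificity exclusion: drop features whose only signal is a
   parent-vs-parent difference (no hybrid-vs-parent contrast) and
   features that differ between reciprocal F1 partners;
4. phenotype-correlation filter: Pearson correlation of genotype x stage
   mean profiles against the phenotype, keep two-tailed p < alpha;
5. VIP filter: keep features with mean PLS variable importance in
   projection >= 1.

Each stage's survivors are a subset of the previous stage's, so the
per-stage counts are monotonically non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .data_model_io import (AnalysisConfig, CrossDesign, OmicsMatrix,
                            SampleMeta, genotype_means)
from .pattern_predictor import fit_pls, mean_vip, pls_scan

STAGES = ["input", "differential", "two_way_anova", "specificity",
          "phenotype_correlation", "vip"]


@dataclass
class ScreenReport:
    """Stage-by-stage survivors of the screening cascade."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    flags: pd.DataFrame | None = None  # per-feature pass/fail per stage
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    final_features: list[str] = field(default_factory=list)

    def summary(self) -> pd.Series:
        return pd.Series(self.stage_counts)


# ---------------------------------------------------------------------------
# stage 1: differential features
# ---------------------------------------------------------------------------

def differential_features(matrix: OmicsMatrix, group_a: list[str],
                          group_b: list[str],
                          config: AnalysisConfig | None = None,
                          log_transform: bool = True,
                          pseudocount: float = 1.0,
                          ) -> tuple[list[str], pd.DataFrame]:
    """Per-feature Welch t-test on log2 levels with BH adjustment.

    Returns the surviving feature list and a table of log2FC (A minus B),
    raw and adjusted p, and direction. Features that are constant and
    equal in both groups get p = 1.
    """
    config = config or AnalysisConfig()
    if min(len(group_a), len(group_b)) < 2:
        raise ValueError("both groups need at least two replicates")
    A = matrix.values[list(group_a)].to_numpy(float)
    B = matrix.values[list(group_b)].to_numpy(float)
    if log_transform:
        A = np.log2(A + pseudocount)
        B = np.log2(B + pseudocount)
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    degenerate = np.isnan(p)
    p = np.where(degenerate & (np.abs(log2fc) < 1e-12), 1.0,
                 np.where(degenerate, 0.0, p))
    adj = multipletests(p, method=config.fdr_method)[1]
    table = pd.DataFrame({"log2fc": log2fc, "p": p, "adj_p": adj,
                          "direction": np.where(log2fc >= 0, "up", "down")},
                         index=matrix.feature_ids)
    keep = (np.abs(log2fc) >= config.de_log2fc) & (adj <= config.de_adj_p)
    return list(table.index[keep]), table


# ---------------------------------------------------------------------------
# stage 2: two-way ANOVA
# ---------------------------------------------------------------------------

def two_way_anova_filter(matrix: OmicsMatrix, meta: SampleMeta,
                         config: AnalysisConfig | None = None,
                         features: list[str] | None = None,
                         order: tuple[str, str] = ("genotype", "stage"),
                         ) -> tuple[list[str], pd.DataFrame]:
    """Per-feature genotype x stage fixed-effects ANOVA (type-I SS).

    Factors enter in ``order`` (genotype first by default); p-values per
    effect are BH-adjusted across features and a feature survives only
    when genotype, stage and their interaction are all significant at
    ``config.alpha``. Features with empty design cells are skipped.
    """
    config = config or AnalysisConfig()
    features = features if features is not None else matrix.feature_ids
    t = meta.table
    if t["genotype_id"].nunique() < 2 or t["stage"].nunique() < 2:
        raise ValueError("two-way ANOVA needs >=2 genotypes and >=2 stages")
    first, second = order
    colmap = {"genotype": "genotype_id", "stage": "stage"}
    base = pd.DataFrame({
        "genotype": t["genotype_id"].astype(str).to_numpy(),
        "stage": t["stage"].astype(str).to_numpy(),
    }, index=t["sample_id"])
    cells = base.groupby(["genotype", "stage"]).size()
    full_grid = t["genotype_id"].nunique() * t["stage"].nunique()
    if len(cells) < full_grid:
        raise ValueError("two-way ANOVA requires every genotype x stage cell")
    del colmap
    pvals = {}
    formula = f"value ~ C({first}) * C({second})"
    samples = list(base.index)
    for f in features:
        df = base.copy()
        df["value"] = matrix.values.loc[f, samples].to_numpy(float)
        if df["value"].std(ddof=0) == 0:
            pvals[f] = (1.0, 1.0, 1.0)
            continue
        table = anova_lm(ols(formula, data=df).fit(), typ=1)
        pvals[f] = tuple(table["PR(>F)"].iloc[:3])
    out = pd.DataFrame(pvals, index=[f"p_{first}", f"p_{second}", "p_interaction"]).T
    for col in out.columns:
        out[f"adj_{col[2:]}"] = multipletests(out[col], method=config.fdr_method)[1]
    adj_cols = [c for c in out.columns if c.startswith("adj_")]
    keep = (out[adj_cols] <= config.alpha).all(axis=1)
    return list(out.index[keep]), out


# ---------------------------------------------------------------------------
# stage 3: specificity exclusion
# ---------------------------------------------------------------------------

def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if min(a.size, b.size) < 2:
        return 1.0
    if a.std(ddof=0) == 0 and b.std(ddof=0) == 0:
        return 0.0 if a.mean() != b.mean() else 1.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def exclude_specific(features: list[str], matrix: OmicsMatrix,
                     meta: SampleMeta, design: CrossDesign,
                     config: AnalysisConfig | None = None,
                     ) -> tuple[list[str], pd.DataFrame]:
    """Drop features specific to parents or to one reciprocal partner.

    A feature is excluded when (a) no hybrid differs from its parents
    although some parent pair differs (the signal is parental only), or
    (b) any reciprocal F1 pair differs significantly between its two
    members (parent-of-origin artifact). Welch t-tests at ``config.alpha``.
    """
    config = config or AnalysisConfig()
    vals = matrix.values
    rows = []
    parent_sets = {}
    for pooled in design.pooled_ids:
        fem, male = design.parents_of(pooled)
        members = design.members_of(pooled)
        parent_sets[pooled] = (
            [s for m in members for s in meta.samples_of(m)],
            meta.samples_of(fem), meta.samples_of(male),
            [meta.samples_of(m) for m in members],
        )
    for f in features:
        row = vals.loc[f]
        hybrid_parent_signal = False
        parent_parent_signal = False
        reciprocal_divergent = False
        for f1_s, pf_s, pm_s, member_s in parent_sets.values():
            f1 = row[f1_s].to_numpy(float)
            pf = row[pf_s].to_numpy(float)
            pm = row[pm_s].to_numpy(float)
            if (_welch_p(f1, pf) < config.alpha
                    or _welch_p(f1, pm) < config.alpha):
                hybrid_parent_signal = True
            if _welch_p(pf, pm) < config.alpha:
                parent_parent_signal = True
            if len(member_s) == 2:
                a = row[member_s[0]].to_numpy(float)
                b = row[member_s[1]].to_numpy(float)
                if _welch_p(a, b) < config.alpha:
                    reciprocal_divergent = True
        parent_only = parent_parent_signal and not hybrid_parent_signal
        rows.append({"feature_id": f, "parent_only": parent_only,
                     "reciprocal_divergent": reciprocal_divergent,
                     "excluded": parent_only or reciprocal_divergent})
    table = pd.DataFrame(rows).set_index("feature_id")
    keep = [f for f in features if not table.loc[f, "excluded"]]
    return keep, table


# ---------------------------------------------------------------------------
# stage 4: phenotype correlation
# ---------------------------------------------------------------------------

def phenotype_correlation_screen(features: list[str], matrix: OmicsMatrix,
                                 meta: SampleMeta, trait_values: pd.Series,
                                 alpha: float = 0.05,
                                 ) -> tuple[list[str], pd.DataFrame]:
    """Pearson correlation of genotype x stage mean profiles vs a phenotype.

    ``trait_values`` is indexed by genotype id (stage-averaged profiles are
    used) or by ``(genotype, stage)`` tuples. Features with fewer than
    three matched points are skipped (dropped with NaN correlation).
    """
    by_stage = isinstance(trait_values.index[0], tuple)
    prof = genotype_means(matrix, meta, by_stage=by_stage)
    common = [c for c in prof.columns if c in set(trait_values.index)]
    if len(common) < 3:
        raise ValueError("fewer than 3 matched profile/phenotype points")
    y = trait_values.loc[common].to_numpy(float)
    rows = []
    for f in features:
        x = prof.loc[f, common].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            rows.append({"feature_id": f, "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append({"feature_id": f, "r": r, "p": p})
    table = pd.DataFrame(rows).set_index("feature_id")
    keep = list(table.index[(table["p"] < alpha).fillna(False)])
    return keep, table


# ---------------------------------------------------------------------------
# stage 5: VIP
# ---------------------------------------------------------------------------

def vip_screen(features: list[str], predictors: pd.DataFrame, response,
               config: AnalysisConfig | None = None,
               ) -> tuple[list[str], pd.DataFrame]:
    """Keep features whose mean VIP across latent factors >= the threshold.

    ``predictors`` is a samples x features matrix restricted to the
    candidate features; the latent-factor count is chosen by the adjusted
    R^2 scan. A single-feature model trivially has VIP = 1 (warned).
    """
    config = config or AnalysisConfig()
    X = predictors[features]
    if X.shape[1] == 1:
        import warnings
        warnings.warn("single-feature model: VIP is identically 1")
    scan = pls_scan(X, response, config)
    model = fit_pls(X.to_numpy(float),
                    np.asarray(response, float).reshape(-1, 1),
                    scan.best_n_factors)
    vips = mean_vip(model)
    table = pd.DataFrame({"mean_vip": vips}, index=features)
    keep = list(table.index[table["mean_vip"] >= config.vip_threshold])
    return keep, table


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def run_screen(matrix: OmicsMatrix, meta: SampleMeta, design: CrossDesign,
               group_a: list[str], group_b: list[str],
               trait_values: pd.Series, hybrid_response: pd.Series,
               hybrid_predictors_from: pd.DataFrame | None = None,
               config: AnalysisConfig | None = None) -> ScreenReport:
    """Run the full five-stage screening cascade.

    ``group_a``/``group_b`` are the sample groups of the differential
    stage; ``trait_values`` feeds the phenotype-correlation stage
    (indexed by genotype or (genotype, stage)); ``hybrid_response`` is the
    per-hybrid response of the VIP stage, predicted from measured hybrid
    mean profiles (or ``hybrid_predictors_from``, hybrids x all features,
    when given).
    """
    config = config or AnalysisConfig()
    report = ScreenReport()
    surviving = matrix.feature_ids
    report.stage_counts["input"] = len(surviving)
    flags = pd.DataFrame(index=matrix.feature_ids)

    surviving, de_table = differential_features(matrix, group_a, group_b, config)
    report.tables["differential"] = de_table
    report.stage_counts["differential"] = len(surviving)
    flags["differential"] = flags.index.isin(surviving)

    if surviving and meta.table["stage"].nunique() >= 2:
        surviving, aov = two_way_anova_filter(matrix, meta, config, surviving)
        report.tables["two_way_anova"] = aov
    report.stage_counts["two_way_anova"] = len(surviving)
    flags["two_way_anova"] = flags.index.isin(surviving)

    if surviving:
        surviving, spec = exclude_specific(surviving, matrix, meta, design, config)
        report.tables["specificity"] = spec
    report.stage_counts["specificity"] = len(surviving)
    flags["specificity"] = flags.index.isin(surviving)

    if surviving:
        surviving, corr = phenotype_correlation_screen(
            surviving, matrix, meta, trait_values, config.alpha)
        report.tables["phenotype_correlation"] = corr
    report.stage_counts["phenotype_correlation"] = len(surviving)
    flags["phenotype_correlation"] = flags.index.isin(surviving)

    if surviving:
        if hybrid_predictors_from is None:
            prof = genotype_means(matrix, meta)
            pooled_means = {}
            for pooled in design.pooled_ids:
                members = design.members_of(pooled)
                pooled_means[pooled] = prof[members].mean(axis=1)
            hybrid_predictors_from = pd.DataFrame(pooled_means).T
        pred = hybrid_predictors_from.loc[hybrid_response.index]
        surviving, vips = vip_screen(surviving, pred, hybrid_response, config)
        report.tables["vip"] = vips
    report.stage_counts["vip"] = len(surviving)
    flags["vip"] = flags.index.isin(surviving)

    report.flags = flags
    report.final_features = surviving
    return report
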