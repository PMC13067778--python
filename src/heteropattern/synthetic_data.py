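"""Synthetic diallel-cross studies with known inheritance structure.

The generator emulates the structure of a reciprocal diallel hybrid
study: a panel of inbred parents, reciprocal F1 hybrids for every
unordered parent pair, replicated omics profiles across stages,
replicated trait tables (including a stylized multiplicative yield
model), and paired per-accession variant sets. Every generated feature
carries a known inheritance pattern, so downstream classification,
screening and predictability claims can be tested against ground truth.

Per feature, parental true means are drawn around a lognormal base
level; the F1 true mean is set *exactly* by the feature's assigned
pattern (additive = mid-parent; PD_t = P_m + t(P_f - P_m); dominant =
the named parent; overdominant = beyond the nearer parent by a margin
proportional to the parental gap). Inheritance patterns are treated as
properties of the parent pair: both members of a reciprocal pair share
the same true mean (no parent-of-origin effects). Replicates multiply
the true mean by lognormal noise with a fixed coefficient of variation,
so ``noise_cv = 0`` is an exact, noise-free limit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model_io import (CrossDesign, OmicsMatrix, SampleMeta, TraitTable,
                            VariantSet, write_cross_design, write_interval_table,
                            write_omics_matrix, write_sample_meta,
                            write_trait_table, write_vcf)

#: generator pattern vocabulary -> classifier pattern vocabulary
TRUE_PATTERNS = {
    "additive": "additive",
    "PD_low": "partially_dominant",
    "PD_high": "partially_dominant",
    "dominant_female": "dominant",
    "dominant_male": "dominant",
    "overdominant": "overdominant",
    "NA_like": "NA",
}

#: default inheritance-pattern mixture: additive plus partially dominant
#: effects dominate (collectively 70%), as observed in rice hybrid omics
DEFAULT_MIXTURE = {
    "additive": 0.40,
    "PD_low": 0.15,
    "PD_high": 0.15,
    "dominant_female": 0.08,
    "dominant_male": 0.08,
    "overdominant": 0.06,
    "NA_like": 0.08,
}

DEFAULT_VARIANT_POOL = {
    "SNP": (200, 120),
    "InDel": (60, 40),
    "CNV": (20, 10),
    "SV": (15, 8),
}


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    ``pattern_mixture`` gives the probability of each generating pattern
    (must sum to 1); ``pd_low_t``/``pd_high_t`` are the partial-dominance
    degrees of the two PD subtypes. ``parent_effect_sd`` is the log-scale
    between-parent spread; alternatively ``parent_gap_frac`` fixes a
    deterministic relative gap between adjacent parent levels (useful for
    controlled power settings). ``noise_cv`` is the within-replicate
    coefficient of variation of the multiplicative lognormal noise.
    ``variant_pool`` maps each variant class to
    ``(n_common, n_unique_per_side)`` drawn for every accession pair.
    """

    n_parents: int = 6
    n_features: int = 1000
    pattern_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE))
    pd_low_t: float = 0.3
    pd_high_t: float = 0.7
    parent_effect_sd: float = 0.25
    parent_gap_frac: float | None = None
    overdominant_margin: float = 1.5
    noise_cv: float = 0.05
    n_replicates: int = 3
    stages: list[str] = field(default_factory=lambda: ["S1"])
    stage_effect_sd: float = 0.0
    interaction_sd: float = 0.0
    base_log_mean: float = np.log(1000.0)
    base_log_sd: float = 0.5
    trait_model: str = "linear"  # "linear" | "multiplicative"
    n_traits: int = 2
    n_informative: int = 20
    trait_noise_frac: float = 0.05
    variant_pool: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_VARIANT_POOL))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parents < 2:
            raise ValueError("n_parents must be >= 2")
        total = sum(self.pattern_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern_mixture must sum to 1; sums to {total}")
        unknown = set(self.pattern_mixture) - set(TRUE_PATTERNS)
        if unknown:
            raise ValueError(f"unknown patterns in mixture: {sorted(unknown)}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.overdominant_margin <= 0:
            raise ValueError("overdominant_margin must be > 0")
        for cls, (nc, nu) in self.variant_pool.items():
            if nc < 0 or nu < 0:
                raise ValueError(f"variant pool sizes must be >= 0 ({cls})")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimulatedStudy:
    """A complete synthetic study plus its ground truth."""

    config: SimulationConfig
    matrix: OmicsMatrix
    meta: SampleMeta
    design: CrossDesign
    traits: TraitTable | None
    variant_sets: dict[str, VariantSet]
    truth: pd.DataFrame  # per feature: generating pattern, true t, direction
    parent_true_means: pd.DataFrame  # features x parents
    f1_true_means: pd.DataFrame  # features x pooled hybrids
    trait_truth: dict = field(default_factory=dict)
    variant_truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cross design
# ---------------------------------------------------------------------------

def simulate_cross(config: SimulationConfig) -> tuple[CrossDesign, SampleMeta]:
    """Full reciprocal diallel among ``n_parents`` inbred lines.

    Every unordered parent pair yields two reciprocal hybrids sharing a
    pooled genotype id; n parents give n(n-1)/2 pooled pairs and n(n-1)
    hybrid ids. Sample metadata covers every genotype x stage x replicate.
    """
    parents = [f"P{i + 1:02d}" for i in range(config.n_parents)]
    rows = []
    for a, b in itertools.combinations(parents, 2):
        pooled = f"H_{a}_{b}"
        rows.append({"hybrid_id": f"{a}x{b}", "female_parent_id": a,
                     "male_parent_id": b, "pooled_id": pooled})
        rows.append({"hybrid_id": f"{b}x{a}", "female_parent_id": b,
                     "male_parent_id": a, "pooled_id": pooled})
    design = CrossDesign(pd.DataFrame(rows))

    meta_rows = []
    for geno in parents:
        for stage in config.stages:
            for rep in range(1, config.n_replicates + 1):
                meta_rows.append({
                    "sample_id": f"{geno}_{stage}_r{rep}", "genotype_id": geno,
                    "role": "parent", "female_parent_id": "",
                    "male_parent_id": "", "stage": stage, "replicate": rep})
    for row in rows:
        for stage in config.stages:
            for rep in range(1, config.n_replicates + 1):
                meta_rows.append({
                    "sample_id": f"{row['hybrid_id']}_{stage}_r{rep}",
                    "genotype_id": row["hybrid_id"], "role": "F1",
                    "female_parent_id": row["female_parent_id"],
                    "male_parent_id": row["male_parent_id"],
                    "stage": stage, "replicate": rep})
    return design, SampleMeta(pd.DataFrame(meta_rows))


# ---------------------------------------------------------------------------
# omics profiles
# ---------------------------------------------------------------------------

def _parent_levels(config: SimulationConfig, rng: np.random.Generator,
                   base: np.ndarray) -> np.ndarray:
    """Per-feature true parental means (n_features x n_parents)."""
    n, p = config.n_features, config.n_parents
    if config.parent_gap_frac is not None:
        # deterministic relative gap: parent levels equally spaced around the
        # base, adjacent separation = parent_gap_frac * base level
        offsets = np.arange(p) - (p - 1) / 2.0
        ranks = np.array([rng.permutation(p) for _ in range(n)])
        levels = base[:, None] * (1.0 + config.parent_gap_frac * offsets[ranks])
    else:
        z = rng.standard_normal((n, p))
        levels = base[:, None] * np.exp(config.parent_effect_sd * z)
    return levels


def true_f1_mean(pattern: str, p_female: float, p_male: float,
                 config: SimulationConfig, direction_up: bool = True) -> float:
    """True F1 mean under a generating pattern (exact formulas)."""
    if pattern == "additive":
        return (p_female + p_male) / 2.0
    if pattern == "PD_low":
        return p_male + config.pd_low_t * (p_female - p_male)
    if pattern == "PD_high":
        return p_male + config.pd_high_t * (p_female - p_male)
    if pattern == "dominant_female":
        return p_female
    if pattern == "dominant_male":
        return p_male
    if pattern == "overdominant":
        gap = abs(p_female - p_male)
        margin = config.overdominant_margin * gap
        return (max(p_female, p_male) + margin if direction_up
                else min(p_female, p_male) - margin)
    if pattern == "NA_like":
        return (p_female + p_male) / 2.0
    raise ValueError(f"unknown pattern {pattern!r}")


def _noisy(mean: np.ndarray, cv: float, rng: np.random.Generator,
           size: tuple) -> np.ndarray:
    """Lognormal multiplicative noise with the requested CV and unit mean."""
    if cv == 0:
        return np.broadcast_to(mean, size).copy()
    sigma2 = np.log1p(cv ** 2)
    z = rng.standard_normal(size)
    return mean * np.exp(np.sqrt(sigma2) * z - sigma2 / 2.0)


def simulate_profiles(design: CrossDesign, meta: SampleMeta,
                      config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[OmicsMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pattern-labelled omics profiles for a simulated cross.

    Returns ``(matrix, truth, parent_true_means, f1_true_means)``; the truth
    table records each feature's generating pattern (generator and
    classifier vocabulary), its true partial-dominance degree, and the
    overdominance direction.
    """
    rng = rng or config.rng()
    n = config.n_features
    feature_ids = [f"feat{i + 1:05d}" for i in range(n)]
    parents = sorted(set(design.hybrids["female_parent_id"])
                     | set(design.hybrids["male_parent_id"]))

    names = list(config.pattern_mixture)
    probs = np.array([config.pattern_mixture[k] for k in names])
    assigned = rng.choice(names, size=n, p=probs)
    up = rng.random(n) < 0.5

    base = np.exp(config.base_log_mean + config.base_log_sd * rng.standard_normal(n))
    levels = _parent_levels(config, rng, base)
    na_mask = assigned == "NA_like"
    levels[na_mask] = base[na_mask, None]  # indistinguishable parents
    parent_means = pd.DataFrame(levels, index=feature_ids, columns=parents)

    pooled_ids = design.pooled_ids
    f1 = np.empty((n, len(pooled_ids)))
    for j, pooled in enumerate(pooled_ids):
        fem, male = design.parents_of(pooled)
        pf = parent_means[fem].to_numpy()
        pm = parent_means[male].to_numpy()
        for i in range(n):
            f1[i, j] = true_f1_mean(assigned[i], pf[i], pm[i], config, up[i])
    f1_means = pd.DataFrame(f1, index=feature_ids, columns=pooled_ids)

    true_t = np.where(assigned == "PD_low", config.pd_low_t,
                      np.where(assigned == "PD_high", config.pd_high_t, np.nan))
    truth = pd.DataFrame({
        "feature_id": feature_ids,
        "true_pattern": assigned,
        "expected_call": [TRUE_PATTERNS[a] for a in assigned],
        "true_t": true_t,
        "direction_up": up,
    }).set_index("feature_id")

    # stage and genotype-x-stage multipliers (log-scale, shared by replicates)
    stages = config.stages
    genotypes = list(meta.table["genotype_id"].unique())
    stage_mult = {s: np.exp(config.stage_effect_sd * rng.standard_normal(n))
                  for s in stages}
    inter_mult = {}
    if config.interaction_sd > 0:
        for g in genotypes:
            for s in stages:
                inter_mult[(g, s)] = np.exp(
                    config.interaction_sd * rng.standard_normal(n))

    hybrid_pooled = dict(zip(design.hybrids["hybrid_id"], design.hybrids["pooled_id"]))
    cols = {}
    for row in meta.table.itertuples():
        g = row.genotype_id
        if g in hybrid_pooled:
            mean = f1_means[hybrid_pooled[g]].to_numpy()
        else:
            mean = parent_means[g].to_numpy()
        mean = mean * stage_mult[row.stage]
        if (g, row.stage) in inter_mult:
            mean = mean * inter_mult[(g, row.stage)]
        cols[row.sample_id] = _noisy(mean, config.noise_cv, rng, (n,))
    matrix = OmicsMatrix(pd.DataFrame(cols, index=feature_ids), "transcript")
    return matrix, truth, parent_means, f1_means


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def multiplicative_cross(p1_components: tuple[float, float],
                         p2_components: tuple[float, float]) -> dict:
    """Two-component multiplicative yield model for a single cross.

    Yield is the product of two component traits (e.g. grain number x
    grain weight). Both components are additive in the F1 (component =
    mid-parent value); yield heterosis then emerges from the product. When
    the parents' yields are equal, BPH of yield is non-negative by the
    AM-GM inequality, with equality iff the parents' components coincide.
    """
    a1, b1 = map(float, p1_components)
    a2, b2 = map(float, p2_components)
    f1_a, f1_b = (a1 + a2) / 2.0, (b1 + b2) / 2.0
    y1, y2 = a1 * b1, a2 * b2
    f1_yield = f1_a * f1_b
    p_high = max(y1, y2)
    return {"parent_yields": (y1, y2), "f1_components": (f1_a, f1_b),
            "f1_yield": f1_yield,
            "bph_yield": (f1_yield - p_high) / p_high if p_high else float("nan")}


def simulate_traits(design: CrossDesign, config: SimulationConfig,
                    parent_true_means: pd.DataFrame,
                    f1_true_means: pd.DataFrame,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[TraitTable, dict]:
    """Replicated trait tables from true molecular levels.

    ``linear`` model: each trait is a sparse weighted sum of true feature
    levels plus Gaussian replicate noise (sd = ``trait_noise_frac`` x the
    between-genotype sd of the true trait).

    ``multiplicative`` model: two component traits, additive in the F1,
    whose product is the yield trait; parental component values are drawn
    reciprocally so every parent has the same true yield, the regime in
    which component additivity alone generates non-negative yield
    heterosis (AM-GM).
    """
    rng = rng or config.rng()
    parents = list(parent_true_means.columns)
    pooled = list(f1_true_means.columns)
    genotypes = parents + pooled
    truth: dict = {"model": config.trait_model}
    rows = []

    if config.trait_model == "linear":
        n = len(parent_true_means)
        weights = pd.DataFrame(0.0, index=parent_true_means.index,
                               columns=[f"trait{t + 1}" for t in range(config.n_traits)])
        for t in range(config.n_traits):
            idx = rng.choice(n, size=min(config.n_informative, n), replace=False)
            weights.iloc[idx, t] = rng.standard_normal(len(idx))
        truth["weights"] = weights
        levels = pd.concat([parent_true_means, f1_true_means], axis=1)
        for trait in weights.columns:
            true_vals = levels.T @ weights[trait]
            sd = float(true_vals.std()) * config.trait_noise_frac
            for g in genotypes:
                for rep in range(1, config.n_replicates + 1):
                    rows.append({"genotype_id": g, "trait": trait,
                                 "replicate": rep,
                                 "value": true_vals[g] + sd * rng.standard_normal()})
        polarity = {t: "higher_better" for t in weights.columns}

    elif config.trait_model == "multiplicative":
        # reciprocal component draws: component_a varies, component_b set so
        # that every parent's true yield equals a common value
        common_yield = 4000.0
        comp_a = {p: float(rng.uniform(80, 240)) for p in parents}
        comp_b = {p: common_yield / comp_a[p] for p in parents}
        truth["components"] = {"a": comp_a, "b": comp_b, "yield": common_yield}
        vals = {}
        for g in parents:
            vals[g] = (comp_a[g], comp_b[g])
        for h in pooled:
            fem, male = design.parents_of(h)
            vals[h] = ((comp_a[fem] + comp_a[male]) / 2.0,
                       (comp_b[fem] + comp_b[male]) / 2.0)
        for g, (a, b) in vals.items():
            for rep in range(1, config.n_replicates + 1):
                na = a * (1 + config.trait_noise_frac * rng.standard_normal())
                nb = b * (1 + config.trait_noise_frac * rng.standard_normal())
                rows.append({"genotype_id": g, "trait": "component_a",
                             "replicate": rep, "value": na})
                rows.append({"genotype_id": g, "trait": "component_b",
                             "replicate": rep, "value": nb})
                rows.append({"genotype_id": g, "trait": "yield",
                             "replicate": rep, "value": na * nb})
        polarity = {"component_a": "higher_better", "component_b": "higher_better",
                    "yield": "higher_better"}
    else:
        raise ValueError(f"unknown trait model {config.trait_model!r}")

    # hybrids appear under pooled ids; map both reciprocal members to them
    return TraitTable(pd.DataFrame(rows), polarity), truth


# ---------------------------------------------------------------------------
# planted screening study
# ---------------------------------------------------------------------------

def simulate_screen_study(n_parents: int = 6, n_features: int = 200,
                          planted_frac: float = 0.05,
                          decoy_frac: float = 0.05,
                          fold: float = 8.0, noise_cv: float = 0.05,
                          n_replicates: int = 3, seed: int = 0) -> dict:
    """Synthetic study with planted phenotype-linked features for the screen.

    The parent panel splits into two halves (think *indica*-like vs
    *japonica*-like). Three feature classes are planted:

    * ``planted`` (default 5%): strongly differential between the parent
      groups, stage- and interaction-responsive, additive in hybrids, and
      the sole drivers of the phenotype;
    * ``decoy``: same group/stage structure but diluted by strong
      independent per-genotype variation, so they correlate with the
      phenotype only through the shared group contrast — they survive the
      univariate stages but carry low multivariate (VIP) importance;
    * ``null`` (the rest): pure noise around a constant level.

    Returns a dict with the matrix, metadata, design, the phenotype per
    (genotype, stage), the per-hybrid response, and the truth lists.
    """
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(n_parents=n_parents, n_features=n_features,
                           noise_cv=noise_cv, n_replicates=n_replicates,
                           stages=["S1", "S2"], seed=seed)
    design, meta = simulate_cross(cfg)
    parents = sorted(set(design.hybrids["female_parent_id"]))
    group_a = parents[: n_parents // 2]
    group_b = parents[n_parents // 2:]

    n_planted = max(1, int(round(planted_frac * n_features)))
    n_decoy = max(1, int(round(decoy_frac * n_features)))
    feature_ids = [f"feat{i + 1:05d}" for i in range(n_features)]
    planted = feature_ids[:n_planted]
    decoys = feature_ids[n_planted:n_planted + n_decoy]

    genotypes = list(meta.table["genotype_id"].unique())
    hybrid_parents = dict(zip(design.hybrids["hybrid_id"],
                              zip(design.hybrids["female_parent_id"],
                                  design.hybrids["male_parent_id"])))

    base = 1000.0
    # per-genotype baseline for planted/decoy features: group contrast,
    # additive in hybrids; decoys add independent per-genotype wobble
    def genotype_level(f_idx: int, geno: str, kind: str) -> float:
        def parent_level(p: str) -> float:
            lvl = base * (fold if p in group_a else 1.0)
            if kind == "decoy":
                lvl *= float(decoy_wobble[f_idx][p])
            return lvl
        if geno in hybrid_parents:
            fem, male = hybrid_parents[geno]
            return (parent_level(fem) + parent_level(male)) / 2.0
        return parent_level(geno)

    decoy_wobble = {i: {p: np.exp(0.6 * rng.standard_normal())
                        for p in parents}
                    for i in range(n_planted, n_planted + n_decoy)}
    # stage response: common S2 boost plus genotype-specific modulation
    stage_mult = {i: {(g, "S1"): 1.0 for g in genotypes} for i in range(n_features)}
    for i in list(range(n_planted + n_decoy)):
        for g in genotypes:
            stage_mult[i][(g, "S2")] = float(rng.uniform(1.3, 2.2))
    for i in range(n_planted + n_decoy, n_features):
        for g in genotypes:
            stage_mult[i][(g, "S2")] = 1.0

    means = np.full((n_features, 0), np.nan)
    cols = {}
    true_mean = {}
    for row in meta.table.itertuples():
        g, s = row.genotype_id, row.stage
        mean = np.empty(n_features)
        for i in range(n_features):
            if i < n_planted:
                mean[i] = genotype_level(i, g, "planted") * stage_mult[i][(g, s)]
            elif i < n_planted + n_decoy:
                mean[i] = genotype_level(i, g, "decoy") * stage_mult[i][(g, s)]
            else:
                mean[i] = base
        true_mean[(g, s)] = mean
        cols[row.sample_id] = _noisy(mean, noise_cv, rng, (n_features,))
    matrix = OmicsMatrix(pd.DataFrame(cols, index=feature_ids), "transcript")

    # phenotype: weighted sum of planted true levels per (genotype, stage)
    weights = rng.uniform(0.5, 1.5, size=n_planted)
    trait_values = pd.Series({
        (g, s): float(weights @ m[:n_planted])
        for (g, s), m in true_mean.items()})
    hybrid_response = pd.Series({
        pooled: float(np.mean([trait_values[(m, s)]
                               for m in design.members_of(pooled)
                               for s in cfg.stages]))
        for pooled in design.pooled_ids})

    group_a_samples = [s for p in group_a for s in meta.samples_of(p)]
    group_b_samples = [s for p in group_b for s in meta.samples_of(p)]
    return {"matrix": matrix, "meta": meta, "design": design,
            "trait_values": trait_values, "hybrid_response": hybrid_response,
            "group_a_samples": group_a_samples,
            "group_b_samples": group_b_samples,
            "planted": planted, "decoys": decoys,
            "nulls": feature_ids[n_planted + n_decoy:]}


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _random_small_key(chrom: str, pos: int, indel: bool,
                      rng: np.random.Generator) -> tuple:
    ref = _BASES[rng.integers(4)]
    if indel:
        ins = "".join(_BASES[rng.integers(4)] for _ in range(int(rng.integers(1, 6))))
        alt = ref + ins
    else:
        alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
    return (chrom, pos, ref, alt, "1/1")


def simulate_variants(design: CrossDesign, config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[dict[str, VariantSet], dict]:
    """Paired variant sets for every parental accession.

    For each unordered accession pair and each variant class, exactly
    ``n_common`` pair-specific shared keys and ``n_unique`` private keys
    per side are drawn at globally unique positions, so the pairwise
    common count is known by construction (private keys from other pairs
    accumulate into an accession's total unique count in panels with more
    than two accessions).
    """
    rng = rng or config.rng()
    parents = sorted(set(design.hybrids["female_parent_id"])
                     | set(design.hybrids["male_parent_id"]))
    sets = {p: VariantSet(p) for p in parents}
    truth: dict = {}
    pos_counter = itertools.count(1000)
    for a, b in itertools.combinations(parents, 2):
        pair_truth = {}
        for cls, (n_common, n_unique) in config.variant_pool.items():
            for target in ("both", "a", "b"):
                count = n_common if target == "both" else n_unique
                for _ in range(count):
                    pos = next(pos_counter) * 10  # unique, spaced positions
                    chrom = f"chr{1 + pos % 12}"
                    if cls in ("SNP", "InDel"):
                        key = _random_small_key(chrom, pos, cls == "InDel", rng)
                    else:
                        length = int(rng.integers(200, 5000))
                        vtype = ("DUP" if cls == "CNV" else "DEL")
                        key = (chrom, pos, pos + length - 1, vtype, length)
                    if target in ("both", "a"):
                        sets[a].add(cls, key)
                    if target in ("both", "b"):
                        sets[b].add(cls, key)
            pair_truth[cls] = {"n_common": n_common, "n_unique_per_side": n_unique}
        truth[(a, b)] = pair_truth
    return sets, truth


# ---------------------------------------------------------------------------
# orchestration and export
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a complete synthetic study from one root seed."""
    rng = config.rng()
    design, meta = simulate_cross(config)
    matrix, truth, parent_means, f1_means = simulate_profiles(
        design, meta, config, rng)
    traits, trait_truth = simulate_traits(design, config, parent_means,
                                          f1_means, rng)
    variant_sets, variant_truth = simulate_variants(design, config, rng)
    return SimulatedStudy(config=config, matrix=matrix, meta=meta,
                          design=design, traits=traits,
                          variant_sets=variant_sets, truth=truth,
                          parent_true_means=parent_means,
                          f1_true_means=f1_means, trait_truth=trait_truth,
                          variant_truth=variant_truth)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write a simulated study as standard-format text files plus truth tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_omics_matrix(study.matrix, out / "omics.tsv")
    write_sample_meta(study.meta, out / "meta.tsv")
    write_cross_design(study.design, out / "design.tsv")
    if study.traits is not None:
        write_trait_table(study.traits, out / "traits.tsv")
    study.truth.to_csv(out / "truth_patterns.tsv", sep="\t")
    study.parent_true_means.to_csv(out / "truth_parent_means.tsv", sep="\t")
    study.f1_true_means.to_csv(out / "truth_f1_means.tsv", sep="\t")
    vdir = out / "variants"
    vdir.mkdir(exist_ok=True)
    for acc, vs in study.variant_sets.items():
        small = sorted(vs.keys["SNP"] | vs.keys["InDel"])
        write_vcf(small, vdir / f"{acc}.vcf", sample=acc)
        write_interval_table(sorted(vs.keys["CNV"]), vdir / f"{acc}.cnv.tsv")
        write_interval_table(sorted(vs.keys["SV"]), vdir / f"{acc}.sv.tsv")
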