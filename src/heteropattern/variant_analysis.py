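"""Pairwise variant sharing, genetic distance and heterosis association.

Two accessions' variants are *common* when their comparison keys match
exactly — (CHROM, POS, REF, ALT, GT) for SNPs/InDels, (CHROM, POS1,
POS2, TYPE, SIZE) for CNVs/SVs — and *unique* otherwise; the sum of
unique variants over the classes in scope is the pair's genetic
distance. Unique/common counts are related to trait heterosis by
Spearman correlation, yield heterosis by quadratic regression (the
grain-number / seed-setting trade-off makes it non-monotone), and
haplotype groups of gene-level variant profiles by a Welch t-test of
heterozygous- versus homozygous-haplotype hybrids.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import CrossDesign, VariantSet, VARIANT_CLASSES

logger = logging.getLogger("heteropattern")


@dataclass
class PairwiseVariantStats:
    """Common/unique key counts for one unordered accession pair.

    Satisfies, per class: common + unique_a + unique_b = |union of keys|,
    and symmetry under swapping the accessions.
    """

    accession_a: str
    accession_b: str
    common: dict[str, int] = field(default_factory=dict)
    unique_a: dict[str, int] = field(default_factory=dict)
    unique_b: dict[str, int] = field(default_factory=dict)

    def genetic_distance(self, classes=None) -> int:
        classes = classes or list(self.common)
        return sum(self.unique_a[c] + self.unique_b[c] for c in classes)

    def unique_total(self, cls: str) -> int:
        return self.unique_a[cls] + self.unique_b[cls]


def pairwise_variant_stats(sets: dict[str, VariantSet],
                           classes=VARIANT_CLASSES,
                           accessions: list[str] | None = None,
                           ) -> dict[frozenset, PairwiseVariantStats]:
    """Exact set intersection/difference counts for all unordered pairs.

    Accessions named in ``accessions`` but absent from ``sets`` cause
    their pairs to be skipped with a warning.
    """
    accs = accessions or sorted(sets)
    out = {}
    for a, b in itertools.combinations(accs, 2):
        if a not in sets or b not in sets:
            logger.warning("skipping pair (%s, %s): accession missing", a, b)
            continue
        st = PairwiseVariantStats(a, b)
        for cls in classes:
            ka, kb = sets[a].keys[cls], sets[b].keys[cls]
            st.common[cls] = len(ka & kb)
            st.unique_a[cls] = len(ka - kb)
            st.unique_b[cls] = len(kb - ka)
        out[frozenset((a, b))] = st
    return out


def variant_stats_table(stats_map: dict[frozenset, PairwiseVariantStats],
                        classes=VARIANT_CLASSES) -> pd.DataFrame:
    """Flatten pairwise stats into a tidy per-pair table."""
    rows = []
    for st in stats_map.values():
        row = {"accession_a": st.accession_a, "accession_b": st.accession_b}
        for cls in classes:
            row[f"common_{cls}"] = st.common[cls]
            row[f"unique_{cls}"] = st.unique_total(cls)
        row["genetic_distance"] = st.genetic_distance(list(classes))
        rows.append(row)
    return pd.DataFrame(rows)


def variant_heterosis_correlation(stats_map: dict[frozenset, PairwiseVariantStats],
                                  heterosis: pd.DataFrame,
                                  classes=VARIANT_CLASSES,
                                  count_kind: str = "unique",
                                  method: str = "spearman",
                                  ) -> pd.DataFrame:
    """Correlate per-pair variant counts with per-hybrid trait BPH.

    ``heterosis`` is the tidy BPH table (hybrid_id, trait, BPH,
    female_parent_id, male_parent_id); reciprocal hybrids are pooled, so
    each parent pair contributes one BPH per trait. Returns per
    (class, trait) rho and two-tailed p; combinations with fewer than 4
    mapped hybrids are skipped.
    """
    if count_kind not in ("unique", "common"):
        raise ValueError("count_kind must be 'unique' or 'common'")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for trait, grp in heterosis.groupby("trait"):
        for cls in classes:
            xs, ys = [], []
            for rec in grp.itertuples():
                pair = frozenset((rec.female_parent_id, rec.male_parent_id))
                if pair not in stats_map:
                    continue
                st = stats_map[pair]
                count = (st.unique_total(cls) if count_kind == "unique"
                         else st.common[cls])
                xs.append(count)
                ys.append(rec.BPH)
            if len(xs) < 4:
                continue
            xs, ys = np.asarray(xs, float), np.asarray(ys, float)
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = corr(xs, ys)
            rows.append({"trait": trait, "variant_class": cls,
                         "count_kind": count_kind, "rho": float(rho),
                         "p": float(p), "n": len(xs)})
    return pd.DataFrame(rows)


def quadratic_fit(x, y) -> dict:
    """Least-squares quadratic y = a x^2 + b x + c with vertex and R^2.

    Requires >= 4 points and >= 3 distinct x values (otherwise the design
    is collinear and the parabola is unidentifiable).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise ValueError("quadratic fit needs at least 4 points")
    if np.unique(x).size <= 2:
        raise ValueError("quadratic fit needs at least 3 distinct x values")
    coef = np.polynomial.polynomial.polyfit(x, y, 2)  # c, b, a
    c, b, a = (float(v) for v in coef)
    pred = np.polynomial.polynomial.polyval(x, coef)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    vertex = -b / (2 * a) if a != 0 else float("nan")
    return {"a": a, "b": b, "c": c, "vertex": vertex, "r2": r2}


def haplotype_groups(variant_profiles: pd.DataFrame) -> pd.Series:
    """Group accessions by exact identity of presence/absence profiles.

    ``variant_profiles`` is accessions x variants (0/1). Returns a Series
    mapping accession -> haplotype label ("hap1", "hap2", ... by group
    size then first occurrence).
    """
    keys = variant_profiles.apply(lambda row: tuple(row), axis=1)
    order = []
    for k in keys:
        if k not in order:
            order.append(k)
    sizes = keys.value_counts()
    ranked = sorted(order, key=lambda k: (-sizes[k], order.index(k)))
    label = {k: f"hap{i + 1}" for i, k in enumerate(ranked)}
    return keys.map(label)


def haplotype_contrast(variant_profiles: pd.DataFrame, design: CrossDesign,
                       heterosis: pd.DataFrame) -> pd.DataFrame:
    """Heterozygous- vs homozygous-haplotype BPH contrast per trait.

    Accessions are grouped by exact variant-profile identity; each pooled
    hybrid is labelled heterozygous when its parents carry different
    haplotypes. Welch t-test of BPH between heterozygous and pooled
    homozygous hybrids; traits with fewer than 2 hybrids on a side are
    skipped.
    """
    haps = haplotype_groups(variant_profiles)
    if haps.nunique() < 2:
        return pd.DataFrame(columns=["trait", "n_het", "n_hom", "mean_het",
                                     "mean_hom", "t", "p"])
    het = {}
    for pooled in design.pooled_ids:
        fem, male = design.parents_of(pooled)
        if fem in haps.index and male in haps.index:
            het[pooled] = haps[fem] != haps[male]
    rows = []
    for trait, grp in heterosis.groupby("trait"):
        grp = grp[grp["hybrid_id"].isin(het)]
        is_het = grp["hybrid_id"].map(het)
        a = grp.loc[is_het, "BPH"].to_numpy(float)
        b = grp.loc[~is_het, "BPH"].to_numpy(float)
        if a.size < 2 or b.size < 2:
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"trait": trait, "n_het": int(a.size), "n_hom": int(b.size),
                     "mean_het": float(a.mean()), "mean_hom": float(b.mean()),
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)
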