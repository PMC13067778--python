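"""Mid-parent values, better-parent heterosis and heterosis correlations.

Better-parent heterosis (BPH) for a trait is

    BPH = (F1 - P_high) / P_high

with ``P_high`` the better parent's mean. For higher-is-better traits the
better parent is the one with the larger mean; for earlier-is-better
traits (heading date) the earlier parent is the better one, and the ratio
is multiplied by -1 so that a positive BPH again means the hybrid
outperforms both parents. BPH is dimensionless and invariant to a change
of trait units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import CrossDesign, TraitTable


def mid_parent_value(p_female: float, p_male: float) -> float:
    """Arithmetic mean of the two parental values — the additive expectation."""
    return (float(p_female) + float(p_male)) / 2.0


@dataclass
class BPHResult:
    bph: float
    mpv: float
    better_parent: str  # "female" | "male" | (tie ->) "female"
    mph: float  # mid-parent heterosis, (F1 - MPV)/MPV, for convenience


def compute_bph(f1, p_female, p_male, polarity: str = "higher_better") -> BPHResult:
    """Better-parent heterosis from replicate values (means are used).

    Ties in the parental means are broken toward the female parent; a zero
    better-parent mean leaves BPH undefined (NaN).
    """
    f1_m = float(np.mean(f1))
    pf_m = float(np.mean(p_female))
    pm_m = float(np.mean(p_male))
    mpv = mid_parent_value(pf_m, pm_m)
    if polarity == "higher_better":
        better = "female" if pf_m >= pm_m else "male"
        sign = 1.0
    elif polarity == "earlier_better":
        better = "female" if pf_m <= pm_m else "male"
        sign = -1.0
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    p_high = pf_m if better == "female" else pm_m
    bph = sign * (f1_m - p_high) / p_high if p_high != 0 else float("nan")
    mph = (f1_m - mpv) / mpv if mpv != 0 else float("nan")
    return BPHResult(bph=bph, mpv=mpv, better_parent=better, mph=mph)


def heterosis_table(traits: TraitTable, design: CrossDesign,
                    pool_reciprocals: bool = True) -> pd.DataFrame:
    """Per (hybrid, trait) BPH/MPV table.

    With ``pool_reciprocals`` (the default) the replicate values of both
    members of a reciprocal pair are combined under the pooled hybrid id.
    Rows where a trait is unmeasured for the hybrid or a parent are skipped.
    """
    rows = []
    groups = (design.pooled_ids if pool_reciprocals
              else list(design.hybrids["hybrid_id"]))
    for gid in groups:
        if pool_reciprocals:
            members = design.members_of(gid)
            fem, male = design.parents_of(gid)
        else:
            row = design.hybrids.set_index("hybrid_id").loc[gid]
            members = [gid]
            fem, male = row["female_parent_id"], row["male_parent_id"]
        for trait in traits.traits:
            f1 = np.concatenate([traits.replicate_values(m, trait) for m in members])
            if f1.size == 0:  # traits recorded under the pooled id directly
                f1 = traits.replicate_values(gid, trait)
            pf = traits.replicate_values(fem, trait)
            pm = traits.replicate_values(male, trait)
            if f1.size == 0 or pf.size == 0 or pm.size == 0:
                continue
            res = compute_bph(f1, pf, pm, traits.polarity[trait])
            rows.append({"hybrid_id": gid, "trait": trait, "MPV": res.mpv,
                         "BPH": res.bph, "MPH": res.mph,
                         "better_parent": res.better_parent,
                         "female_parent_id": fem, "male_parent_id": male})
    return pd.DataFrame(rows)


def heterosis_correlations(table: pd.DataFrame, method: str = "pearson",
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trait x trait correlation of BPH across hybrids.

    Returns (correlation matrix, two-tailed p-value matrix). Pairs with
    fewer than three complete hybrids, or with a constant column, are
    masked as NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    wide = table.pivot(index="hybrid_id", columns="trait", values="BPH")
    traits = list(wide.columns)
    k = len(traits)
    corr = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    pval = pd.DataFrame(np.where(np.eye(k), 0.0, np.nan), index=traits, columns=traits)
    func = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i in range(k):
        for j in range(i + 1, k):
            sub = wide[[traits[i], traits[j]]].dropna()
            x, y = sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()
            if len(sub) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = func(x, y)
            corr.iloc[i, j] = corr.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    return corr, pval


def bootstrap_bph_ci(f1, p_female, p_male, polarity: str = "higher_better",
                     n_boot: int = 1000, level: float = 0.95,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for BPH over replicates."""
    rng = rng or np.random.default_rng()
    f1 = np.asarray(f1, float)
    pf = np.asarray(p_female, float)
    pm = np.asarray(p_male, float)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        draws[b] = compute_bph(rng.choice(f1, f1.size),
                               rng.choice(pf, pf.size),
                               rng.choice(pm, pm.size), polarity).bph
    lo = (1 - level) / 2
    return tuple(np.nanquantile(draws, [lo, 1 - lo]))
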