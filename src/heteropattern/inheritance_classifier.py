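"""Per-molecule inheritance-pattern classification in F1 hybrids.

For every molecule (transcript or metabolite feature) and every pooled
reciprocal hybrid, replicate levels of four groups — F1, female parent,
male parent, and a mid-parent pseudo-group — are compared by one-way
ANOVA with Fisher's-LSD-style pairwise contrasts on the pooled error
term. The contrast outcomes and the geometry of the means assign one of
five patterns:

* additive       — F1 indistinguishable from the mid-parent value (MPV)
                   but different from both parents;
* dominant       — F1 indistinguishable from one parent but different
                   from the MPV;
* partially dominant (PD) — F1 strictly between the MPV and the parent
                   on its side, different from both;
* overdominant   — F1 beyond the same-side parent and different from it;
* NA             — any other configuration (unclassified).

The degree of partial dominance is PD = (F1 - P_m) / (P_f - P_m), with
the female parent as the reference pole: 0 at the male parent, 0.5 at
the MPV, 1 at the female parent. PD degrees pooled over calls split at
0.5 into empirical low/high subtypes whose group means (canonically near
0.3 and 0.7) parameterize the virtual partially dominant profiles used
downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import (AnalysisConfig, CrossDesign, OmicsMatrix,
                            PATTERNS, SampleMeta)

#: relative tolerance below which the pooled error variance is treated as
#: exactly zero and contrasts fall back to exact mean equality
_ZERO_VAR_RTOL = 1e-12


@dataclass
class PatternCall:
    """Classification of one feature in one pooled hybrid."""

    feature_id: str
    hybrid_pooled_id: str
    pattern: str  # one of PATTERNS
    direction: str  # "female" | "male" | "none": parent the call points toward
    pd_degree: float  # NaN when parents indistinguishable in level
    p_vs_mpv: float
    p_vs_female: float
    p_vs_male: float
    reason: str = ""


def pd_degree(f1_mean: float, p_female_mean: float, p_male_mean: float) -> float:
    """Partial-dominance degree (F1 - P_m)/(P_f - P_m).

    Affine-invariant in the three levels; undefined (NaN) when the parents
    coincide. 0 at the male parent, 1 at the female parent, 0.5 at MPV.
    """
    denom = p_female_mean - p_male_mean
    if denom == 0:
        return float("nan")
    return (f1_mean - p_male_mean) / denom


def build_mpv_group(female_reps: np.ndarray, male_reps: np.ndarray,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Mid-parent pseudo-replicates: replicate-index-matched parental means.

    When the parents have unequal replicate counts the longer group is
    subsampled (seeded shuffle) to the shorter one before pairing.
    """
    nf, nm = len(female_reps), len(male_reps)
    if nf != nm:
        rng = rng or np.random.default_rng()
        if nf > nm:
            female_reps = rng.permutation(female_reps)[:nm]
        else:
            male_reps = rng.permutation(male_reps)[:nf]
    return (np.asarray(female_reps, float) + np.asarray(male_reps, float)) / 2.0


def _lsd_contrasts(groups: list[np.ndarray], alpha: float,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fisher's-LSD pairwise contrasts of group 0 (F1) against groups 1..3.

    Returns (means of all groups, p-values of the three contrasts,
    significance flags). With zero pooled within-group variance the
    contrasts degenerate to exact mean equality (p = 0 or 1).
    """
    means = np.array([g.mean() for g in groups])
    ns = np.array([g.size for g in groups])
    sse = sum(float(((g - m) ** 2).sum()) for g, m in zip(groups, means))
    df_err = int(ns.sum()) - len(groups)
    scale = float(np.mean(np.abs(means))) or 1.0
    mse = sse / df_err if df_err > 0 else 0.0
    diffs = means[0] - means[1:]
    if mse <= (_ZERO_VAR_RTOL * scale) ** 2:
        pvals = np.where(np.abs(diffs) <= _ZERO_VAR_RTOL * scale, 1.0, 0.0)
    else:
        se = np.sqrt(mse * (1.0 / ns[0] + 1.0 / ns[1:]))
        tstat = np.abs(diffs) / se
        pvals = 2.0 * stats.t.sf(tstat, df_err)
    return means, pvals, pvals < alpha


def classify_pattern(f1_reps, female_reps, male_reps, alpha: float = 0.05,
                     feature_id: str = "", hybrid_id: str = "",
                     rng: np.random.Generator | None = None) -> PatternCall:
    """Classify one feature's inheritance pattern in one pooled hybrid.

    ``f1_reps`` should already pool the replicates of both reciprocal
    hybrids. Groups with fewer than two replicates yield an NA call with a
    reason code rather than an error.
    """
    f1 = np.asarray(f1_reps, float)
    pf = np.asarray(female_reps, float)
    pm = np.asarray(male_reps, float)
    nan = float("nan")
    if min(f1.size, pf.size, pm.size) < 2:
        return PatternCall(feature_id, hybrid_id, "NA", "none", nan,
                           nan, nan, nan, reason="insufficient_replicates")
    mpv = build_mpv_group(pf, pm, rng)
    means, pvals, sig = _lsd_contrasts([f1, mpv, pf, pm], alpha)
    m_f1, m_mpv, m_pf, m_pm = means
    s_mpv, s_f, s_m = sig
    p_mpv, p_f, p_m = (float(p) for p in pvals)
    degree = pd_degree(m_f1, m_pf, m_pm)

    # parent on the same side of the MPV as the F1 mean
    if m_f1 > m_mpv:
        same_side = "female" if m_pf >= m_pm else "male"
    elif m_f1 < m_mpv:
        same_side = "female" if m_pf <= m_pm else "male"
    else:
        same_side = "none"
    m_side = {"female": m_pf, "male": m_pm}.get(same_side, nan)
    s_side = {"female": s_f, "male": s_m}.get(same_side, False)

    pattern, direction, reason = "NA", "none", ""
    if (not s_mpv) and s_f and s_m:
        pattern = "additive"
    elif s_mpv and (not s_f or not s_m):
        pattern = "dominant"
        if not s_f and not s_m:  # nearer parent breaks the tie
            direction = "female" if abs(m_f1 - m_pf) <= abs(m_f1 - m_pm) else "male"
        else:
            direction = "female" if not s_f else "male"
    elif (same_side != "none" and s_mpv and s_side
          and min(m_mpv, m_side) < m_f1 < max(m_mpv, m_side)):
        pattern = "partially_dominant"
        direction = same_side
    elif (same_side != "none" and s_side
          and not (min(m_mpv, m_side) <= m_f1 <= max(m_mpv, m_side))):
        pattern = "overdominant"
        direction = same_side
    else:
        reason = "unresolved_contrasts"
    if pattern != "partially_dominant" and pattern != "NA" and np.isnan(degree):
        reason = "equal_parents"
    return PatternCall(feature_id, hybrid_id, pattern, direction, degree,
                       p_mpv, p_f, p_m, reason)


def classify_study(matrix: OmicsMatrix, meta: SampleMeta, design: CrossDesign,
                   config: AnalysisConfig | None = None,
                   per_stage: bool = False,
                   features: list[str] | None = None) -> pd.DataFrame:
    """Classify every feature in every pooled reciprocal hybrid.

    Stages are pooled by default (set ``per_stage`` to classify each stage
    separately; stage then appears as an extra column). Returns a tidy
    DataFrame of :class:`PatternCall` fields.
    """
    config = config or AnalysisConfig()
    rng = config.rng()
    features = features if features is not None else matrix.feature_ids
    vals = matrix.values
    stages = meta.stages if per_stage else [None]
    rows = []
    for pooled in design.pooled_ids:
        fem, male = design.parents_of(pooled)
        members = design.members_of(pooled)
        for stage in stages:
            f1_samples = [s for m in members for s in meta.samples_of(m, stage)]
            pf_samples = meta.samples_of(fem, stage)
            pm_samples = meta.samples_of(male, stage)
            if not f1_samples or not pf_samples or not pm_samples:
                continue
            f1_block = vals[f1_samples].to_numpy()
            pf_block = vals[pf_samples].to_numpy()
            pm_block = vals[pm_samples].to_numpy()
            index = {f: i for i, f in enumerate(matrix.feature_ids)}
            for f in features:
                i = index[f]
                call = classify_pattern(f1_block[i], pf_block[i], pm_block[i],
                                        config.alpha, f, pooled, rng)
                row = call.__dict__.copy()
                if per_stage:
                    row["stage"] = stage
                rows.append(row)
    return pd.DataFrame(rows)


def estimate_pd_subtypes(degrees, split: float = 0.5,
                         fallback: tuple[float, float] = (0.3, 0.7),
                         ) -> tuple[float, float]:
    """Empirical PD subtypes: mean degree below and above the split.

    The two means become the ``t`` parameters of the virtual partially
    dominant profiles. An empty side falls back to the canonical values
    (0.3 / 0.7) with a warning.
    """
    d = np.asarray(degrees, float)
    d = d[np.isfinite(d)]
    low = d[d < split]
    high = d[d >= split]
    t_low, t_high = fallback
    if low.size:
        t_low = float(low.mean())
    else:
        warnings.warn(f"no PD degrees below {split}; using fallback {fallback[0]}")
    if high.size:
        t_high = float(high.mean())
    else:
        warnings.warn(f"no PD degrees above {split}; using fallback {fallback[1]}")
    return t_low, t_high


def pattern_proportions(calls: pd.DataFrame,
                        weights: pd.Series | None = None) -> pd.DataFrame:
    """Per-hybrid proportions over the five patterns (rows sum to 1).

    ``weights`` optionally weight features (indexed by feature_id), e.g. to
    emphasize features tied to a trait.
    """
    out = {}
    for hybrid, grp in calls.groupby("hybrid_pooled_id"):
        if weights is not None:
            w = weights.reindex(grp["feature_id"]).fillna(0).to_numpy()
        else:
            w = np.ones(len(grp))
        total = w.sum()
        props = {p: float(w[(grp["pattern"] == p).to_numpy()].sum()) / total
                 for p in PATTERNS}
        out[hybrid] = props
    return pd.DataFrame(out).T[PATTERNS]
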