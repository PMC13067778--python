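"""Virtual hybrid profiles and heterosis predictability via PLS.

A *virtual hybrid profile* predicts every F1 molecular level from the
parental levels under an assumed inheritance pattern:

* ``additive``         (P_f + P_m) / 2
* ``PD_low``/``PD_high``  P_m + t (P_f - P_m) with t the empirical
  partial-dominance subtypes (canonically 0.3 / 0.7)
* ``dominant_female``  P_f          * ``dominant_male``  P_m
* ``actual_F1``        measured hybrid means, when available

Predictability of a response (trait heterosis, or the hybrid phenotype)
from each profile mode is scored two ways, following common
chemometrics practice:

* PLS regression scanned over latent-factor counts; the model is chosen
  by the highest adjusted R^2 = 1 - (1 - R^2)(n-1)/(n-k-1), with k the
  number of latent factors;
* PLS-DA on discrete heterosis classes with tenfold cross-validated
  Q^2 = 1 - PRESS/TSS over at most five components, plus a label
  permutation test on the between/within-class separation (B/W) of the
  first-component scores.

Predictors are autoscaled inside every fit; fold assignment and label
permutations are seeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .data_model_io import AnalysisConfig, CrossDesign

MODES = ["actual_F1", "additive", "PD_low", "PD_high",
         "dominant_female", "dominant_male"]


@dataclass
class PredictabilityResult:
    mode: str
    adj_r2_curve: list[float] = field(default_factory=list)
    best_adj_r2: float = float("nan")
    best_n_factors: int = 0
    r2_at_best: float = float("nan")
    q2: float = float("nan")
    q2_n_components: int = 0
    permutation_p: float = float("nan")


# ---------------------------------------------------------------------------
# virtual profiles
# ---------------------------------------------------------------------------

def build_virtual_profiles(parent_means: pd.DataFrame, design: CrossDesign,
                           pd_params: tuple[float, float] = (0.3, 0.7),
                           f1_means: pd.DataFrame | None = None,
                           ) -> dict[str, pd.DataFrame]:
    """Hybrid x feature matrices, one per inheritance-pattern mode.

    ``parent_means`` is features x parent genotypes; ``f1_means``
    (features x pooled hybrid ids), when given, supplies the
    ``actual_F1`` mode. Hybrids whose parents lack profiles are dropped
    with a log entry.
    """
    t_low, t_high = pd_params
    rows = {m: [] for m in MODES if m != "actual_F1"}
    kept = []
    for pooled in design.pooled_ids:
        fem, male = design.parents_of(pooled)
        if fem not in parent_means.columns or male not in parent_means.columns:
            import logging
            logging.getLogger("heteropattern").warning(
                "dropping hybrid %s: missing parent profile", pooled)
            continue
        pf = parent_means[fem].to_numpy(float)
        pm = parent_means[male].to_numpy(float)
        kept.append(pooled)
        rows["additive"].append((pf + pm) / 2.0)
        rows["PD_low"].append(pm + t_low * (pf - pm))
        rows["PD_high"].append(pm + t_high * (pf - pm))
        rows["dominant_female"].append(pf)
        rows["dominant_male"].append(pm)
    profiles = {m: pd.DataFrame(v, index=kept, columns=parent_means.index)
                for m, v in rows.items()}
    if f1_means is not None:
        avail = [h for h in kept if h in f1_means.columns]
        profiles["actual_F1"] = f1_means[avail].T
    return profiles


# ---------------------------------------------------------------------------
# PLS fitting
# ---------------------------------------------------------------------------

def fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int) -> PLSRegression:
    """Autoscaled NIPALS PLS fit (thin wrapper, convergence warnings muted)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PLSRegression(n_components=n_components, scale=True,
                              max_iter=2000)
        model.fit(X, Y)
    return model


def vip_matrix(model: PLSRegression) -> np.ndarray:
    """Per-factor VIP scores, shape (n_features, n_components).

    Column ``a`` holds the VIP of every predictor for the model truncated
    to the first ``a + 1`` latent factors. Each column satisfies the VIP
    normalization identity: the VIPs' squares sum to the number of
    predictors.
    """
    W = model.x_weights_          # p x A
    T = model.x_scores_           # n x A
    Q = model.y_loadings_         # q x A
    p, A = W.shape
    ss = (Q ** 2).sum(axis=0) * (T ** 2).sum(axis=0)  # explained SS per factor
    Wn2 = (W / np.linalg.norm(W, axis=0)) ** 2        # p x A, columns sum to 1
    vips = np.empty((p, A))
    for a in range(A):
        num = Wn2[:, : a + 1] @ ss[: a + 1]
        vips[:, a] = np.sqrt(p * num / ss[: a + 1].sum())
    return vips


def mean_vip(model: PLSRegression) -> np.ndarray:
    """Mean VIP across all retained latent factors (screening statistic)."""
    return vip_matrix(model).mean(axis=1)


def pls_scan(predictors: pd.DataFrame | np.ndarray, response,
             config: AnalysisConfig | None = None,
             mode: str = "") -> PredictabilityResult:
    """Scan PLS latent-factor counts; pick the highest adjusted R^2.

    The factor count is capped at ``min(max_latent_regression,
    n_samples - 2, n_features)``. Raises on a constant response.
    """
    config = config or AnalysisConfig()
    X = np.asarray(predictors, float)
    y = np.asarray(response, float).reshape(-1, 1)
    n, p = X.shape
    if n < 4:
        raise ValueError("PLS scan needs at least 4 samples")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; predictability undefined")
    kmax = max(1, min(config.max_latent_regression, n - 2, p))
    tss = float(((y - y.mean()) ** 2).sum())
    curve = []
    for k in range(1, kmax + 1):
        model = fit_pls(X, y, k)
        resid = y - model.predict(X)
        r2 = 1.0 - float((resid ** 2).sum()) / tss
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
        curve.append(adj)
    best_k = int(np.argmax(curve)) + 1
    best = PredictabilityResult(mode=mode, adj_r2_curve=curve,
                                best_adj_r2=float(curve[best_k - 1]),
                                best_n_factors=best_k)
    model = fit_pls(X, y, best_k)
    resid = y - model.predict(X)
    best.r2_at_best = 1.0 - float((resid ** 2).sum()) / tss
    return best


def _one_hot(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    Y = (labels[:, None] == classes[None, :]).astype(float)
    return Y, classes


def plsda_q2(predictors, class_labels, config: AnalysisConfig | None = None,
             rng: np.random.Generator | None = None) -> PredictabilityResult:
    """PLS-DA predictability: cross-validated Q^2 over <= 5 components.

    The class response is one-hot encoded; Q^2 = 1 - PRESS/TSS pooled over
    stratified tenfold cross-validation (fold count reduced to the
    smallest class when needed), maximized over the component count.
    """
    config = config or AnalysisConfig()
    rng = rng or config.rng()
    X = np.asarray(predictors, float)
    labels = np.asarray(class_labels)
    Y, classes = _one_hot(labels)
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least two classes")
    counts = Y.sum(axis=0)
    if counts.min() < 3:
        raise ValueError("every class needs at least 3 members")
    n, p = X.shape
    n_splits = int(min(config.cv_folds, counts.min()))
    kmax = max(1, min(config.max_components_da, n - n // n_splits - 2, p))
    seed = int(rng.integers(2 ** 31 - 1))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    best_q2, best_k = -np.inf, 0
    for k in range(1, kmax + 1):
        press = tss = 0.0
        for train, test in cv.split(X, labels):
            model = fit_pls(X[train], Y[train], k)
            pred = model.predict(X[test])
            press += float(((Y[test] - pred) ** 2).sum())
            tss += float(((Y[test] - Y[train].mean(axis=0)) ** 2).sum())
        q2 = 1.0 - press / tss
        if q2 > best_q2:
            best_q2, best_k = q2, k
    return PredictabilityResult(mode="PLS-DA", q2=float(best_q2),
                                q2_n_components=best_k)


def _component1_scores(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """First-component PLS scores: X projected on the dominant direction of
    the X'Y cross-covariance (SVD form of the first NIPALS component)."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xc = Xc / sd
    Yc = Y - Y.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
    return Xc @ u[:, 0]


def _bw_statistic(scores: np.ndarray, labels: np.ndarray) -> float:
    """Between-class to within-class sum-of-squares ratio of scores."""
    grand = scores.mean()
    between = within = 0.0
    for c in np.unique(labels):
        grp = scores[labels == c]
        between += grp.size * (grp.mean() - grand) ** 2
        within += float(((grp - grp.mean()) ** 2).sum())
    return between / within if within > 0 else np.inf


def permutation_test(predictors, class_labels,
                     config: AnalysisConfig | None = None,
                     n_permutations: int | None = None,
                     rng: np.random.Generator | None = None,
                     all_components: bool = False) -> float:
    """Label-permutation p-value for PLS-DA class separation.

    The statistic is the B/W ratio of the first-component scores (set
    ``all_components`` to pool scores of up to ``max_components_da``
    components instead). The p-value uses the add-one rule
    p = (1 + #{permuted >= observed}) / (1 + n_permutations), so its
    minimum at 2000 permutations is 1/2001.
    """
    config = config or AnalysisConfig()
    rng = rng or config.rng()
    n_perm = n_permutations or config.n_permutations
    X = np.asarray(predictors, float)
    labels = np.asarray(class_labels)
    Y, _ = _one_hot(labels)

    def statistic(lab: np.ndarray) -> float:
        Yl, _ = _one_hot(lab)
        if all_components:
            k = max(1, min(config.max_components_da, X.shape[0] - 2, X.shape[1]))
            model = fit_pls(X, Yl, k)
            scores = model.x_scores_
            return float(np.mean([_bw_statistic(scores[:, a], lab)
                                  for a in range(scores.shape[1])]))
        return _bw_statistic(_component1_scores(X, Yl), lab)

    observed = statistic(labels)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if statistic(perm) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


# ---------------------------------------------------------------------------
# mode comparison
# ---------------------------------------------------------------------------

def compare_modes(profiles: dict[str, pd.DataFrame], response,
                  config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Rank inheritance-pattern modes by PLS predictability of a response.

    ``response`` may be a Series (one trait) or DataFrame (hybrids x
    traits); every mode is scanned on the identical hybrid set. Returns a
    tidy table (mode, trait, best adjusted R^2, factor count) sorted by
    predictability within each trait.
    """
    config = config or AnalysisConfig()
    if len(profiles) < 2:
        raise ValueError("mode comparison needs at least two modes")
    resp = pd.DataFrame(response) if not isinstance(response, pd.DataFrame) else response
    common = None
    for mat in profiles.values():
        common = mat.index if common is None else common.intersection(mat.index)
    common = common.intersection(resp.index)
    rows = []
    for trait in resp.columns:
        y = resp.loc[common, trait]
        for mode, mat in profiles.items():
            res = pls_scan(mat.loc[common], y, config, mode=mode)
            rows.append({"mode": mode, "trait": trait,
                         "best_adj_r2": res.best_adj_r2,
                         "n_factors": res.best_n_factors})
    out = pd.DataFrame(rows)
    out["rank"] = out.groupby("trait")["best_adj_r2"].rank(ascending=False)
    return out.sort_values(["trait", "rank"]).reset_index(drop=True)


def mode_lsd_comparison(table: pd.DataFrame) -> pd.DataFrame:
    """Paired LSD-style contrasts of best adjusted R^2 between modes.

    Treats traits as replicates (one-way ANOVA across modes with Fisher's
    LSD pairwise t-contrasts on the pooled error term). Needs >= 2 traits.
    """
    wide = table.pivot(index="trait", columns="mode", values="best_adj_r2")
    modes = list(wide.columns)
    if wide.shape[0] < 2:
        raise ValueError("LSD comparison needs at least two traits")
    groups = [wide[m].dropna().to_numpy() for m in modes]
    means = [g.mean() for g in groups]
    ns = [g.size for g in groups]
    sse = sum(float(((g - m) ** 2).sum()) for g, m in zip(groups, means))
    df_err = sum(ns) - len(groups)
    mse = sse / df_err if df_err else 0.0
    out = pd.DataFrame(np.nan, index=modes, columns=modes)
    for i, a in enumerate(modes):
        for j, b in enumerate(modes):
            if i >= j:
                continue
            se = np.sqrt(mse * (1 / ns[i] + 1 / ns[j]))
            if se == 0:
                p = 0.0 if means[i] != means[j] else 1.0
            else:
                t = abs(means[i] - means[j]) / se
                p = 2 * stats.t.sf(t, df_err)
            out.loc[a, b] = out.loc[b, a] = p
    np.fill_diagonal(out.values, 1.0)
    return out
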