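"""Outcome analysis for stented femoral bifurcations.

Patency classification (duplex PSVR rule), cohort summaries, zone-wise
two-group comparisons with Benjamini–Hochberg false-discovery-rate control,
logistic-regression odds ratios, ROC analysis with Youden-index threshold
discovery (DeLong AUC confidence interval), bias-corrected bootstrap
validation of the discovered threshold, and two-way random-effects intraclass
correlation for inter-observer agreement.

Primary patency uses the Methods definition: a peak systolic velocity ratio
(PSVR) of 2.4 *or lower* in the absence of clinically driven target lesion
revascularisation (TLR).  A limb with no PSVR and no TLR is unevaluable and
drops out of the patency denominator.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "PSVR_CUTOFF",
    "classify_patency",
    "add_patency",
    "summarize_cohort",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "compare_groups",
    "GroupComparison",
    "fit_logistic",
    "LogisticFit",
    "roc_youden",
    "ROCResult",
    "bootstrap_threshold",
    "BootstrapResult",
    "icc_agreement",
    "AgreementResult",
    "plot_roc",
]

PSVR_CUTOFF = 2.4

#: combined sample size at or below which the rank-sum test is exact
WILCOXON_EXACT_MAX_N = 25


# ---------------------------------------------------------------------------
# patency and cohort summaries
# ---------------------------------------------------------------------------

def classify_patency(psvr: float, tlr_performed: bool, cutoff: float = PSVR_CUTOFF) -> str | float:
    """Classify one limb: patent iff PSVR <= cutoff and no clinically driven TLR.

    Returns ``"patent"``, ``"restenosis"`` or NaN when the limb is
    unevaluable (no PSVR and no TLR).
    """
    if tlr_performed:
        return "restenosis"
    if psvr is None or (isinstance(psvr, float) and np.isnan(psvr)):
        return np.nan
    if psvr <= 0:
        raise ValueError("PSVR must be positive")
    return "patent" if psvr <= cutoff else "restenosis"


def add_patency(
    df: pd.DataFrame,
    psvr_col: str = "psvr_12m",
    tlr_col: str = "tlr_performed",
    out_col: str = "patency",
    cutoff: float = PSVR_CUTOFF,
) -> pd.DataFrame:
    """Vectorised patency classification; unevaluable limbs get NaN."""
    psvr = pd.to_numeric(df[psvr_col], errors="coerce")
    tlr = df[tlr_col].fillna(False).astype(bool)
    out = np.where(
        tlr, "restenosis", np.where(psvr <= cutoff, "patent", "restenosis")
    ).astype(object)
    out[psvr.isna() & ~tlr] = np.nan
    res = df.copy()
    res[out_col] = out
    return res


def summarize_cohort(df: pd.DataFrame, cutoff: float = PSVR_CUTOFF) -> dict:
    """Cohort-level counts and rates.

    Patency denominators exclude limbs that died or were lost to follow-up
    (and any limb left unevaluable).  Percentages are rounded to one decimal,
    except the Azema distribution which is reported as integer percentages.
    """
    if df.empty:
        raise ValueError("cohort is empty")
    n = len(df)
    followed = df["followup_status"].eq("followed")
    cls = add_patency(df, cutoff=cutoff)["patency"]
    evaluable = followed & cls.notna()
    n_eval = int(evaluable.sum())
    n_patent = int((cls[evaluable] == "patent").sum())

    out = {
        "n_limbs": n,
        "n_followed": int(followed.sum()),
        "followup_12m_pct": round(100.0 * followed.sum() / n, 1),
        "followup_1m_pct": round(100.0 * df["psvr_1m"].notna().sum() / n, 1),
        "n_evaluable": n_eval,
        "n_patent": n_patent,
        "n_restenosis": n_eval - n_patent,
        "patency_12m_pct": round(100.0 * n_patent / n_eval, 1) if n_eval else np.nan,
        "restenosis_12m_pct": (
            round(100.0 * (n_eval - n_patent) / n_eval, 1) if n_eval else np.nan
        ),
    }
    ind = df["indication"]
    out["claudication_pct"] = round(100.0 * ind.eq("claudication").sum() / n, 1)
    out["clti_pct"] = round(100.0 * ind.eq("CLTI").sum() / n, 1)
    out["azema_pct"] = {
        k: int(round(100.0 * (df["azema"] == k).sum() / n)) for k in ("I", "II", "III")
    }
    return out


# ---------------------------------------------------------------------------
# group comparison and multiplicity
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = WILCOXON_EXACT_MAX_N
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact null enumeration when the combined sample is small (<= 25) and free
    of ties; otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values.

    Order-preserving with the input, monotone in p within the family, capped
    at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class GroupComparison:
    """Zone-metric comparison table between outcome groups.

    ``table`` has one row per metric with group medians/IQRs, the test used,
    the raw p and the Benjamini–Hochberg q computed across all rows of this
    one family (declared in ``family``).
    """

    table: pd.DataFrame
    family: str
    groups: tuple[str, str]


def _is_categorical(series: pd.Series) -> bool:
    return series.dtype == object or series.dtype == bool or isinstance(
        series.dtype, pd.CategoricalDtype
    )


def compare_groups(
    df: pd.DataFrame,
    metrics: Sequence[str],
    group_col: str = "patency",
    groups: tuple[str, str] = ("restenosis", "patent"),
    family: str | None = None,
) -> GroupComparison:
    """Compare metrics between the two outcome groups with FDR control.

    Continuous metrics use the Wilcoxon rank-sum test; categorical metrics use
    Fisher's exact test (2x2 with any expected count below 5) or the
    chi-square test.  Metrics that are entirely missing in a group are skipped
    with a warning.  q-values are computed across every retained row of this
    one call, and the family label is stored in the result metadata.
    """
    g0 = df[df[group_col] == groups[0]]
    g1 = df[df[group_col] == groups[1]]
    if g0.empty or g1.empty:
        raise ValueError("both outcome groups must be non-empty")
    rows = []
    for metric in metrics:
        a, b = g0[metric], g1[metric]
        if _is_categorical(df[metric]):
            tab = pd.crosstab(df[group_col], df[metric])
            expected = sps.contingency.expected_freq(tab.to_numpy())
            if tab.shape == (2, 2) and (expected < 5).any():
                p = float(sps.fisher_exact(tab.to_numpy())[1])
                test = "fisher"
            else:
                p = float(sps.chi2_contingency(tab.to_numpy())[1])
                test = "chi-square"
            summary = {
                f"{groups[0]}_median": np.nan, f"{groups[0]}_q1": np.nan,
                f"{groups[0]}_q3": np.nan, f"{groups[1]}_median": np.nan,
                f"{groups[1]}_q1": np.nan, f"{groups[1]}_q3": np.nan,
            }
        else:
            a = pd.to_numeric(a, errors="coerce").dropna()
            b = pd.to_numeric(b, errors="coerce").dropna()
            if a.empty or b.empty:
                warnings.warn(f"metric '{metric}' is all-missing in a group; skipped")
                continue
            p = wilcoxon_rank_sum(a.to_numpy(), b.to_numpy())
            test = "wilcoxon"
            summary = {
                f"{groups[0]}_median": float(a.median()),
                f"{groups[0]}_q1": float(a.quantile(0.25)),
                f"{groups[0]}_q3": float(a.quantile(0.75)),
                f"{groups[1]}_median": float(b.median()),
                f"{groups[1]}_q1": float(b.quantile(0.25)),
                f"{groups[1]}_q3": float(b.quantile(0.75)),
            }
        rows.append({"metric": metric, **summary, "test": test, "p_value": p})
    if not rows:
        raise ValueError("no metric could be compared")
    table = pd.DataFrame(rows)
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    return GroupComparison(
        table=table,
        family=family or f"{len(rows)} metrics, single comparison table",
        groups=groups,
    )


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Odds ratios with Wald 95% confidence intervals from a logistic model."""

    table: pd.DataFrame
    n: int
    outcome: str
    predictors: list[str]
    converged: bool

    def odds_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "odds_ratio"])


def fit_logistic(
    df: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome.

    ``outcome`` must be a boolean/0-1 column; categorical predictors are
    dummy-coded with the first level as reference.  Raises on degenerate
    outcomes, constant predictors and (quasi-)complete separation.
    """
    y = df[outcome].astype(float)
    if y.isna().any():
        keep = y.notna()
        df, y = df[keep], y[keep]
    if not set(np.unique(y)) == {0.0, 1.0}:
        raise ValueError(f"outcome '{outcome}' must contain both classes")
    X = pd.get_dummies(df[list(predictors)], drop_first=True).astype(float)
    for col in X.columns:
        if X[col].nunique() < 2:
            raise ValueError(f"predictor '{col}' is constant")
    model = sm.Logit(y.to_numpy(), sm.add_constant(X, has_constant="add"))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            f"complete separation in predictors {list(X.columns)}"
        ) from exc
    params = pd.Series(res.params, index=model.exog_names)
    if (not res.mle_retvals.get("converged", False)) or np.any(
        np.abs(params.drop("const")) > 15
    ):
        worst = params.drop("const").abs().idxmax()
        raise ValueError(f"possible complete separation for predictor '{worst}'")
    ci = pd.DataFrame(
        np.asarray(res.conf_int()), index=model.exog_names, columns=["lo", "hi"]
    )
    table = pd.DataFrame(
        {
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(ci["lo"]),
            "ci_high": np.exp(ci["hi"]),
            "p_value": pd.Series(res.pvalues, index=model.exog_names),
        }
    ).drop(index="const")
    return LogisticFit(
        table=table,
        n=int(res.nobs),
        outcome=outcome,
        predictors=list(X.columns),
        converged=bool(res.mle_retvals.get("converged", False)),
    )


# ---------------------------------------------------------------------------
# ROC / Youden and bootstrap
# ---------------------------------------------------------------------------

def _auc_rank(scores: np.ndarray, pos: np.ndarray) -> float:
    """AUC for 'higher score predicts positive' via midranks (ties count 1/2);
    identical to the trapezoidal area under the empirical ROC."""
    ranks = sps.rankdata(scores)
    m = int(pos.sum())
    n = len(scores) - m
    return float((ranks[pos].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_variance(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """DeLong variance of the AUC estimate (midrank formulation)."""
    m, n = len(pos_scores), len(neg_scores)
    if m < 2 or n < 2:
        return np.nan
    allsc = np.concatenate([pos_scores, neg_scores])
    tz = sps.rankdata(allsc)
    tx = sps.rankdata(pos_scores)
    ty = sps.rankdata(neg_scores)
    v_pos = (tz[:m] - tx) / n  # structural components over positives
    v_neg = 1.0 - (tz[m:] - ty) / m
    s_pos = np.var(v_pos, ddof=1)
    s_neg = np.var(v_neg, ddof=1)
    return float(s_pos / m + s_neg / n)


def _youden_threshold(
    scores: np.ndarray, pos: np.ndarray, direction: str
) -> tuple[float, float]:
    """Best Youden threshold and J, candidates at midpoints between distinct scores.

    ``direction`` is ``"greater"`` (score >= t predicts positive) or
    ``"less"`` (score <= t predicts positive).  Ties on J resolve to the
    lowest threshold.
    """
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    y = pos[order]
    edges = np.flatnonzero(np.diff(s) > 0)
    if len(edges) == 0:
        raise ValueError("need at least two distinct score values")
    mids = 0.5 * (s[edges] + s[edges + 1])
    cpos = np.cumsum(y)[edges].astype(float)
    cneg = np.cumsum(~y)[edges].astype(float)
    npos, nneg = float(y.sum()), float((~y).sum())
    if direction == "greater":
        sens = (npos - cpos) / npos
        spec = cneg / nneg
    else:
        sens = cpos / npos
        spec = (nneg - cneg) / nneg
    j = sens + spec - 1.0
    # ties on J (within numerical noise) resolve to the lowest midpoint
    k = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return float(mids[k]), float(j[k])


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    if nobs == 0:
        return (np.nan, np.nan)
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


@dataclass
class ROCResult:
    """ROC analysis with Youden-index threshold discovery.

    ``direction`` records the orientation of the positive-prediction rule:
    ``"greater"`` means scores at or above the threshold predict the positive
    class, ``"less"`` the reverse (the relevant case when high calcification
    density protects against restenosis).  AUC is reported after orientation,
    so it is always >= 0.5 when the direction was chosen automatically.
    """

    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    youden_j: float
    direction: str
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    prevalence: float
    n_pos: int
    n_neg: int
    positive_label: str
    curve: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "auc", "threshold", "youden_j", "direction", "sensitivity",
                "specificity", "ppv", "npv", "prevalence", "n_pos", "n_neg",
                "positive_label",
            )
        }
        for k in ("auc_ci", "sensitivity_ci", "specificity_ci", "ppv_ci", "npv_ci"):
            d[k] = list(getattr(self, k))
        return d


def roc_youden(
    scores: Sequence[float],
    labels: Sequence,
    positive: object = "restenosis",
    direction: str = "auto",
) -> ROCResult:
    """Empirical ROC with trapezoidal AUC, DeLong CI and Youden threshold.

    The AUC equals the pairwise concordance probability with ties counted
    one half.  Candidate thresholds are midpoints between consecutive distinct
    scores; among ties on the Youden index the lowest threshold is returned.
    Predictive values come from the confusion table at the chosen threshold
    (equivalently, Bayes' formula at the observed prevalence) with Wilson
    intervals on the implied counts.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(scores) & ~pd.isna(labels)
    scores, labels = scores[keep], labels[keep]
    pos = labels == positive
    npos, nneg = int(pos.sum()), int((~pos).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("both outcome classes must be present")
    if len(np.unique(scores)) < 2:
        raise ValueError("need at least two distinct score values")

    auc_greater = _auc_rank(scores, pos)
    if direction == "auto":
        direction = "greater" if auc_greater >= 0.5 else "less"
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'auto', 'greater' or 'less'")
    oriented = scores if direction == "greater" else -scores
    auc = auc_greater if direction == "greater" else 1.0 - auc_greater
    var = _delong_variance(oriented[pos], oriented[~pos])
    se = np.sqrt(var) if np.isfinite(var) else np.nan
    z = sps.norm.ppf(0.975)
    auc_ci = (
        float(np.clip(auc - z * se, 0, 1)) if np.isfinite(se) else np.nan,
        float(np.clip(auc + z * se, 0, 1)) if np.isfinite(se) else np.nan,
    )

    thr, jbest = _youden_threshold(scores, pos, direction)
    pred_pos = scores >= thr if direction == "greater" else scores <= thr
    tp = int(np.sum(pred_pos & pos))
    fp = int(np.sum(pred_pos & ~pos))
    fn = npos - tp
    tn = nneg - fp
    sens, spec = tp / npos, tn / nneg
    ppv = tp / (tp + fp) if (tp + fp) else np.nan
    npv = tn / (tn + fn) if (tn + fn) else np.nan

    # curve points, one per distinct threshold, oriented
    u = np.unique(oriented)[::-1]
    tpr = [(oriented[pos] >= t).mean() for t in u]
    fpr = [(oriented[~pos] >= t).mean() for t in u]
    curve = pd.DataFrame(
        {"fpr": [0.0] + fpr + [1.0], "tpr": [0.0] + tpr + [1.0],
         "threshold": [np.inf] + list(u if direction == "greater" else -u) + [-np.inf]}
    )

    return ROCResult(
        auc=auc,
        auc_ci=auc_ci,
        threshold=thr,
        youden_j=jbest,
        direction=direction,
        sensitivity=sens,
        sensitivity_ci=_wilson(tp, npos),
        specificity=spec,
        specificity_ci=_wilson(tn, nneg),
        ppv=ppv,
        ppv_ci=_wilson(tp, tp + fp),
        npv=npv,
        npv_ci=_wilson(tn, tn + fn),
        prevalence=npos / (npos + nneg),
        n_pos=npos,
        n_neg=nneg,
        positive_label=str(positive),
        curve=curve,
    )


@dataclass
class BootstrapResult:
    """Bootstrap distribution of the Youden threshold."""

    B: int
    estimate: float
    ci_low: float
    ci_high: float
    ci_method: str
    threshold_original: float
    thresholds: np.ndarray = field(repr=False)
    n_redraws: int = 0
    seed: int | None = None

    @property
    def ci_contains_estimate(self) -> bool:
        return bool(self.ci_low <= self.estimate <= self.ci_high)


def _bc_interval(
    thetas: np.ndarray, theta_hat: float, alpha: float, accel: float = 0.0
) -> tuple[float, float]:
    """Bias-corrected (optionally accelerated) percentile interval."""
    B = len(thetas)
    prop = (np.sum(thetas < theta_hat) + 0.5 * np.sum(thetas == theta_hat)) / B
    prop = float(np.clip(prop, 1.0 / (2 * B), 1 - 1.0 / (2 * B)))
    z0 = sps.norm.ppf(prop)
    zlo, zhi = sps.norm.ppf(alpha / 2), sps.norm.ppf(1 - alpha / 2)
    a1 = sps.norm.cdf(z0 + (z0 + zlo) / (1 - accel * (z0 + zlo)))
    a2 = sps.norm.cdf(z0 + (z0 + zhi) / (1 - accel * (z0 + zhi)))
    lo, hi = np.quantile(thetas, [a1, a2])
    return float(lo), float(hi)


def bootstrap_threshold(
    scores: Sequence[float],
    labels: Sequence,
    B: int = 1000,
    seed: int = 0,
    positive: object = "restenosis",
    direction: str = "auto",
    stratified: bool = False,
    ci_method: str = "bc",
    alpha: float = 0.05,
) -> BootstrapResult:
    """Bootstrap validation of the Youden threshold.

    Limbs are resampled with replacement (simple resampling by default,
    outcome-stratified on request); the threshold is recomputed per replicate
    with the orientation fixed from the full sample.  Replicates that lose an
    outcome class are redrawn and counted.  The point estimate is the median
    of the replicate thresholds; the confidence interval is bias-corrected
    percentile (``"bc"``) or bias-corrected and accelerated (``"bca"`` via
    jackknife).  Fully reproducible from ``seed``.
    """
    if B < 2:
        raise ValueError("B must be >= 2; a confidence interval needs replicates")
    if ci_method not in ("bc", "bca"):
        raise ValueError("ci_method must be 'bc' or 'bca'")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(scores) & ~pd.isna(labels)
    scores, labels = scores[keep], labels[keep]
    pos = labels == positive
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError("both outcome classes must be present")
    auc_greater = _auc_rank(scores, pos)
    if direction == "auto":
        direction = "greater" if auc_greater >= 0.5 else "less"
    theta_hat, _ = _youden_threshold(scores, pos, direction)

    rng = np.random.default_rng(seed)
    ntot = len(scores)
    pos_idx = np.flatnonzero(pos)
    neg_idx = np.flatnonzero(~pos)
    thetas = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            if stratified:
                idx = np.concatenate(
                    [
                        pos_idx[rng.integers(0, len(pos_idx), len(pos_idx))],
                        neg_idx[rng.integers(0, len(neg_idx), len(neg_idx))],
                    ]
                )
            else:
                idx = rng.integers(0, ntot, ntot)
            p = pos[idx]
            if p.any() and (~p).any() and len(np.unique(scores[idx])) >= 2:
                break
            redraws += 1
            if redraws > 100 + 10 * B:
                raise RuntimeError("too many degenerate bootstrap replicates")
        thetas[b], _ = _youden_threshold(scores[idx], p, direction)

    accel = 0.0
    if ci_method == "bca":
        jack = np.empty(ntot)
        for i in range(ntot):
            mask = np.ones(ntot, dtype=bool)
            mask[i] = False
            jack[i], _ = _youden_threshold(scores[mask], pos[mask], direction)
        d = jack.mean() - jack
        denom = 6.0 * (np.sum(d**2) ** 1.5)
        accel = float(np.sum(d**3) / denom) if denom > 0 else 0.0
    lo, hi = _bc_interval(thetas, theta_hat, alpha, accel)
    return BootstrapResult(
        B=B,
        estimate=float(np.median(thetas)),
        ci_low=lo,
        ci_high=hi,
        ci_method=ci_method,
        threshold_original=theta_hat,
        thresholds=thetas,
        n_redraws=redraws,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# inter-observer agreement
# ---------------------------------------------------------------------------

@dataclass
class AgreementResult:
    """Intraclass correlation with an F-based 95% confidence interval."""

    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int
    model: str = "two-way random effects, absolute agreement, single measurement"


def icc_agreement(ratings: pd.DataFrame, alpha: float = 0.05) -> AgreementResult:
    """ICC(2,1) from the two-way ANOVA mean squares of a subjects-by-raters table.

    Requires a complete table with at least 5 subjects and 2 raters; missing
    cells raise (no imputation).  A table with no between-subject variance
    yields an ICC at or below zero, reported as computed.
    """
    data = ratings.to_numpy(dtype=float)
    n, k = data.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 subjects and 2 raters")
    if np.any(~np.isfinite(data)):
        raise ValueError("ratings table has missing cells; no imputation is performed")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return AgreementResult(np.nan, np.nan, np.nan, n, k)
    icc = (msr - mse) / denom
    if mse == 0 and msc == 0:  # perfect agreement, CI degenerate
        return AgreementResult(1.0, 1.0, 1.0, n, k)

    # F-based interval with Satterthwaite degrees of freedom
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return AgreementResult(float(icc), np.nan, np.nan, n, k)
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    if v_den == 0:
        return AgreementResult(float(icc), np.nan, np.nan, n, k)
    v = (a * msc + b * mse) ** 2 / v_den
    f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return AgreementResult(float(icc), float(lower), float(upper), n, k)


# ---------------------------------------------------------------------------
# plotting (optional)
# ---------------------------------------------------------------------------

def plot_roc(result: ROCResult, path=None, ax=None):
    """Plot the empirical ROC with the Youden threshold annotated."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot(result.curve["fpr"], result.curve["tpr"], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.plot(1 - result.specificity, result.sensitivity, "o", color="crimson")
    ax.annotate(
        f"{result.threshold:.0f} HU\nJ={result.youden_j:.2f}",
        (1 - result.specificity, result.sensitivity),
        textcoords="offset points",
        xytext=(8, -12),
        fontsize=8,
    )
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {result.auc:.2f} ({result.auc_ci[0]:.2f}-{result.auc_ci[1]:.2f})")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
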