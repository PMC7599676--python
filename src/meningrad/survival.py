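"""Statistical chain: univariate logistic screening, ROC/Youden
dichotomization, Cox proportional hazards, Kaplan–Meier and log-rank, and
cohort summary tables.

Effect sizes are ratio-type estimates (odds ratios from logistic fits,
hazard ratios from Cox fits) with Wald 95% confidence intervals. The AUC
is the tie-corrected Mann–Whitney probability; the Youden threshold is the
observed feature value maximizing J = sensitivity + specificity - 1, ties
broken toward the lower threshold so reports are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from lifelines.utils import restricted_mean_survival_time
from scipy import stats

__all__ = [
    "EffectEstimate",
    "ROCAnalysis",
    "SurvivalCurve",
    "univariate_logistic",
    "roc_analysis",
    "dichotomize",
    "cox_fit",
    "kaplan_meier",
    "log_rank",
    "cohort_summary",
]


@dataclass
class EffectEstimate:
    """A ratio-type association estimate with Wald 95% CI.

    ``degenerate`` marks complete separation / empty cells, where the
    estimate is reported as 0 or ``inf`` without a meaningful CI.
    """

    kind: str  # "odds_ratio" | "hazard_ratio"
    name: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "name": self.name,
            "estimate": self.estimate,
            "ci95": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "n_used": self.n_used,
            "degenerate": self.degenerate,
        }


@dataclass
class ROCAnalysis:
    """AUC with Mann–Whitney p-value and the Youden-index operating point."""

    auc: float
    p_value: float
    threshold: float
    sensitivity_at_threshold: float
    specificity_at_threshold: float
    youden_j: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "p_value": self.p_value,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity_at_threshold,
            "specificity": self.specificity_at_threshold,
            "youden_j": self.youden_j,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


@dataclass
class SurvivalCurve:
    """Product-limit estimate for one group plus its restricted mean."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    restricted_mean: float
    horizon: float
    n: int
    events: int


def _clean(cohort: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return cohort[cols].dropna()


def univariate_logistic(
    cohort: pd.DataFrame, predictor: str, outcome: str = "relapse"
) -> EffectEstimate:
    """Odds ratio for a binary predictor from a logistic fit with intercept.

    For a 2x2 table with all cells positive the ML estimate equals the
    cross-product ratio (a*d)/(b*c). A zero cell (complete separation on
    one side) yields a degenerate estimate of 0 or ``inf`` with the
    ``degenerate`` flag set, mirroring how such associations are reported
    in small-cohort tables.
    """
    df = _clean(cohort, [predictor, outcome])
    x = df[predictor].astype(float).to_numpy()
    y = df[outcome].astype(float).to_numpy()
    if np.unique(x).size < 2:
        raise ValueError(f"no variation in predictor '{predictor}'")
    if set(np.unique(x)) <= {0.0, 1.0}:
        a = int(((x == 1) & (y == 1)).sum())  # exposed, event
        b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum())
        d = int(((x == 0) & (y == 0)).sum())
        if min(a, b, c, d) == 0:
            est = 0.0 if (a == 0 or d == 0) else math.inf
            return EffectEstimate(
                "odds_ratio", predictor, est, math.nan, math.nan, math.nan,
                len(df), degenerate=True,
            )
    model = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    beta = float(model.params[1])
    se = float(model.bse[1])
    return EffectEstimate(
        kind="odds_ratio",
        name=predictor,
        estimate=math.exp(beta),
        ci_low=math.exp(beta - 1.959963984540054 * se),
        ci_high=math.exp(beta + 1.959963984540054 * se),
        p_value=float(model.pvalues[1]),
        n_used=len(df),
    )


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann–Whitney AUC via average ranks."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_analysis(
    cohort: pd.DataFrame, feature: str, outcome: str = "relapse"
) -> ROCAnalysis:
    """ROC of a continuous feature for a binary outcome, with Youden cutoff.

    The positive call is ``feature > threshold``; candidate thresholds are
    the observed feature values. Among thresholds maximizing J the lowest
    is chosen.
    """
    df = _clean(cohort, [feature, outcome])
    scores = df[feature].astype(float).to_numpy()
    labels = df[outcome].astype(int).to_numpy()
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present for ROC analysis")
    auc = _auc_mann_whitney(scores, labels)
    try:
        p = float(
            stats.mannwhitneyu(
                scores[labels == 1], scores[labels == 0], alternative="two-sided"
            ).pvalue
        )
    except ValueError:  # all scores identical
        p = 1.0
    best = None
    for t in np.unique(scores):
        calls = scores > t
        sens = float((calls & (labels == 1)).sum() / n_pos)
        spec = float((~calls & (labels == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(t), sens, spec)
    j, thr, sens, spec = best
    return ROCAnalysis(
        auc=auc,
        p_value=p,
        threshold=thr,
        sensitivity_at_threshold=sens,
        specificity_at_threshold=spec,
        youden_j=j,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def dichotomize(
    cohort: pd.DataFrame, feature: str, threshold: float, new_column: str | None = None
) -> pd.DataFrame:
    """Add a binary ``high_<feature>`` column: feature value > threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out = cohort.copy()
    col = new_column or f"high_{feature}"
    out[col] = out[feature] > threshold
    return out


def cox_fit(
    cohort: pd.DataFrame,
    covariates: list[str],
    time: str = "followup_months",
    event: str = "relapse",
) -> list[EffectEstimate]:
    """Cox proportional-hazards fit (Efron ties), Wald 95% CIs per covariate."""
    df = _clean(cohort, list(covariates) + [time, event]).astype(float)
    if df[event].sum() < 1:
        raise ValueError("no events in cohort; Cox model undefined")
    from lifelines.exceptions import ConvergenceError

    # stock stopping rules leave ~1e-6 error in the estimate, so tighten
    # until the fit agrees with direct partial-likelihood maximization;
    # large effect sizes can make undamped Newton overshoot and overflow,
    # so retry with progressively damped steps before giving up
    attempts = [
        {"precision": 1e-12, "r_precision": 1e-16},
        {"precision": 1e-12, "r_precision": 1e-16, "step_size": 0.5},
        {"precision": 1e-12, "r_precision": 1e-16, "step_size": 0.1},
    ]
    cph = None
    last_err: Exception | None = None
    for fit_options in attempts:
        candidate = CoxPHFitter()
        try:
            candidate.fit(
                df, duration_col=time, event_col=event, fit_options=fit_options
            )
            cph = candidate
            break
        except ConvergenceError as err:
            last_err = err
    if cph is None:
        raise ValueError(f"Cox model did not converge: {last_err}") from last_err
    out = []
    for cov in covariates:
        beta = float(cph.params_[cov])
        se = float(cph.standard_errors_[cov])
        out.append(
            EffectEstimate(
                kind="hazard_ratio",
                name=cov,
                estimate=math.exp(beta),
                ci_low=math.exp(beta - 1.959963984540054 * se),
                ci_high=math.exp(beta + 1.959963984540054 * se),
                p_value=float(cph.summary.loc[cov, "p"]),
                n_used=len(df),
            )
        )
    return out


def kaplan_meier(
    cohort: pd.DataFrame,
    group: str,
    time: str = "followup_months",
    event: str = "relapse",
) -> dict[str, SurvivalCurve]:
    """Product-limit curves per level of ``group``.

    The reported "mean" survival is the restricted mean survival time with
    the horizon at the largest observed time in the cohort, the convention
    of common clinical software when the last observation is censored.
    """
    df = _clean(cohort, [group, time, event])
    horizon = float(df[time].max())
    out = {}
    for level, sub in df.groupby(group):
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time].astype(float), sub[event].astype(bool), label=str(level))
        rmst = float(restricted_mean_survival_time(kmf, t=horizon))
        sf = kmf.survival_function_
        out[str(level)] = SurvivalCurve(
            group=str(level),
            times=sf.index.to_numpy(dtype=float),
            survival=sf.iloc[:, 0].to_numpy(dtype=float),
            restricted_mean=rmst,
            horizon=horizon,
            n=len(sub),
            events=int(sub[event].sum()),
        )
    if not out:
        raise ValueError(f"no groups found for '{group}'")
    return out


def log_rank(
    cohort: pd.DataFrame,
    group: str,
    time: str = "followup_months",
    event: str = "relapse",
) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test between two groups."""
    df = _clean(cohort, [group, time, event])
    levels = df[group].unique()
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, found {len(levels)}")
    g0 = df[df[group] == levels[0]]
    g1 = df[df[group] == levels[1]]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("one group is empty")
    if df[event].sum() < 1:
        raise ValueError("no events in cohort")
    res = _lifelines_logrank(
        g0[time].astype(float),
        g1[time].astype(float),
        event_observed_A=g0[event].astype(bool),
        event_observed_B=g1[event].astype(bool),
    )
    return float(res.test_statistic), float(res.p_value)


def cohort_summary(cohort: pd.DataFrame) -> dict:
    """Demographics/outcome summary: N, mean age (SD), percentages to 1 dp."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    n = len(cohort)

    def pct(count: int) -> float:
        return round(100.0 * count / n, 1)

    loc = cohort.get("localization")
    loc_pct = {}
    for level in ("convexity_falx", "skull_base", "ventricular"):
        loc_pct[level] = pct(int((loc == level).sum())) if loc is not None else 0.0
    simpson = cohort.get("simpson_grade")
    simpson_pct = {}
    for grade in (1, 2, 3, 4):
        simpson_pct[str(grade)] = (
            pct(int((simpson == grade).sum())) if simpson is not None else 0.0
        )
    relapse_n = int(cohort["relapse"].sum()) if "relapse" in cohort else 0
    complete_n = (
        int(cohort["complete_resection"].sum()) if "complete_resection" in cohort else 0
    )
    summary = {
        "n": n,
        "mean_age": round(float(cohort["age"].mean()), 1) if "age" in cohort else None,
        "sd_age": round(float(cohort["age"].std(ddof=1)), 1) if "age" in cohort else None,
        "pct_women": pct(int((cohort["sex"] == "female").sum())) if "sex" in cohort else None,
        "localization_pct": loc_pct,
        "simpson_grade_pct": simpson_pct,
        "pct_complete_resection": pct(complete_n),
        "pct_radiation": pct(int(cohort["postop_radiation"].sum()))
        if "postop_radiation" in cohort
        else None,
        "relapse_n": relapse_n,
        "pct_relapse": pct(relapse_n),
        "mean_followup_months": round(float(cohort["followup_months"].mean()), 1)
        if "followup_months" in cohort
        else None,
    }
    return summary
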