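"""The full screening procedure: univariate screening of semantic flags
and radiomic features, Youden dichotomization of promising features,
multivariate survival modeling of recurrence, and PFS analyses.

The chain is:

1. univariate logistic regression of each semantic flag on relapse;
2. ROC analysis of each continuous radiomic feature;
3. features passing the selection rule (semantic p < 0.05; radiomic
   Mann-Whitney p <= 0.10, a deliberately permissive "trend" rule for a
   screening step) are dichotomized at the Youden threshold and advanced;
4. multivariate Cox model of time-to-recurrence on the advanced features
   (multivariate logistic available as an alternative);
5. PFS associations: univariate Cox per clinical/semantic/radiomic
   covariate, then a multivariate Cox on the significant ones plus
   completeness of resection;
6. Kaplan-Meier curves and a log-rank test for the strongest semantic flag.

All thresholds are derived from the data at hand; an absolute texture
threshold is never transferred between datasets because it depends on the
quantization scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import survival as ss
from .synthetic import SEMANTIC_FLAGS

__all__ = ["ScreeningConfig", "run_screening_procedure", "render_report"]

#: default clinical covariates screened for PFS association
DEFAULT_PFS_COVARIATES = (
    "complete_resection",
    "convexity_falx_location",
    "female_sex",
    "age_over_65",
    "postop_radiation",
)


@dataclass
class ScreeningConfig:
    semantic_alpha: float = 0.05
    roc_p_max: float = 0.10
    pfs_alpha: float = 0.05
    recurrence_model: str = "cox"  # or "logistic"
    time_col: str = "followup_months"
    event_col: str = "relapse"


def _prepare_clinical(cohort: pd.DataFrame) -> pd.DataFrame:
    df = cohort.copy()
    if "localization" in df:
        df["convexity_falx_location"] = df["localization"] == "convexity_falx"
    if "sex" in df:
        df["female_sex"] = df["sex"] == "female"
    if "age" in df:
        df["age_over_65"] = df["age"] > 65
    return df


def run_screening_procedure(
    cohort: pd.DataFrame,
    semantic: list[str] | None = None,
    radiomic: list[str] | None = None,
    config: ScreeningConfig | None = None,
) -> dict:
    """Run the screening chain and return a JSON-serializable report."""
    cfg = config or ScreeningConfig()
    semantic = list(semantic) if semantic is not None else [
        f for f in SEMANTIC_FLAGS if f in cohort.columns
    ]
    radiomic = list(radiomic) if radiomic is not None else [
        c for c in ("cluster_prominence",) if c in cohort.columns
    ]
    df = _prepare_clinical(cohort)
    report: dict = {
        "n": len(df),
        "config": {
            "semantic_alpha": cfg.semantic_alpha,
            "roc_p_max": cfg.roc_p_max,
            "pfs_alpha": cfg.pfs_alpha,
            "recurrence_model": cfg.recurrence_model,
        },
        "cohort_summary": ss.cohort_summary(df),
    }

    # 1. univariate logistic screening of semantic flags
    uni = {}
    for flag in semantic:
        try:
            uni[flag] = ss.univariate_logistic(df, flag, cfg.event_col).to_dict()
        except ValueError as err:
            uni[flag] = {"error": str(err)}
    report["univariate_semantic"] = uni

    # 2. ROC per radiomic feature + 3. Youden dichotomization of trends
    rocs, advanced = {}, []
    for feat in radiomic:
        roc = ss.roc_analysis(df, feat, cfg.event_col)
        rocs[feat] = roc.to_dict()
        if roc.p_value <= cfg.roc_p_max:
            df = ss.dichotomize(df, feat, roc.threshold)
            high = f"high_{feat}"
            advanced.append(high)
            uni_high = ss.univariate_logistic(df, high, cfg.event_col)
            report.setdefault("univariate_dichotomized", {})[high] = uni_high.to_dict()
    report["roc_radiomic"] = rocs

    selected_semantic = [
        flag
        for flag, res in uni.items()
        if "p_value" in res
        and (
            (not res.get("degenerate") and res["p_value"] < cfg.semantic_alpha)
        )
    ]
    report["advanced_features"] = selected_semantic + advanced

    # 4. multivariate recurrence model on the advanced features
    multivariate = {}
    if report["advanced_features"]:
        try:
            if cfg.recurrence_model == "logistic":
                import statsmodels.api as sm

                sub = df[
                    report["advanced_features"] + [cfg.event_col]
                ].dropna().astype(float)
                model = sm.Logit(
                    sub[cfg.event_col],
                    sm.add_constant(sub[report["advanced_features"]]),
                ).fit(disp=0)
                for cov in report["advanced_features"]:
                    beta, se = float(model.params[cov]), float(model.bse[cov])
                    multivariate[cov] = {
                        "kind": "odds_ratio",
                        "estimate": float(np.exp(beta)),
                        "ci95": [float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))],
                        "p_value": float(model.pvalues[cov]),
                    }
            else:
                for est in ss.cox_fit(
                    df, report["advanced_features"], cfg.time_col, cfg.event_col
                ):
                    multivariate[est.name] = est.to_dict()
        except Exception as err:  # noqa: BLE001 - collected, not fatal
            multivariate = {"error": str(err)}
    report["multivariate_recurrence"] = multivariate

    # 5. PFS associations: univariate Cox per covariate
    pfs_covs = [c for c in DEFAULT_PFS_COVARIATES if c in df.columns]
    pfs_covs += [c for c in report["advanced_features"] if c not in pfs_covs]
    pfs_uni = {}
    for cov in pfs_covs:
        try:
            est = ss.cox_fit(df, [cov], cfg.time_col, cfg.event_col)[0]
            pfs_uni[cov] = est.to_dict()
        except Exception as err:  # noqa: BLE001
            pfs_uni[cov] = {"error": str(err)}
    report["pfs_univariate"] = pfs_uni

    significant = [
        c
        for c, res in pfs_uni.items()
        if "p_value" in res and res["p_value"] < cfg.pfs_alpha
    ]
    pfs_multi_covs = list(dict.fromkeys(
        (["complete_resection"] if "complete_resection" in df.columns else [])
        + significant
    ))
    pfs_multi = {}
    if pfs_multi_covs:
        try:
            for est in ss.cox_fit(df, pfs_multi_covs, cfg.time_col, cfg.event_col):
                pfs_multi[est.name] = est.to_dict()
        except Exception as err:  # noqa: BLE001
            pfs_multi = {"error": str(err)}
    report["pfs_multivariate"] = pfs_multi

    # 6. KM + log-rank for the strongest semantic flag
    candidates = [
        (res["p_value"], flag)
        for flag, res in uni.items()
        if "p_value" in res and not res.get("degenerate") and np.isfinite(res["p_value"])
    ]
    if candidates:
        _, top_flag = min(candidates)
        report["top_semantic_feature"] = top_flag
        try:
            curves = ss.kaplan_meier(df, top_flag, cfg.time_col, cfg.event_col)
            chi2, p = ss.log_rank(df, top_flag, cfg.time_col, cfg.event_col)
            report["kaplan_meier"] = {
                "group": top_flag,
                "restricted_mean_months": {
                    g: round(c.restricted_mean, 1) for g, c in curves.items()
                },
                "horizon_months": next(iter(curves.values())).horizon,
                "log_rank_chi2": chi2,
                "log_rank_p": p,
            }
        except ValueError as err:
            report["kaplan_meier"] = {"error": str(err)}
    return report


def render_report(report: dict) -> str:
    """Human-readable text rendering of a screening report."""
    lines = [f"Screening report (n = {report['n']})", "=" * 40]
    cs = report["cohort_summary"]
    lines.append(
        f"Cohort: mean age {cs['mean_age']} (SD {cs['sd_age']}), "
        f"{cs['pct_women']}% women, relapse {cs['relapse_n']} ({cs['pct_relapse']}%)"
    )
    lines.append("\nUnivariate semantic screening (OR, 95% CI, p):")
    for flag, res in report["univariate_semantic"].items():
        if "error" in res:
            lines.append(f"  {flag}: {res['error']}")
        elif res.get("degenerate"):
            lines.append(f"  {flag}: OR {res['estimate']:g} (degenerate separation)")
        else:
            lo, hi = res["ci95"]
            lines.append(
                f"  {flag}: OR {res['estimate']:.2f} ({lo:.2f}-{hi:.2f}), p={res['p_value']:.3g}"
            )
    lines.append("\nROC of radiomic features:")
    for feat, res in report["roc_radiomic"].items():
        lines.append(
            f"  {feat}: AUC {res['auc']:.3f} (p={res['p_value']:.3g}), "
            f"Youden threshold {res['threshold']:.4g} "
            f"(sens {res['sensitivity']:.2f}, spec {res['specificity']:.2f})"
        )
    lines.append(f"\nAdvanced to multivariate: {report['advanced_features'] or 'none'}")
    if report["multivariate_recurrence"]:
        lines.append("Multivariate recurrence model:")
        for cov, res in report["multivariate_recurrence"].items():
            if cov == "error":
                lines.append(f"  error: {res}")
                continue
            lo, hi = res["ci95"]
            label = "HR" if res.get("kind") == "hazard_ratio" else "OR"
            lines.append(
                f"  {cov}: {label} {res['estimate']:.2f} ({lo:.2f}-{hi:.2f}), "
                f"p={res['p_value']:.3g}"
            )
    if report.get("pfs_univariate"):
        lines.append("\nPFS univariate (Cox HR):")
        for cov, res in report["pfs_univariate"].items():
            if "error" in res:
                lines.append(f"  {cov}: {res['error']}")
            else:
                lo, hi = res["ci95"]
                lines.append(
                    f"  {cov}: HR {res['estimate']:.2f} ({lo:.2f}-{hi:.2f}), "
                    f"p={res['p_value']:.3g}"
                )
    if report.get("pfs_multivariate"):
        lines.append("PFS multivariate (Cox HR):")
        for cov, res in report["pfs_multivariate"].items():
            if cov == "error":
                lines.append(f"  error: {res}")
                continue
            lo, hi = res["ci95"]
            lines.append(
                f"  {cov}: HR {res['estimate']:.2f} ({lo:.2f}-{hi:.2f}), "
                f"p={res['p_value']:.3g}"
            )
    km = report.get("kaplan_meier")
    if km and "error" not in km:
        means = ", ".join(f"{g}: {m}" for g, m in km["restricted_mean_months"].items())
        lines.append(
            f"\nKaplan-Meier by {km['group']}: restricted mean PFS (months) {means}; "
            f"log-rank chi2={km['log_rank_chi2']:.2f}, p={km['log_rank_p']:.3g}"
        )
    return "\n".join(lines) + "\n"
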