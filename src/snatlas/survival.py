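"""Outcome association: median-split Kaplan-Meier with log-rank, univariate
and stepwise multivariable Cox models, C-index and nested-model comparison.

Endpoint conventions: disease-free survival (DFS) is analyzed in stage
I-III samples, overall survival (OS) in stage I-IV.  Median splits assign
samples exactly at the median to the low group.  Continuous covariates are
standardized per SD before Cox fitting, so hazard ratios read "per SD".
All tests are two-sided; batched p-values are Benjamini-Hochberg adjusted.
Model fitting leans on lifelines; this module owns the subsetting rules,
the stepwise procedure and the nested-model likelihood-ratio comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .io import BulkCohort

logger = logging.getLogger(__name__)

__all__ = ["SurvivalResult", "endpoint_frame", "km_logrank_median",
           "cox_univariate", "cox_stepwise", "compare_nested"]

ENDPOINT_STAGES = {"dfs": ("I", "II", "III"), "os": ("I", "II", "III", "IV")}


@dataclass
class SurvivalResult:
    """Per-covariate hazard ratios with model-level summaries."""

    table: pd.DataFrame            # index covariate: hr, ci_lo, ci_hi, p[, p_adj]
    endpoint: str
    n: int
    events: int
    concordance: float | None = None
    log_likelihood: float | None = None
    notes: list[str] = field(default_factory=list)


def endpoint_frame(cohort: BulkCohort, endpoint: str,
                   covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Duration/event frame for one endpoint with the stage-subsetting rule.

    Returns columns ``duration``/``event`` plus any covariate columns,
    restricted to stage I-III (DFS) or I-IV (OS) samples with non-missing
    time and event.
    """
    endpoint = endpoint.lower()
    if endpoint not in ENDPOINT_STAGES:
        raise ValueError("endpoint must be 'dfs' or 'os'")
    clin = cohort.clinical
    stages = ENDPOINT_STAGES[endpoint]
    keep = clin["stage"].astype(str).isin(stages)
    df = pd.DataFrame({
        "duration": clin[f"time_{endpoint}"],
        "event": clin[f"event_{endpoint}"],
    }, index=clin.index)
    if covariates is not None:
        for col in covariates.columns:
            df[col] = covariates.loc[df.index, col]
    df = df[keep].dropna(subset=["duration", "event"])
    df["event"] = df["event"].astype(int)
    return df


def km_logrank_median(cohort: BulkCohort, score: pd.Series,
                      endpoint: str) -> dict:
    """Median-split Kaplan-Meier curves and log-rank test for one score.

    High group: score > median; low group: score <= median (ties to low).
    Returns fitted KaplanMeierFitter objects, the log-rank p, and group
    sizes/events.
    """
    df = endpoint_frame(cohort, endpoint,
                        covariates=score.to_frame("score"))
    df = df.dropna(subset=["score"])
    med = float(df["score"].median())
    high = df["score"] > med
    groups = {"high": df[high], "low": df[~high]}
    fitters = {}
    for name, g in groups.items():
        if len(g) and g["event"].sum() == 0:
            logger.warning("km_logrank_median: group %r has zero events", name)
        kmf = KaplanMeierFitter(label=name)
        kmf.fit(g["duration"], g["event"])
        fitters[name] = kmf
    res = logrank_test(groups["high"]["duration"], groups["low"]["duration"],
                       groups["high"]["event"], groups["low"]["event"])
    return {
        "curves": fitters,
        "p": float(res.p_value),
        "statistic": float(res.test_statistic),
        "n": {k: len(g) for k, g in groups.items()},
        "events": {k: int(g["event"].sum()) for k, g in groups.items()},
        "median": med,
    }


def _standardize(df: pd.DataFrame, cols) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        if pd.api.types.is_numeric_dtype(out[c]) and out[c].nunique() > 2:
            sd = out[c].std(ddof=1)
            if sd > 0:
                out[c] = (out[c] - out[c].mean()) / sd
    return out


def _fit_cox(df: pd.DataFrame, covariates: list[str],
             allow_ridge_fallback: bool = False) -> CoxPHFitter:
    cph = CoxPHFitter()
    try:
        cph.fit(df[["duration", "event", *covariates]],
                duration_col="duration", event_col="event")
    except Exception:
        if not allow_ridge_fallback:
            raise
        logger.warning("Cox fit singular (collinear covariates?); "
                       "refitting with a tiny ridge penalty")
        cph = CoxPHFitter(penalizer=1e-6)
        cph.fit(df[["duration", "event", *covariates]],
                duration_col="duration", event_col="event")
    return cph


def cox_univariate(cohort: BulkCohort, covariates: pd.DataFrame,
                   endpoint: str) -> SurvivalResult:
    """One Cox model per covariate, BH-adjusted over the batch.

    Continuous covariates are standardized to unit SD (hazard ratios per
    SD); binary covariates are left as coded.
    """
    df_all = endpoint_frame(cohort, endpoint, covariates=covariates)
    rows = []
    notes = []
    for cov in covariates.columns:
        df = df_all.dropna(subset=[cov])
        df = _standardize(df, [cov])
        try:
            cph = _fit_cox(df, [cov])
        except Exception as exc:            # noqa: BLE001 - surfaced as note
            notes.append(f"{cov}: fit failed ({exc})")
            continue
        s = cph.summary.loc[cov]
        rows.append((cov, float(s["exp(coef)"]),
                     float(s["exp(coef) lower 95%"]),
                     float(s["exp(coef) upper 95%"]), float(s["p"])))
    table = pd.DataFrame(rows, columns=["covariate", "hr", "ci_lo", "ci_hi",
                                        "p"]).set_index("covariate")
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return SurvivalResult(table=table, endpoint=endpoint, n=len(df_all),
                          events=int(df_all["event"].sum()), notes=notes)


def cox_stepwise(cohort: BulkCohort, covariates: pd.DataFrame, endpoint: str,
                 alpha: float = 0.05) -> SurvivalResult:
    """Backward-elimination multivariable Cox model.

    Starts from the full model on the candidate covariates (intended to be
    the univariately significant ones) and repeatedly removes the covariate
    with the largest Wald p >= alpha until all remaining p < alpha.  The
    elimination trace is logged and returned in ``notes``.
    """
    if covariates.shape[1] == 0:
        raise ValueError("no significant candidates for the stepwise model")
    df = endpoint_frame(cohort, endpoint, covariates=covariates)
    df = df.dropna()
    df = _standardize(df, covariates.columns)
    remaining = list(covariates.columns)
    notes = []
    while remaining:
        try:
            cph = _fit_cox(df, remaining)
        except Exception as exc:            # noqa: BLE001
            bad = remaining[-1]
            notes.append(f"dropped {bad}: non-convergence ({exc})")
            logger.warning("cox_stepwise: dropped %s (non-convergence)", bad)
            remaining = [c for c in remaining if c != bad]
            continue
        pvals = cph.summary.loc[remaining, "p"]
        worst = pvals.idxmax()
        if pvals[worst] < alpha:
            break
        remaining = [c for c in remaining if c != worst]
        notes.append(f"eliminated {worst} (p={pvals[worst]:.3g})")
        logger.info("cox_stepwise: eliminated %s (p=%.3g)", worst,
                    pvals[worst])
    if not remaining:
        return SurvivalResult(table=pd.DataFrame(), endpoint=endpoint,
                              n=len(df), events=int(df["event"].sum()),
                              notes=notes + ["no covariate retained"])
    s = cph.summary.loc[remaining]
    table = pd.DataFrame({
        "hr": s["exp(coef)"], "ci_lo": s["exp(coef) lower 95%"],
        "ci_hi": s["exp(coef) upper 95%"], "p": s["p"],
    })
    return SurvivalResult(table=table, endpoint=endpoint, n=len(df),
                          events=int(df["event"].sum()),
                          concordance=float(cph.concordance_index_),
                          log_likelihood=float(cph.log_likelihood_),
                          notes=notes)


def compare_nested(cohort: BulkCohort, base_covariates: pd.DataFrame,
                   added_covariates: pd.DataFrame, endpoint: str) -> dict:
    """Compare base vs base+added Cox models on the same samples.

    Reports Harrell's C for both models, the likelihood-ratio statistic
    2*(ll_full - ll_base) with df = number of added covariates, and its
    chi-squared p-value.
    """
    cov = pd.concat([base_covariates, added_covariates], axis=1)
    if cov.columns.duplicated().any():
        raise ValueError("base and added covariates overlap")
    df = endpoint_frame(cohort, endpoint, covariates=cov).dropna()
    df = _standardize(df, cov.columns)
    base_cols = list(base_covariates.columns)
    added_cols = list(added_covariates.columns)
    cph_base = _fit_cox(df, base_cols, allow_ridge_fallback=True)
    cph_full = _fit_cox(df, base_cols + added_cols, allow_ridge_fallback=True)
    lrt = 2.0 * (cph_full.log_likelihood_ - cph_base.log_likelihood_)
    dof = len(added_cols)
    p = float(scipy.stats.chi2.sf(max(lrt, 0.0), dof))
    if lrt < 1e-8:
        logger.warning("compare_nested: added covariates contribute no "
                       "likelihood (collinear with base?)")
    return {
        "c_index_base": float(cph_base.concordance_index_),
        "c_index_full": float(cph_full.concordance_index_),
        "delta_c_index": float(cph_full.concordance_index_
                               - cph_base.concordance_index_),
        "lrt_statistic": float(lrt),
        "lrt_df": dof,
        "lrt_p": p,
        "n": len(df),
        "events": int(df["event"].sum()),
    }
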