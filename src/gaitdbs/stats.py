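"""Statistical models linking gait-phase neural features to walking performance.

Person-specific analysis: per (subject, recording site or coherence pair,
band), ordinary least squares of WPI on the four gait-phase features (plus
a hemisphere indicator for bilateral subjects), with Benjamini-Hochberg
adjustment across the four phase p-values of each model.

Group analysis: per feature, a linear mixed model
``WPI ~ feature + hemisphere + (1 | subject)`` with REML estimates for
reporting, an ML likelihood-ratio test against the null excluding the
feature, a hemisphere-interaction AIC check, backward model selection and
residual diagnostics.  Wald t statistics use residual degrees of freedom
(n_obs − n_fixed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .types import PHASES

log = logging.getLogger(__name__)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted p(i) are scaled by m/i, a reverse cumulative minimum enforces
    monotonicity, and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# person-specific models


def fit_subject_phase_models(
    feature_table: pd.DataFrame, min_obs: int = 8
) -> pd.DataFrame:
    """OLS of WPI on the four phase features, per subject/site/band.

    ``feature_table`` is long format with columns subject_id, hemisphere,
    site_or_pair, band, phase, trial_id, value, wpi.  Observations are
    (trial, hemisphere) pairs with complete four-phase features.  Returns
    one row per (subject, site_or_pair, band, phase) with the estimate,
    SE, model R², raw and BH-adjusted p (family = the four phases of the
    model).  Rank-deficient models are flagged and dropped.
    """
    rows = []
    for (subj, site, band), grp in feature_table.groupby(
        ["subject_id", "site_or_pair", "band"], sort=True
    ):
        wide = grp.pivot_table(
            index=["trial_id", "hemisphere", "wpi"],
            columns="phase",
            values="value",
        ).reset_index()
        wide = wide.dropna(subset=[p for p in PHASES if p in wide.columns])
        if len(wide) < min_obs or any(p not in wide.columns for p in PHASES):
            continue
        X = wide[list(PHASES)].to_numpy(dtype=float)
        cols = list(PHASES)
        if wide["hemisphere"].nunique() > 1:
            X = np.column_stack(
                [X, (wide["hemisphere"] == "right").to_numpy(dtype=float)]
            )
            cols.append("hemisphere")
        Xc = sm.add_constant(X)
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            log.warning(
                "rank-deficient design for %s/%s/%s; model dropped", subj, site, band
            )
            rows.extend(
                {
                    "subject_id": subj,
                    "site_or_pair": site,
                    "band": band,
                    "phase": p,
                    "estimate": np.nan,
                    "se": np.nan,
                    "r2": np.nan,
                    "p": np.nan,
                    "p_adj": np.nan,
                    "flag": "rank_deficient",
                }
                for p in PHASES
            )
            continue
        fit = sm.OLS(wide["wpi"].to_numpy(dtype=float), Xc).fit()
        phase_p = fit.pvalues[1 : 1 + len(PHASES)]
        p_adj = bh_adjust(phase_p)
        for i, phase in enumerate(PHASES):
            rows.append(
                {
                    "subject_id": subj,
                    "site_or_pair": site,
                    "band": band,
                    "phase": phase,
                    "estimate": float(fit.params[1 + i]),
                    "se": float(fit.bse[1 + i]),
                    "r2": float(fit.rsquared),
                    "p": float(phase_p[i]),
                    "p_adj": float(p_adj[i]),
                    "flag": "",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group-level mixed models


@dataclass
class GroupModelResult:
    feature: str
    estimate: float
    se: float
    t_value: float
    df: int
    p_wald: float
    lrt_chi2: float
    lrt_p: float
    aic_ml: float
    fallback_ols: bool = False
    p_adj: float | None = None


def _aic_ml(res) -> float:
    k = len(res.params) + 1  # fixed effects + RE variance(s) + residual scale
    return float(-2.0 * res.llf + 2.0 * k)


def _fit_mixed(formula: str, data: pd.DataFrame, reml: bool):
    """Random-intercept fit with optimizer retries (best-likelihood wins)."""
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["subject_id"])
        for method in ("lbfgs", "powell", "cg"):
            try:
                res = model.fit(reml=reml, method=method)
            except Exception:
                continue
            if not np.isfinite(res.llf):
                continue
            if best is None or res.llf > best.llf + 1e-9:
                best = res
            if res.converged and method == "lbfgs":
                break
    if best is None:
        raise RuntimeError(f"mixed model failed to fit: {formula}")
    return best


def fit_group_feature_model(
    data: pd.DataFrame, feature_col: str = "value"
) -> GroupModelResult:
    """Mixed model WPI ~ feature + hemisphere + (1 | subject).

    ``data`` needs columns wpi, subject_id, hemisphere and the feature
    column.  REML estimates are reported; the likelihood-ratio test
    refits by maximum likelihood against the null model without the
    feature.  A singular random-effect fit falls back to OLS with a flag.
    """
    data = data.dropna(subset=[feature_col, "wpi"]).copy()
    if data["subject_id"].nunique() < 3 or len(data) < 20:
        raise ValueError("need >= 3 subjects and >= 20 observations")
    data["feat"] = data[feature_col].astype(float)
    hemi_term = " + C(hemisphere)" if data["hemisphere"].nunique() > 1 else ""
    formula = "wpi ~ feat" + hemi_term
    fallback = False
    try:
        res = _fit_mixed(formula, data, reml=True)
        est, se = float(res.params["feat"]), float(res.bse["feat"])
        singular = not np.isfinite(se) or se <= 0
    except Exception:
        singular = True
    if singular:
        log.warning("singular random-effect fit; falling back to OLS")
        fallback = True
        res = smf.ols(formula, data).fit()
        est, se = float(res.params["feat"]), float(res.bse["feat"])
    n = len(data)
    k_fe = 2 + (1 if hemi_term else 0)  # intercept + feature (+ hemisphere)
    df = n - k_fe
    t_val = est / se
    p_wald = float(2.0 * sps.t.sf(np.abs(t_val), df))
    # ML likelihood-ratio test against the null excluding the feature
    if fallback:
        full = smf.ols(formula, data).fit()
        null = smf.ols("wpi ~ 1" + hemi_term, data).fit()
        aic = float(full.aic)
    else:
        full = _fit_mixed(formula, data, reml=False)
        null = _fit_mixed("wpi ~ 1" + hemi_term, data, reml=False)
        aic = _aic_ml(full)
    if np.isfinite(full.llf) and np.isfinite(null.llf):
        chi2 = max(2.0 * (full.llf - null.llf), 0.0)
        lrt_p = float(sps.chi2.sf(chi2, 1))
    else:  # ML refit failed to produce a likelihood; LRT unavailable
        chi2, lrt_p = np.nan, np.nan
    return GroupModelResult(
        feature=feature_col,
        estimate=est,
        se=se,
        t_value=float(t_val),
        df=int(df),
        p_wald=p_wald,
        lrt_chi2=float(chi2),
        lrt_p=lrt_p,
        aic_ml=aic,
        fallback_ols=fallback,
    )


def hemisphere_interaction_check(
    data: pd.DataFrame, feature_col: str = "value"
) -> tuple[float, float]:
    """ΔAIC and Wald p for a feature × hemisphere interaction.

    ΔAIC = AIC(interaction model) − AIC(main-effects model), both fitted
    by maximum likelihood; a positive value means the interaction does
    not improve fit.  Requires bilateral data.
    """
    data = data.dropna(subset=[feature_col, "wpi"]).copy()
    if data["hemisphere"].nunique() < 2:
        raise ValueError("hemisphere interaction requires bilateral data")
    data["feat"] = data[feature_col].astype(float)
    main = _fit_mixed("wpi ~ feat + C(hemisphere)", data, reml=False)
    inter = _fit_mixed("wpi ~ feat * C(hemisphere)", data, reml=False)
    delta_aic = _aic_ml(inter) - _aic_ml(main)
    inter_name = [
        n for n in inter.params.index if ":" in n and "feat" in n
    ]
    p_inter = float(inter.pvalues[inter_name[0]]) if inter_name else np.nan
    return float(delta_aic), p_inter


def backward_select(
    data: pd.DataFrame, feature_cols: list[str], alpha: float = 0.05
) -> list[str]:
    """Backward elimination of fixed effects by ML likelihood-ratio tests.

    Starting from the model containing all features (plus hemisphere where
    bilateral), the feature with the largest LRT p-value above ``alpha``
    is removed until all remaining features are significant.  May return
    an empty list (intercept-only model).
    """
    data = data.dropna(subset=feature_cols + ["wpi"]).copy()
    hemi_term = " + C(hemisphere)" if data["hemisphere"].nunique() > 1 else ""
    retained = list(feature_cols)
    while retained:
        full_formula = "wpi ~ " + " + ".join([f"Q('{c}')" for c in retained]) + hemi_term
        full = _fit_mixed(full_formula, data, reml=False)
        worst, worst_p = None, -1.0
        for c in retained:
            rest = [r for r in retained if r != c]
            null_formula = (
                "wpi ~ " + (" + ".join([f"Q('{r}')" for r in rest]) if rest else "1")
                + hemi_term
            )
            null = _fit_mixed(null_formula, data, reml=False)
            chi2 = max(2.0 * (full.llf - null.llf), 0.0)
            p = float(sps.chi2.sf(chi2, 1))
            if p > worst_p:
                worst, worst_p = c, p
        if worst_p > alpha:
            retained.remove(worst)
        else:
            break
    return retained


@dataclass
class DiagnosticsReport:
    shapiro_p: float
    skewness: float
    kurtosis: float  # Pearson (non-excess) convention
    n: int
    normality_ok: bool | None = None
    skewness_ok: bool | None = None
    kurtosis_ok: bool | None = None


def residual_diagnostics(
    residuals: np.ndarray,
    alpha: float = 0.05,
    skew_threshold: float = 1.0,
    kurtosis_threshold: float = 4.0,
) -> DiagnosticsReport:
    """Shapiro-Wilk normality test plus skewness/kurtosis of residuals.

    Kurtosis is reported in the Pearson (non-excess) convention, so a
    normal distribution gives 3.  With fewer than 8 residuals only the
    descriptive statistics are returned.
    """
    r = np.asarray(residuals, dtype=float)
    r = r[np.isfinite(r)]
    skew = float(sps.skew(r)) if r.size > 2 else np.nan
    kurt = float(sps.kurtosis(r, fisher=False)) if r.size > 3 else np.nan
    if r.size < 8:
        return DiagnosticsReport(np.nan, skew, kurt, int(r.size))
    p = float(sps.shapiro(r).pvalue)
    return DiagnosticsReport(
        shapiro_p=p,
        skewness=skew,
        kurtosis=kurt,
        n=int(r.size),
        normality_ok=p > alpha,
        skewness_ok=abs(skew) < skew_threshold,
        kurtosis_ok=kurt < kurtosis_threshold,
    )


# ---------------------------------------------------------------------------
# feedback-rank agreement


@dataclass
class FeedbackModelResult:
    slope: float
    se: float
    p: float
    random_intercepts: dict[str, float]
    fallback_ols: bool = False


def feedback_rank_model(feedback: pd.DataFrame) -> FeedbackModelResult:
    """Mixed model feedback_rank ~ wpi_rank + (1 | subject).

    ``feedback`` needs columns feedback_rank, wpi_rank, subject_id and at
    least two visits with two trials each (rank variation); constant ranks
    are a failure.
    """
    data = feedback.copy()
    if data["wpi_rank"].nunique() < 2 or data["feedback_rank"].nunique() < 2:
        raise ValueError("constant ranks; model undefined")
    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(
                "feedback_rank ~ wpi_rank", data, groups=data["subject_id"]
            ).fit(reml=True, method=["lbfgs", "powell"])
        slope, se = float(res.params["wpi_rank"]), float(res.bse["wpi_rank"])
        if not np.isfinite(se) or se <= 0:
            raise RuntimeError("singular fit")
        re = {k: float(v.iloc[0]) for k, v in res.random_effects.items()}
    except Exception:
        fallback = True
        res = smf.ols("feedback_rank ~ wpi_rank", data).fit()
        slope, se = float(res.params["wpi_rank"]), float(res.bse["wpi_rank"])
        re = {}
    df = len(data) - 2
    p = float(2.0 * sps.t.sf(abs(slope / se), df))
    return FeedbackModelResult(slope, se, p, re, fallback)
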