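"""Walking Performance Index (WPI).

The WPI combines four trial-level gait metrics — stride velocity (SV),
arm swing amplitude (AS), step-length variability (VSL) and step-time
variability (VST) — after per-visit min-max normalization of each metric
to [0, 1]:

    WPI = ( SV_norm + AS_norm + (1 - VSL_norm) + (1 - VST_norm) ) / 4

SV and AS are oriented so that higher is better; the variability terms
enter inverted so that greater variability lowers the index.  Within each
visit the WPI is additionally normalized to the trial recorded at the
clinically optimized stimulation setting, so a baseline-normalized WPI of
1.2 reads "20% better than the clinical setting at that visit".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

log = logging.getLogger(__name__)

#: metric column -> (component name, higher value is better?)
METRICS = {
    "stride_velocity": ("sv_norm", True),
    "arm_swing_amplitude": ("as_norm", True),
    "step_length_cv": ("vsl_norm", False),
    "step_time_cv": ("vst_norm", False),
}
COMPONENT_COLS = ["sv_norm", "as_norm", "vsl_norm", "vst_norm"]


def normalize_metrics(visit_metrics: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each metric to [0, 1] across one visit's trials.

    The variability components keep their natural orientation (higher =
    more variable); the WPI formula applies the ``1 - x`` flip.  A metric
    that is constant across the visit carries no ranking information and is
    set to the uninformative midpoint 0.5 for every trial.
    """
    if len(visit_metrics) < 2:
        raise ValueError("need >= 2 trials per visit to normalize")
    out = pd.DataFrame(index=visit_metrics.index)
    for col, (comp, _) in METRICS.items():
        x = visit_metrics[col].to_numpy(dtype=float)
        lo, hi = np.min(x), np.max(x)
        if hi - lo < 1e-12:
            log.info("metric %s constant across visit; component set to 0.5", col)
            out[comp] = 0.5
        else:
            out[comp] = (x - lo) / (hi - lo)
    return out


def compute_wpi(components) -> np.ndarray | float:
    """Equal-weight composite of the four normalized components.

    Accepts a DataFrame with the component columns, a dict, or a length-4
    sequence ordered (sv_norm, as_norm, vsl_norm, vst_norm).
    """
    if isinstance(components, pd.DataFrame):
        arr = components[COMPONENT_COLS].to_numpy(dtype=float)
    elif isinstance(components, dict):
        arr = np.array([[components[c] for c in COMPONENT_COLS]], dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(components, dtype=float))
    if arr.shape[1] != 4:
        raise ValueError("expected four components")
    if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
        raise ValueError("components must lie in [0, 1]")
    sv, asw, vsl, vst = arr.T
    w = (sv + asw + (1.0 - vsl) + (1.0 - vst)) / 4.0
    return float(w[0]) if w.size == 1 else w


def baseline_normalize(
    scores: pd.DataFrame, clinical_trial_id: str
) -> pd.DataFrame:
    """Divide each trial's raw WPI by the clinical-setting trial's WPI."""
    if clinical_trial_id not in set(scores["trial_id"]):
        raise ValueError(f"clinical trial {clinical_trial_id!r} not in visit")
    ref = float(
        scores.loc[scores["trial_id"] == clinical_trial_id, "wpi_raw"].iloc[0]
    )
    if ref <= 0:
        raise ValueError("clinical trial has non-positive WPI; visit unusable")
    out = scores.copy()
    out["wpi_baseline_normalized"] = out["wpi_raw"] / ref
    return out


def rank_trials(scores: pd.DataFrame, column: str = "wpi_raw") -> pd.DataFrame:
    """Rank trials within a visit; rank 1 = highest WPI.

    Ties are broken stably by trial order and logged.
    """
    x = scores[column].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 trials to rank")
    if len(np.unique(x)) < len(x):
        log.info("tied WPI values; ties broken by trial order")
    order = np.argsort(-x, kind="stable")
    ranks = np.empty(len(x), dtype=int)
    ranks[order] = np.arange(1, len(x) + 1)
    out = scores.copy()
    out["rank"] = ranks
    return out


def score_visit(
    visit_metrics: pd.DataFrame, clinical_trial_id: str
) -> pd.DataFrame:
    """Components + raw WPI + baseline normalization + ranks for one visit.

    ``visit_metrics`` needs a ``trial_id`` column and the four metric
    columns.
    """
    comps = normalize_metrics(visit_metrics)
    scores = visit_metrics[["trial_id"]].copy()
    scores[COMPONENT_COLS] = comps[COMPONENT_COLS].to_numpy()
    scores["wpi_raw"] = compute_wpi(comps)
    scores = baseline_normalize(scores, clinical_trial_id)
    return rank_trials(scores)


# ---------------------------------------------------------------------------
# validity analyses


@dataclass
class VIFReport:
    vif: dict[str, float]
    infinite: list[str]


def vif(metric_table: pd.DataFrame) -> VIFReport:
    """Variance inflation factors across the four gait metrics.

    VIF_j = 1 / (1 - R²_j) with R²_j from regressing metric j (with an
    intercept) on the other three over all trials.  Exactly collinear
    metrics are reported as infinite and flagged.
    """
    cols = list(METRICS)
    if len(metric_table) < 5:
        raise ValueError("need >= 5 trials for VIF")
    X = metric_table[cols].to_numpy(dtype=float)
    out: dict[str, float] = {}
    infinite: list[str] = []
    for j, col in enumerate(cols):
        y = X[:, j]
        others = np.column_stack(
            [np.ones(len(y))] + [X[:, k] for k in range(4) if k != j]
        )
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = np.sum((y - y.mean()) ** 2)
        r2 = 0.0 if tss == 0 else 1.0 - np.sum(resid**2) / tss
        if r2 > 1 - 1e-10:
            out[col] = np.inf
            infinite.append(col)
        else:
            out[col] = float(1.0 / (1.0 - r2))
    return VIFReport(out, infinite)


def sensitivity(
    visit_metrics: pd.DataFrame, clinical_trial_id: str, delta: float = 0.10
) -> pd.DataFrame:
    """Perturb each metric by ±delta and report the WPI shift.

    For each metric and each sign the whole column is rescaled by
    (1 ± delta), components are re-normalized and the WPI recomputed; the
    report gives the mean signed and mean absolute change in raw WPI per
    trial, one row per (metric, sign).
    """
    if delta <= -1:
        raise ValueError("delta must be > -1")
    base = score_visit(visit_metrics, clinical_trial_id)
    rows = []
    for col in METRICS:
        for sign in (+1, -1):
            perturbed = visit_metrics.copy()
            perturbed[col] = perturbed[col] * (1.0 + sign * delta)
            new = score_visit(perturbed, clinical_trial_id)
            d = new["wpi_raw"].to_numpy() - base["wpi_raw"].to_numpy()
            rows.append(
                {
                    "metric": col,
                    "sign": "+" if sign > 0 else "-",
                    "mean_delta_wpi": float(np.mean(d)),
                    "mean_abs_delta_wpi": float(np.mean(np.abs(d))),
                }
            )
    return pd.DataFrame(rows)


def compare_conditions(
    strides_a: pd.DataFrame,
    strides_b: pd.DataFrame,
    min_strides: int = 10,
) -> pd.DataFrame:
    """Per-metric percent change between two walking conditions.

    Inputs are stride-level metric tables (columns: stride_velocity,
    arm_swing_amplitude, step_time, step_length).  Strides are paired by
    their order index, truncating to the shorter sequence, and compared
    with a Wilcoxon signed-rank test; with fewer than ``min_strides``
    strides in either condition only descriptive output is produced.
    """
    cols = [c for c in strides_a.columns if c in strides_b.columns]
    n = min(len(strides_a), len(strides_b))
    if n < min(len(strides_a), len(strides_b)) or len(strides_a) != len(strides_b):
        log.info("unequal stride counts; truncating to %d pairs", n)
    rows = []
    run_test = len(strides_a) >= min_strides and len(strides_b) >= min_strides
    for col in cols:
        a = strides_a[col].to_numpy(dtype=float)[:n]
        b = strides_b[col].to_numpy(dtype=float)[:n]
        ma, mb = np.mean(a), np.mean(b)
        pct = 100.0 * (mb - ma) / ma if ma != 0 else np.nan
        p = np.nan
        if run_test:
            d = b - a
            if np.allclose(d, 0):
                p = 1.0
            else:
                p = float(wilcoxon(a, b).pvalue)
        rows.append(
            {
                "metric": col,
                "mean_a": float(ma),
                "mean_b": float(mb),
                "percent_change": float(pct),
                "n_pairs": n,
                "wilcoxon_p": p,
            }
        )
    return pd.DataFrame(rows)
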