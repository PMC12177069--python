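"""Gait event detection, cycle segmentation, turn exclusion and metrics.

Events are detected primarily from force-sensitive-resistor (FSR)
footswitches; a goniometer-based fallback covers trials where footswitch
signal quality is inadequate (e.g. toe walking).  Cycles are anchored at
reference-side heel strikes and partitioned into the four canonical phases
DS1/CLS/DS2/ILS; turning cycles are flagged by cumulative heading change
and excluded from all performance metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.stats import kruskal

from .types import GaitCycle, GaitEvent, Signal

log = logging.getLogger(__name__)

#: footswitch activation threshold as a fraction of the channel's trial max
FSR_THRESHOLD_FRAC = 0.10
#: minimum time between successive events on one channel
FSR_DEBOUNCE_S = 0.05
#: cumulative heading change (degrees) within a cycle that marks a turn
TURN_THRESHOLD_DEG = 45.0


@dataclass
class StrideMetrics:
    """Spatiotemporal metrics for one gait cycle.

    ``step_times`` / ``step_lengths`` hold the two half-stride steps
    (reference heel strike -> contralateral -> next reference); the scalar
    fields are their means.
    """

    stride_index: int
    cycle: GaitCycle
    stride_length: float
    stride_velocity: float
    step_times: np.ndarray
    step_lengths: np.ndarray
    arm_swing_amplitude: float

    @property
    def step_time(self) -> float:
        return float(np.mean(self.step_times))

    @property
    def step_length(self) -> float:
        return float(np.mean(self.step_lengths))


@dataclass
class TrialMetrics:
    """Trial-level aggregate over valid non-turn strides."""

    stride_velocity: float
    arm_swing_amplitude: float
    step_length_cv: float
    step_time_cv: float
    n_valid_strides: int
    usable: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "stride_velocity": self.stride_velocity,
            "arm_swing_amplitude": self.arm_swing_amplitude,
            "step_length_cv": self.step_length_cv,
            "step_time_cv": self.step_time_cv,
        }


# ---------------------------------------------------------------------------
# event detection


def _threshold_crossings(x: np.ndarray, rate: float, thr: float):
    """(upward, downward) crossing times of ``thr`` with debouncing."""
    above = x > thr
    d = np.diff(above.astype(int))
    up = np.flatnonzero(d == 1) + 1
    down = np.flatnonzero(d == -1) + 1
    min_gap = int(FSR_DEBOUNCE_S * rate)

    def _debounce(idx):
        keep = []
        last = -10 * min_gap
        for i in idx:
            if i - last >= min_gap:
                keep.append(i)
                last = i
        return np.asarray(keep, dtype=int)

    return _debounce(up) / rate, _debounce(down) / rate


def detect_events_fsr(
    streams: dict[str, Signal],
) -> tuple[list[GaitEvent], dict[str, bool]]:
    """Detect heel strikes and toe offs from footswitch channels.

    Heel strike = upward threshold crossing of the heel channel; toe off =
    downward crossing of the union of the forefoot channels (i.e. the
    last-active forefoot sensor).  Returns the time-sorted event list and a
    per-side quality flag dict (``True`` = signal unusable, fallback
    needed).
    """
    events: list[GaitEvent] = []
    flags: dict[str, bool] = {}
    for side, hs_lab, to_lab in (("l", "LHS", "LTO"), ("r", "RHS", "RTO")):
        heel = streams.get(f"fsr_{side}_heel")
        fore = [
            streams[k]
            for k in (f"fsr_{side}_met1", f"fsr_{side}_met5", f"fsr_{side}_toe")
            if k in streams
        ]
        if heel is None or not fore:
            raise ValueError(f"missing footswitch channels for side {side!r}")
        rate = heel.rate_hz
        hmax = np.max(np.abs(heel.data))
        flat = hmax < 1e-6 or np.ptp(heel.data) < 0.05 * max(hmax, 1e-6)
        flags[side] = bool(flat)
        if flat:
            log.warning("footswitch heel channel flat/saturated for side %s", side)
            continue
        up, _ = _threshold_crossings(heel.data, rate, FSR_THRESHOLD_FRAC * hmax)
        events.extend(GaitEvent(t, hs_lab) for t in up)
        # union of forefoot activity; its deactivation is the toe off
        union = np.zeros(fore[0].n, dtype=bool)
        for s in fore:
            smax = np.max(np.abs(s.data))
            if smax > 1e-6:
                union |= s.data > FSR_THRESHOLD_FRAC * smax
        _, down = _threshold_crossings(union.astype(float), rate, 0.5)
        events.extend(GaitEvent(t, to_lab) for t in down)
    events.sort(key=lambda e: e.time_s)
    return events, flags


def detect_events_goniometer(
    streams: dict[str, Signal], smooth_s: float = 0.03
) -> tuple[list[GaitEvent], dict[str, bool]]:
    """Fallback event detection from ankle goniometer angles.

    Heel strike is taken at the local dorsiflexion maximum that precedes
    loading; toe off at the peak plantarflexion (most negative) angular
    velocity.  Both are kinematic surrogates and are approximate.
    """
    events: list[GaitEvent] = []
    flags: dict[str, bool] = {}
    for side, hs_lab, to_lab in (("l", "LHS", "LTO"), ("r", "RHS", "RTO")):
        sig = streams.get(f"ankle_angle_{side}")
        if sig is None:
            raise ValueError(f"missing ankle angle for side {side!r}")
        rate = sig.rate_hz
        x = gaussian_filter1d(sig.data, sigma=max(smooth_s * rate, 1.0))
        rng_x = np.ptp(x)
        flags[side] = bool(rng_x < 1.0)  # < 1 degree of motion: unusable
        if flags[side]:
            log.warning("goniometer channel constant for side %s", side)
            continue
        dist = int(0.4 * rate)
        peaks, _ = find_peaks(x, prominence=0.3 * rng_x, distance=dist)
        events.extend(GaitEvent(p / rate, hs_lab) for p in peaks)
        v = np.gradient(x) * rate
        troughs, _ = find_peaks(-v, prominence=0.3 * np.ptp(v), distance=dist)
        events.extend(GaitEvent(p / rate, to_lab) for p in troughs)
    events.sort(key=lambda e: e.time_s)
    return events, flags


# ---------------------------------------------------------------------------
# cycles


def build_cycles(
    events: list[GaitEvent], reference_side: str = "left"
) -> list[GaitCycle]:
    """Assemble complete reference-side-anchored gait cycles.

    For a left reference the expected pattern is LHS, RTO, RHS, LTO, LHS;
    for a right reference the labels are mirrored.  Runs that violate the
    pattern (missing or out-of-order events) are skipped and logged;
    neighbouring complete cycles are unaffected.
    """
    if reference_side == "left":
        order = ("LHS", "RTO", "RHS", "LTO", "LHS")
    elif reference_side == "right":
        order = ("RHS", "LTO", "LHS", "RTO", "RHS")
    else:
        raise ValueError("reference_side must be 'left' or 'right'")
    ev = sorted(events, key=lambda e: e.time_s)
    anchors = [i for i, e in enumerate(ev) if e.label == order[0]]
    cycles: list[GaitCycle] = []
    for a, b in zip(anchors[:-1], anchors[1:]):
        segment = ev[a : b + 1]
        labels = [e.label for e in segment]
        if labels != list(order):
            log.info(
                "skipping malformed cycle at t=%.3f (pattern %s)",
                ev[a].time_s,
                labels,
            )
            continue
        times = [e.time_s for e in segment]
        if not all(t1 < t2 for t1, t2 in zip(times[:-1], times[1:])):
            log.info("skipping non-monotone cycle at t=%.3f", ev[a].time_s)
            continue
        cycles.append(
            GaitCycle(*times, reference_side=reference_side)
        )
    return cycles


def exclude_turns(
    cycles: list[GaitCycle],
    heading: Signal | None,
    threshold_deg: float = TURN_THRESHOLD_DEG,
) -> list[GaitCycle]:
    """Flag turning cycles and return the straight-walking subset.

    A cycle is a turn when the cumulative unsigned heading change within
    [lhs, lhs_next) exceeds ``threshold_deg``.  Flags are set on the input
    cycles in place; the returned list contains only non-turn cycles and is
    a pure filter (metric values of retained strides are untouched).
    """
    if heading is None:
        log.warning("no heading stream; keeping all cycles")
        return list(cycles)
    t = heading.times()
    for c in cycles:
        m = (t >= c.lhs) & (t < c.lhs_next)
        h = heading.data[m]
        change = float(np.sum(np.abs(np.diff(h)))) if h.size >= 2 else 0.0
        c.is_turn = change > threshold_deg
    return [c for c in cycles if not c.is_turn]


# ---------------------------------------------------------------------------
# metrics


def _pos_at(sig_x: Signal, sig_y: Signal, t: float) -> np.ndarray:
    tx = sig_x.times()
    return np.array(
        [np.interp(t, tx, sig_x.data), np.interp(t, sig_y.times(), sig_y.data)]
    )


def compute_stride_metrics(
    cycles: list[GaitCycle], kinematics: dict[str, Signal]
) -> list[StrideMetrics]:
    """Per-stride spatiotemporal metrics from pelvis and wrist streams.

    Stride length is the horizontal pelvis displacement over the cycle;
    step length is the pelvis displacement between alternating heel
    strikes (a proxy for the foot-to-foot distance on this walker); arm
    swing amplitude is the mean over both arms of the within-cycle range
    of anteroposterior wrist excursion.
    """
    px, py = kinematics["pelvis_x"], kinematics["pelvis_y"]
    wl, wr = kinematics["wrist_ap_l"], kinematics["wrist_ap_r"]
    t_end = min(s.duration_s for s in (px, py, wl, wr))
    out: list[StrideMetrics] = []
    for i, c in enumerate(cycles):
        if c.lhs_next > t_end + 1e-9:
            log.info("stride %d extends past stream end; dropped", i)
            continue
        p0 = _pos_at(px, py, c.lhs)
        pm = _pos_at(px, py, c.rhs)
        p1 = _pos_at(px, py, c.lhs_next)
        stride_length = float(np.linalg.norm(p1 - p0))
        step_lengths = np.array(
            [np.linalg.norm(pm - p0), np.linalg.norm(p1 - pm)]
        )
        step_times = np.array([c.rhs - c.lhs, c.lhs_next - c.rhs])
        swings = []
        for w in (wl, wr):
            tw = w.times()
            m = (tw >= c.lhs) & (tw < c.lhs_next)
            if m.sum() < 4:
                swings.append(np.nan)
            else:
                swings.append(float(np.ptp(w.data[m])))
        out.append(
            StrideMetrics(
                stride_index=i,
                cycle=c,
                stride_length=stride_length,
                stride_velocity=stride_length / c.stride_time_s,
                step_times=step_times,
                step_lengths=step_lengths,
                arm_swing_amplitude=float(np.nanmean(swings)),
            )
        )
    return out


def _cv(x: np.ndarray) -> float:
    """Coefficient of variation with sample SD (ddof=1)."""
    x = np.asarray(x, dtype=float)
    m = np.mean(x)
    if x.size < 2 or m == 0:
        return 0.0
    return float(np.std(x, ddof=1) / m)


def aggregate_trial_metrics(
    stride_metrics: list[StrideMetrics], min_strides: int = 5
) -> TrialMetrics:
    """Aggregate stride metrics to the trial level.

    Variability metrics are the coefficient of variation (sample SD over
    mean) across all individual steps of the retained strides.
    """
    n = len(stride_metrics)
    if n < min_strides:
        log.warning("only %d valid strides (< %d); trial unusable", n, min_strides)
        return TrialMetrics(np.nan, np.nan, np.nan, np.nan, n, usable=False)
    sv = np.array([s.stride_velocity for s in stride_metrics])
    asw = np.array([s.arm_swing_amplitude for s in stride_metrics])
    steps_t = np.concatenate([s.step_times for s in stride_metrics])
    steps_l = np.concatenate([s.step_lengths for s in stride_metrics])
    return TrialMetrics(
        stride_velocity=float(np.mean(sv)),
        arm_swing_amplitude=float(np.nanmean(asw)),
        step_length_cv=_cv(steps_l),
        step_time_cv=_cv(steps_t),
        n_valid_strides=n,
    )


# ---------------------------------------------------------------------------
# stride-order consistency


@dataclass
class StrideOrderResult:
    summary: pd.DataFrame
    statistic: float | None = None
    p_value: float | None = None
    order_groups: dict[int, np.ndarray] = field(default_factory=dict)


def stride_order_consistency(cycles: list[GaitCycle]) -> StrideOrderResult:
    """Test whether stride time depends on within-bout stride order.

    Bouts are maximal runs of consecutive non-turn cycles (walking segments
    between turns).  Stride times are grouped by their 1-based order within
    the bout and compared with a Kruskal-Wallis test; with fewer than two
    order groups containing >= 2 strides only the summary is returned.
    """
    bouts: list[list[GaitCycle]] = []
    cur: list[GaitCycle] = []
    for c in cycles:
        if c.is_turn:
            if cur:
                bouts.append(cur)
            cur = []
        else:
            cur.append(c)
    if cur:
        bouts.append(cur)
    groups: dict[int, list[float]] = {}
    for bout in bouts:
        for j, c in enumerate(bout, start=1):
            groups.setdefault(j, []).append(c.stride_time_s)
    order_groups = {k: np.asarray(v) for k, v in sorted(groups.items())}
    summary = pd.DataFrame(
        {
            "order": list(order_groups),
            "n": [len(v) for v in order_groups.values()],
            "mean_stride_time_s": [float(np.mean(v)) for v in order_groups.values()],
            "sd_stride_time_s": [
                float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
                for v in order_groups.values()
            ],
        }
    )
    testable = [v for v in order_groups.values() if len(v) >= 2]
    if len(testable) < 2:
        return StrideOrderResult(summary, order_groups=order_groups)
    stat, p = kruskal(*testable)
    return StrideOrderResult(summary, float(stat), float(p), order_groups)
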