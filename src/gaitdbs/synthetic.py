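"""Synthetic cohort generator with known ground truth.

Real recordings of pallidal/cortical field potentials during overground
walking are not publicly deposited, so every stage of the pipeline is
exercised on simulated cohorts whose generative parameters are known.  A
subject is given a smooth unimodal "response surface" mapping stimulation
settings (amplitude mA, frequency Hz, pulse width us) to a true walking
performance level; each trial realizes that level as

* gait event times with stride-to-stride jitter that shrinks as
  performance rises,
* footswitch / goniometer / pelvis / wrist / chest-accelerometer streams
  whose derived metrics invert the walking-performance-index components,
* per-hemisphere neural channels (one pallidal + two cortical bipolar
  channels at 500 Hz) built from 1/f background plus gait-phase-gated
  band oscillations whose power tracks performance with configurable
  slopes (in z-units per baseline-normalized WPI unit),
* a device accelerometer at 64 Hz on a clock offset from the wearables.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` so identical (config, seed) pairs give
identical cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .types import PHASES, Signal, StimSetting

log = logging.getLogger(__name__)

#: band name -> carrier frequency (Hz) used for the synthetic oscillations
BAND_CARRIERS = {"delta": 3.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0}

#: conversion between the requested biomarker slope (z-units per WPI unit)
#: and the relative band-power modulation the generator applies, per gait
#: phase.  The z-scale of the extracted features depends on the sample-level
#: power fluctuations of the synthetic oscillations, and short phases (the
#: double-support intervals, ~12% of the cycle) are attenuated by the time
#: resolution of the wavelet transform more than the long swing phases.
#: These constants were calibrated once on the default generator so that a
#: requested slope is reproduced by the full extraction pipeline.
REL_POWER_PER_Z = {"DS1": 7.9, "CLS": 6.0, "DS2": 7.9, "ILS": 6.0}

#: log-SD of the lognormal trial-to-trial band-power gain.  Band power in
#: real recordings fluctuates substantially from bout to bout independent of
#: stimulation; this term sets the between-trial feature variance (and hence
#: the effect-size regime of the biomarker regressions).
BAND_POWER_TRIAL_LOGSD = 1.15

# metric target maps: linear in the true walking performance level w
_METRIC_MAPS = {
    "stride_velocity": (0.55, 0.85),  # m/s at w=0, slope per w-unit
    "arm_swing_amplitude": (0.40, 0.95),  # m
    "step_length_cv": (0.130, -0.100),  # unitless CV, decreasing in w
    "step_time_cv": (0.100, -0.080),
}


def metric_targets(w: float) -> dict[str, float]:
    """Noise-free trial-metric targets for true performance level ``w``."""
    out = {}
    for name, (a, b) in _METRIC_MAPS.items():
        out[name] = max(a + b * w, 0.005)
    return out


@dataclass
class GroundTruthSurface:
    """Gaussian-bump response surface over a subject's safe parameter box."""

    optimum: np.ndarray  # (3,) mA, Hz, us
    peak_wpi: float
    baseline_wpi: float
    axis_widths: np.ndarray  # (3,) per-parameter scale
    observation_noise_sd: float
    safe_box: np.ndarray  # (3, 2) lo/hi per axis

    def __post_init__(self) -> None:
        self.optimum = np.asarray(self.optimum, dtype=float)
        self.axis_widths = np.asarray(self.axis_widths, dtype=float)
        self.safe_box = np.asarray(self.safe_box, dtype=float)
        if not (self.peak_wpi > self.baseline_wpi):
            raise ValueError("peak_wpi must exceed baseline_wpi")
        if np.any(self.axis_widths <= 0):
            raise ValueError("axis widths must be positive")
        if self.observation_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        inside = (self.optimum >= self.safe_box[:, 0]) & (
            self.optimum <= self.safe_box[:, 1]
        )
        if not inside.all():
            raise ValueError("optimum must lie inside the safe box")

    def value(self, setting: StimSetting | Sequence[float]) -> float:
        """Noise-free surface value at ``setting`` (inside the safe box)."""
        x = setting.as_array() if isinstance(setting, StimSetting) else np.asarray(
            setting, dtype=float
        )
        if np.any(x < self.safe_box[:, 0] - 1e-9) or np.any(
            x > self.safe_box[:, 1] + 1e-9
        ):
            raise ValueError(f"setting {x} outside safe box")
        r2 = np.sum(((x - self.optimum) / self.axis_widths) ** 2)
        return float(
            self.baseline_wpi + (self.peak_wpi - self.baseline_wpi) * np.exp(-0.5 * r2)
        )


def true_wpi(surface: GroundTruthSurface, setting: StimSetting) -> float:
    """Deterministic expected walking performance at ``setting``."""
    return surface.value(setting)


@dataclass
class SubjectConfig:
    """Per-subject simulation parameters.

    ``biomarker_slopes`` maps (site_or_pair, band, phase) keys to slopes in
    z-units per baseline-normalized WPI unit; the default imposes the
    pallidal-beta decline during the double-support and ipsilateral-swing
    phases that the group analysis targets.
    """

    subject_id: str
    hemispheres: int = 2
    safe_range: np.ndarray = field(
        default_factory=lambda: np.array([[2.8, 5.0], [60.0, 180.0], [60.0, 90.0]])
    )
    clinical_setting: StimSetting | None = None
    stride_period_s: float = 1.1
    biomarker_slopes: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: {
            ("GP", "beta", "DS2"): -0.22,
            ("GP", "beta", "ILS"): -0.22,
        }
    )
    fs_neural: float = 500.0
    fs_device_accel: float = 64.0
    fs_wearable: float = 100.0
    clock_offset_s: float = 0.0
    turn_every_n_strides: int = 5

    def __post_init__(self) -> None:
        self.safe_range = np.asarray(self.safe_range, dtype=float)
        if self.fs_neural != 500.0:
            raise ValueError("neural sampling rate is fixed at 500 Hz")
        if self.fs_device_accel != 64.0:
            raise ValueError("device accelerometer rate is fixed at 64 Hz")
        if self.stride_period_s <= 0:
            raise ValueError("stride period must be positive")
        if self.hemispheres not in (1, 2):
            raise ValueError("hemispheres must be 1 or 2")
        if self.clinical_setting is None:
            mid = self.safe_range.mean(axis=1)
            self.clinical_setting = StimSetting(*mid, clinical=True)
        x = self.clinical_setting.as_array()
        if np.any(x < self.safe_range[:, 0]) or np.any(x > self.safe_range[:, 1]):
            raise ValueError("clinical setting outside safe range")

    @property
    def hemisphere_names(self) -> tuple[str, ...]:
        return ("left",) if self.hemispheres == 1 else ("left", "right")


def build_surface(subject: SubjectConfig, seed: int) -> GroundTruthSurface:
    """Draw a seeded ground-truth response surface for one subject.

    The optimum is placed in the central 60% of the safe box, the per-axis
    widths span 25-60% of each axis, and the peak/baseline levels are drawn
    so that the clinical setting sits well below the peak.
    """
    box = np.asarray(subject.safe_range, dtype=float)
    span = box[:, 1] - box[:, 0]
    if np.any(span <= 0):
        raise ValueError("degenerate safe box (zero-width axis)")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _stable_hash(subject.subject_id)])
    )
    optimum = box[:, 0] + span * rng.uniform(0.2, 0.8, size=3)
    widths = span * rng.uniform(0.25, 0.6, size=3)
    baseline = rng.uniform(0.30, 0.45)
    peak = baseline + rng.uniform(0.35, 0.50)
    noise_sd = 0.04
    return GroundTruthSurface(
        optimum=optimum,
        peak_wpi=float(peak),
        baseline_wpi=float(baseline),
        axis_widths=widths,
        observation_noise_sd=noise_sd,
        safe_box=box,
    )


def _stable_hash(s: str) -> int:
    # deterministic across processes (hash() is salted)
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


@dataclass
class TrialGroundTruth:
    """Everything the generator knows about one trial."""

    lhs: np.ndarray
    rto: np.ndarray
    rhs: np.ndarray
    lto: np.ndarray
    turn_cycle_indices: np.ndarray
    true_wpi: float
    wpi_used: float  # true wpi + trial-level observation noise
    wpi_ref: float  # clinical-setting true wpi (baseline for normalization)
    neural_covariate: float  # performance scale driving biomarker modulation
    metric_targets: dict[str, float]
    stride_period_s: float
    artifact_intervals: list[tuple[float, float, str, str]] = field(
        default_factory=list
    )  # (start_s, end_s, kind, channel)

    def left_cycles(self) -> list[tuple[float, float, float, float, float]]:
        """(lhs, rto, rhs, lto, lhs_next) tuples for complete left cycles."""
        out = []
        n = len(self.lhs) - 1
        for k in range(n):
            out.append(
                (self.lhs[k], self.rto[k], self.rhs[k], self.lto[k], self.lhs[k + 1])
            )
        return out


@dataclass
class TrialRecording:
    """One simulated walking trial."""

    trial_id: str
    subject_id: str
    visit_id: str
    setting: StimSetting
    kinematics: dict[str, Signal]
    neural: dict[str, Signal]  # keys "left/GP", "right/ctxA", ...
    device_accel: Signal
    ground_truth: TrialGroundTruth
    seed: int

    @property
    def duration_s(self) -> float:
        return self.kinematics["chest_accel"].duration_s


# ---------------------------------------------------------------------------
# trial simulation


def _simulate_events(
    n_strides: int,
    period: float,
    step_cv: float,
    rng: np.random.Generator,
    t_start: float = 1.0,
):
    """Event times for n_strides complete left AND right cycles.

    Step-time jitter is split evenly between whole-stride and within-stride
    components so the sample CV of step times matches ``step_cv``.
    """
    sd = step_cv / np.sqrt(2.0)
    n = n_strides
    periods = period * (1.0 + sd * rng.standard_normal(n + 1))
    periods = np.clip(periods, 0.4 * period, 1.6 * period)
    lhs = t_start + np.concatenate([[0.0], np.cumsum(periods)])  # n+2 heel strikes
    lhs = lhs[: n + 1]
    # right heel strike mid-stride with its own jitter
    half = periods[: n + 1] / 2.0 * (1.0 + sd * rng.standard_normal(n + 1))
    rhs = lhs + np.clip(half, 0.25 * period, 0.75 * period)
    rto = lhs + 0.12 * periods[: n + 1]
    lto = rhs + 0.12 * periods[: n + 1]
    return lhs, rto, rhs, lto, periods[: n + 1]


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1] if n > 1 else 1.0
    spec = spec / np.sqrt(f)
    x = np.fft.irfft(spec, n=n)
    s = x.std()
    return x / s if s > 0 else x


def _phase_gates(
    t: np.ndarray, gt_lhs, gt_rto, gt_rhs, gt_lto
) -> dict[str, np.ndarray]:
    """Boolean per-sample gate for each gait phase (left-referenced cycles)."""
    gates = {p: np.zeros(t.shape, dtype=bool) for p in PHASES}
    n = len(gt_lhs) - 1
    for k in range(n):
        bounds = {
            "DS1": (gt_lhs[k], gt_rto[k]),
            "CLS": (gt_rto[k], gt_rhs[k]),
            "DS2": (gt_rhs[k], gt_lto[k]),
            "ILS": (gt_lto[k], gt_lhs[k + 1]),
        }
        for p, (a, b) in bounds.items():
            gates[p] |= (t >= a) & (t < b)
    return gates


def _band_component(
    t: np.ndarray,
    fs: float,
    fc: float,
    amp: float,
    env: np.ndarray,
    rng: np.random.Generator,
    am_rate_hz: float = 10.0,
) -> np.ndarray:
    """Narrowband oscillation: wandering-phase carrier with stochastic AM.

    The multiplicative amplitude modulation (drawn on a coarse grid and
    interpolated) makes sample-level band power fluctuate the way
    physiological narrowband activity does.
    """
    dphi = 2 * np.pi * fc / fs + 0.05 * rng.standard_normal(t.size)
    phase = np.cumsum(dphi)
    n_c = int(t.size / fs * am_rate_hz) + 2
    coarse = rng.standard_normal(n_c)
    am = 1.0 + 0.5 * np.interp(
        np.arange(t.size) * (am_rate_hz / fs), np.arange(n_c), coarse
    )
    am = np.clip(am, 0.1, None)
    return amp * env * am * np.sin(phase)


def simulate_trial(
    subject: SubjectConfig,
    surface: GroundTruthSurface,
    setting: StimSetting,
    n_strides: int,
    seed: int,
    metric_noise_sd: float = 0.03,
    sites: Sequence[str] | None = None,
    wpi_used: float | None = None,
    neural_wpi_covariate: float | None = None,
) -> TrialRecording:
    """Simulate one walking trial at ``setting``.

    ``n_strides`` is the number of complete gait cycles per reference side
    (a "step" is half a stride, so a 200-step bout is ``n_strides=100``).
    ``metric_noise_sd`` is the relative noise applied to each per-stride
    metric realization on top of the trial-level observation noise.
    ``sites`` restricts which neural channels are synthesized (default all
    three per hemisphere).

    ``wpi_used`` overrides the trial-level realized performance (true
    surface value plus observation noise); ``neural_wpi_covariate``
    overrides the covariate driving the biomarker power modulation.  The
    cohort generator supplies the latter on the per-visit
    baseline-normalized scale the index itself is defined on, so imposed
    slopes are recovered on the scale the analysis regresses on.
    """
    if n_strides < 4:
        raise ValueError("n_strides must be >= 4 to form cycles")
    w_true = surface.value(setting)
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF])
    rngs = [np.random.default_rng(s) for s in ss.spawn(8)]
    r_ev, r_kin, r_neu, r_wpi = rngs[0], rngs[1], rngs[2], rngs[3]

    sites = sites or ("GP", "ctxA", "ctxB")
    w = (
        float(wpi_used)
        if wpi_used is not None
        else w_true + surface.observation_noise_sd * r_wpi.standard_normal()
    )
    targets = metric_targets(w)
    period = subject.stride_period_s * (1.15 - 0.25 * np.clip(w, 0.0, 1.2))

    lhs, rto, rhs, lto, periods = _simulate_events(
        n_strides, period, targets["step_time_cv"], r_ev
    )
    duration = float(lto[-1] + 1.0)
    n_cycles = len(lhs) - 1

    # turn cycles: one every turn_every_n_strides, alternating direction
    turn_idx = np.arange(
        subject.turn_every_n_strides - 1, n_cycles, subject.turn_every_n_strides
    )

    w_ref = surface.value(subject.clinical_setting)
    covariate = (
        float(neural_wpi_covariate)
        if neural_wpi_covariate is not None
        else float(w) / w_ref
    )
    gt = TrialGroundTruth(
        lhs=lhs,
        rto=rto,
        rhs=rhs,
        lto=lto,
        turn_cycle_indices=turn_idx,
        true_wpi=w_true,
        wpi_used=float(w),
        wpi_ref=w_ref,
        neural_covariate=covariate,
        metric_targets=targets,
        stride_period_s=float(period),
    )

    kin = _simulate_kinematics(
        subject, gt, targets, duration, metric_noise_sd, r_kin
    )
    neural = _simulate_neural(subject, gt, duration, r_neu, sites)
    device = _simulate_device_accel(subject, gt, duration, rngs[4])

    return TrialRecording(
        trial_id="",
        subject_id=subject.subject_id,
        visit_id="",
        setting=setting,
        kinematics=kin,
        neural=neural,
        device_accel=device,
        ground_truth=gt,
        seed=int(seed),
    )


def _simulate_kinematics(
    subject: SubjectConfig,
    gt: TrialGroundTruth,
    targets: dict[str, float],
    duration: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> dict[str, Signal]:
    fs = subject.fs_wearable
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    lhs, rto, rhs, lto = gt.lhs, gt.rto, gt.rhs, gt.lto
    n_cycles = len(lhs) - 1
    turn_set = set(int(i) for i in gt.turn_cycle_indices)

    # --- pelvis: per-step displacements along the current heading ----------
    sv = targets["stride_velocity"]
    mean_step = sv * gt.stride_period_s / 2.0
    # anchor events: alternate LHS_k, RHS_k, LHS_{k+1}, ...
    anchor_t = [0.0]
    pos = [np.zeros(2)]
    heading = 0.0
    heading_t = [0.0]
    heading_v = [0.0]
    turn_sign = 1.0
    for k in range(n_cycles):
        is_turn = k in turn_set
        d1 = mean_step * (1.0 + targets["step_length_cv"] * rng.standard_normal())
        d2 = mean_step * (1.0 + targets["step_length_cv"] * rng.standard_normal())
        if is_turn:
            d1 *= 0.4
            d2 *= 0.4
            h_mid = heading + turn_sign * 90.0
            h_end = heading + turn_sign * 180.0
            turn_sign = -turn_sign
        else:
            h_mid = h_end = heading
        for d, h, tt in ((d1, h_mid, rhs[k]), (d2, h_end, lhs[k + 1])):
            u = np.array([np.cos(np.deg2rad(h)), np.sin(np.deg2rad(h))])
            pos.append(pos[-1] + max(d, 0.0) * u)
            anchor_t.append(tt)
        heading = h_end
        heading_t.append(lhs[k + 1])
        heading_v.append(heading)
    anchor_t = np.asarray(anchor_t)
    pos = np.asarray(pos)
    pelvis_x = np.interp(t, anchor_t, pos[:, 0])
    pelvis_y = np.interp(t, anchor_t, pos[:, 1])
    heading_sig = np.interp(t, heading_t, heading_v)

    # --- wrist anteroposterior positions (relative to pelvis) --------------
    stride_phase = np.interp(t, lhs, np.arange(len(lhs)), left=0, right=len(lhs) - 1)
    amp = targets["arm_swing_amplitude"] * (
        1.0 + noise_sd * rng.standard_normal()
    )
    wrist_l = 0.5 * amp * np.sin(2 * np.pi * stride_phase)
    wrist_r = -0.5 * amp * np.sin(2 * np.pi * stride_phase)
    wnoise = 0.002
    wrist_l = wrist_l + wnoise * rng.standard_normal(n)
    wrist_r = wrist_r + wnoise * rng.standard_normal(n)

    # --- footswitches -------------------------------------------------------
    def _stance_pulse(on: np.ndarray, off: np.ndarray) -> np.ndarray:
        x = np.zeros(n)
        for a, b in zip(on, off):
            x[(t >= a) & (t < b)] = 1.0
        return x

    # left foot: stance LHS_k .. LTO_k ; right foot: stance RHS_k .. RTO_{k+1}
    fsr = {}
    l_heel_off = lhs + 0.65 * (lto - lhs)
    fsr["fsr_l_heel"] = _stance_pulse(lhs, l_heel_off)
    for name, lag in (("fsr_l_met1", 0.06), ("fsr_l_met5", 0.08), ("fsr_l_toe", 0.10)):
        fsr[name] = _stance_pulse(lhs + lag * gt.stride_period_s, lto)
    r_on = rhs
    r_off = np.append(rto[1:], min(rhs[-1] + 0.5 * gt.stride_period_s, duration))
    r_heel_off = r_on + 0.65 * (r_off - r_on)
    fsr["fsr_r_heel"] = _stance_pulse(r_on, r_heel_off)
    for name, lag in (("fsr_r_met1", 0.06), ("fsr_r_met5", 0.08), ("fsr_r_toe", 0.10)):
        fsr[name] = _stance_pulse(r_on + lag * gt.stride_period_s, r_off)
    for k in fsr:
        fsr[k] = fsr[k] + 0.01 * rng.standard_normal(n)

    # --- goniometer ankle angles -------------------------------------------
    def _angle(hs_times: np.ndarray, to_times: np.ndarray) -> np.ndarray:
        ang = np.zeros(n)
        s_hs, s_to = 0.04, 0.06
        for a in hs_times:
            ang += 12.0 * np.exp(-0.5 * ((t - a) / s_hs) ** 2)
        for b in to_times:
            # steepest plantarflexion (most negative velocity) at b
            ang += -18.0 * np.exp(-0.5 * ((t - (b + s_to)) / s_to) ** 2)
        return ang + 0.2 * rng.standard_normal(n)

    ankle_l = _angle(lhs, lto)
    ankle_r = _angle(rhs, rto)

    # --- chest acceleration: impulses at every heel strike ------------------
    chest = 0.08 * rng.standard_normal(n)
    s_imp = 0.03
    for a in np.sort(np.concatenate([lhs, rhs])):
        a_amp = 2.0 + 0.2 * rng.standard_normal()
        chest += a_amp * np.exp(-0.5 * ((t - a) / s_imp) ** 2)

    out = {
        "pelvis_x": pelvis_x,
        "pelvis_y": pelvis_y,
        "heading_deg": heading_sig,
        "wrist_ap_l": wrist_l,
        "wrist_ap_r": wrist_r,
        "ankle_angle_l": ankle_l,
        "ankle_angle_r": ankle_r,
        "chest_accel": chest,
        **fsr,
    }
    return {k: Signal(v, fs, 0.0, k) for k, v in out.items()}


def _simulate_neural(
    subject: SubjectConfig,
    gt: TrialGroundTruth,
    duration: float,
    rng: np.random.Generator,
    sites: Sequence[str] = ("GP", "ctxA", "ctxB"),
) -> dict[str, Signal]:
    fs = subject.fs_neural
    off = subject.clock_offset_s
    n = int(round((duration + abs(off)) * fs))
    t = np.arange(n) / fs  # device-local time
    # device sample k occurs at common (wearable) time k/fs + offset
    gates = _phase_gates(t + off, gt.lhs, gt.rto, gt.rhs, gt.lto)
    w_hat = gt.neural_covariate  # baseline-normalized performance scale

    base_amp = {"GP": {"beta": 0.7}, "ctxA": {"beta": 0.45}, "ctxB": {"beta": 0.45}}
    default_amp = 0.35

    out: dict[str, Signal] = {}
    for hemi in subject.hemisphere_names:
        # shared pallidal beta source for cortico-pallidal coherence
        shared = {}
        for site in sites:
            x = _pink_noise(n, rng)
            for band, fc in BAND_CARRIERS.items():
                amp = base_amp.get(site, {}).get(band, default_amp)
                # trial-level physiological power fluctuation
                amp = amp * np.exp(
                    0.5 * BAND_POWER_TRIAL_LOGSD * rng.standard_normal()
                )
                env = np.ones(n)
                for phase in PHASES:
                    slope = subject.biomarker_slopes.get((site, band, phase), 0.0)
                    if slope != 0.0:
                        # log-linear power modulation: never degenerate, and
                        # symmetric in relative terms around the baseline
                        gain = np.exp(
                            slope * REL_POWER_PER_Z[phase] * (w_hat - 1.0)
                        )
                        env = np.where(gates[phase], env * np.sqrt(gain), env)
                env = gaussian_filter1d(env, sigma=fs * 0.02)
                comp = _band_component(t, fs, fc, amp, env, rng)
                if band == "beta" and site == "GP":
                    shared["beta"] = comp / max(amp, 1e-12)
                if band == "beta" and site in ("ctxA", "ctxB") and "beta" in shared:
                    comp = amp * (
                        0.6 * shared["beta"] + 0.8 * comp / max(amp, 1e-12)
                    )
                x = x + comp
            out[f"{hemi}/{site}"] = Signal(x, fs, 0.0, f"{hemi}/{site}")
    return out


def _simulate_device_accel(
    subject: SubjectConfig,
    gt: TrialGroundTruth,
    duration: float,
    rng: np.random.Generator,
) -> Signal:
    """Device accelerometer on its own clock (offset from the wearables)."""
    fs = subject.fs_device_accel
    n = int(round((duration + abs(subject.clock_offset_s)) * fs))
    # sample k of the device stream occurs at common time k/fs + offset
    t_common = np.arange(n) / fs + subject.clock_offset_s
    x = 0.08 * rng.standard_normal(n)
    s_imp = 0.03
    for a in np.sort(np.concatenate([gt.lhs, gt.rhs])):
        x += (2.0 + 0.2 * rng.standard_normal()) * np.exp(
            -0.5 * ((t_common - a) / s_imp) ** 2
        )
    return Signal(x, fs, 0.0, "device_accel")


# ---------------------------------------------------------------------------
# artifacts


@dataclass
class ArtifactSpec:
    """Contaminants to inject into the neural channels.

    Amplitudes for ``gamma_burst`` are in detection-domain z-units (relative
    to the standard deviation of the 75-150 Hz band-passed background).
    """

    stim_tone: float | None = None  # amplitude relative to channel SD
    subharmonic: float | None = None
    gamma_burst_z: float | None = None
    gamma_burst_count: int = 5
    gamma_burst_dur_s: float = 0.12
    ekg_spikes: float | None = None  # spike amplitude (signal units)
    ekg_rate_hz: float = 1.1
    packet_loss_count: int = 0
    packet_loss_dur_s: float = 0.12

    def empty(self) -> bool:
        return (
            self.stim_tone is None
            and self.subharmonic is None
            and self.gamma_burst_z is None
            and self.ekg_spikes is None
            and self.packet_loss_count == 0
        )


def inject_artifacts(
    recording: TrialRecording, spec: ArtifactSpec, seed: int
) -> TrialRecording:
    """Add the named contaminants in place; true intervals go to ground truth."""
    from scipy.signal import butter, sosfiltfilt

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 77]))
    gt = recording.ground_truth
    f_stim = recording.setting.frequency_Hz
    for key, sig in recording.neural.items():
        x = sig.data
        n = x.size
        fs = sig.rate_hz
        t = np.arange(n) / fs
        sd = x.std()
        if spec.stim_tone is not None:
            x = x + spec.stim_tone * sd * np.sin(2 * np.pi * f_stim * t)
            gt.artifact_intervals.append((0.0, n / fs, "stim_tone", key))
        if spec.subharmonic is not None:
            x = x + spec.subharmonic * sd * np.sin(2 * np.pi * (f_stim / 2.0) * t)
            gt.artifact_intervals.append((0.0, n / fs, "subharmonic", key))
        if spec.gamma_burst_z is not None:
            if spec.gamma_burst_z < 3.0:
                log.warning(
                    "gamma burst amplitude %.1f z is below the detectability "
                    "floor; injected anyway",
                    spec.gamma_burst_z,
                )
            sos = butter(4, [75.0, 150.0], btype="bandpass", fs=fs, output="sos")
            sigma_band = sosfiltfilt(sos, x).std()
            dur = spec.gamma_burst_dur_s
            # the bursts themselves inflate the per-trial z denominator;
            # pre-compensate so the requested z is what the detector sees
            sig_t = dur / 4.0
            q = spec.gamma_burst_count * sig_t * np.sqrt(np.pi) / (n / fs)
            infl = 1.0 - 0.5 * spec.gamma_burst_z**2 * q
            if infl <= 0.05:
                log.warning(
                    "gamma bursts too dense for the requested z level; "
                    "amplitude left uncompensated"
                )
                sigma_eff = sigma_band
            else:
                sigma_eff = sigma_band / np.sqrt(infl)
            for _ in range(spec.gamma_burst_count):
                c = rng.uniform(1.0, n / fs - 1.0)
                win = np.exp(-0.5 * ((t - c) / sig_t) ** 2)
                x = x + (
                    spec.gamma_burst_z
                    * sigma_eff
                    * win
                    * np.sin(2 * np.pi * 110.0 * t)
                )
                gt.artifact_intervals.append(
                    (c - dur / 2.0, c + dur / 2.0, "gamma_burst", key)
                )
        if spec.ekg_spikes is not None:
            t0 = rng.uniform(0.0, 1.0 / spec.ekg_rate_hz)
            beats = np.arange(t0, n / fs, 1.0 / spec.ekg_rate_hz)
            for b in beats:
                x = x + spec.ekg_spikes * _ekg_wavelet(t - b, fs)
            gt.artifact_intervals.append((0.0, n / fs, "ekg_spikes", key))
        if spec.packet_loss_count > 0:
            for _ in range(spec.packet_loss_count):
                c = rng.uniform(1.0, n / fs - 1.0)
                i0 = int(c * fs)
                i1 = min(i0 + int(spec.packet_loss_dur_s * fs), n)
                x[i0:i1] = x[max(i0 - 1, 0)]  # device repeats the last sample
                gt.artifact_intervals.append(
                    (i0 / fs, i1 / fs, "packet_loss", key)
                )
        sig.data = x
    return recording


def _ekg_wavelet(dt: np.ndarray, fs: float) -> np.ndarray:
    """Small biphasic spike (QRS-like), ~40 ms wide."""
    s = 0.012
    return np.where(
        np.abs(dt) < 0.1, (1.0 - (dt / s) ** 2) * np.exp(-0.5 * (dt / s) ** 2), 0.0
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortConfig:
    subjects: list[SubjectConfig]
    n_visits: int = 2
    settings_per_visit: int = 3
    n_strides: int = 20
    metric_noise_sd: float = 0.03
    artifact_spec: ArtifactSpec | None = None
    sites: tuple[str, ...] = ("GP", "ctxA", "ctxB")


@dataclass
class Cohort:
    subjects: list[SubjectConfig]
    surfaces: dict[str, GroundTruthSurface]
    trials: list[TrialRecording]
    manifest: pd.DataFrame
    feedback: pd.DataFrame | None = None

    def trial(self, trial_id: str) -> TrialRecording:
        for tr in self.trials:
            if tr.trial_id == trial_id:
                return tr
        raise KeyError(trial_id)


def simulate_cohort(config: CohortConfig, seed: int) -> Cohort:
    """Simulate a full multi-visit cohort with randomized trial order.

    Every visit contains exactly one clinical-setting trial plus
    ``settings_per_visit - 1`` settings drawn uniformly from the subject's
    safe box.
    """
    if not config.subjects:
        raise ValueError("need at least one subject")
    if config.n_visits < 1 or config.settings_per_visit < 2:
        raise ValueError("need >= 1 visit and >= 2 settings per visit")
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 1001])
    rng = np.random.default_rng(ss)
    trials: list[TrialRecording] = []
    surfaces: dict[str, GroundTruthSurface] = {}
    rows = []
    for subject in config.subjects:
        surface = build_surface(subject, seed)
        surfaces[subject.subject_id] = surface
        box = subject.safe_range
        for v in range(config.n_visits):
            visit_id = f"{subject.subject_id}_v{v + 1}"
            settings = [subject.clinical_setting]
            for _ in range(config.settings_per_visit - 1):
                x = box[:, 0] + (box[:, 1] - box[:, 0]) * rng.uniform(size=3)
                settings.append(StimSetting.from_array(x))
            # realized trial-level performance, then the visit's
            # baseline-normalized covariate on the same min-max scale the
            # walking performance index is defined on
            w_used = np.array(
                [
                    surface.value(s)
                    + surface.observation_noise_sd * rng.standard_normal()
                    for s in settings
                ]
            )
            span = w_used.max() - w_used.min()
            W = (
                (w_used - w_used.min()) / span
                if span > 1e-9
                else np.full(len(w_used), 0.5)
            )
            covariates = W / max(W[0], 0.3)  # index 0 is the clinical setting
            order = rng.permutation(len(settings))
            for j, idx in enumerate(order):
                setting = settings[idx]
                trial_seed = int(rng.integers(0, 2**31 - 1))
                tr = simulate_trial(
                    subject,
                    surface,
                    setting,
                    config.n_strides,
                    trial_seed,
                    config.metric_noise_sd,
                    sites=config.sites,
                    wpi_used=float(w_used[idx]),
                    neural_wpi_covariate=float(covariates[idx]),
                )
                tr.trial_id = f"{visit_id}_t{j + 1}"
                tr.visit_id = visit_id
                if config.artifact_spec is not None and not config.artifact_spec.empty():
                    inject_artifacts(tr, config.artifact_spec, trial_seed)
                trials.append(tr)
                rows.append(
                    {
                        "trial_id": tr.trial_id,
                        "subject_id": subject.subject_id,
                        "visit_id": visit_id,
                        "amplitude_mA": setting.amplitude_mA,
                        "frequency_Hz": setting.frequency_Hz,
                        "pulse_width_us": setting.pulse_width_us,
                        "clinical_flag": bool(setting.clinical),
                        "true_wpi": tr.ground_truth.true_wpi,
                    }
                )
    manifest = pd.DataFrame(rows)
    ids = manifest["trial_id"]
    if ids.duplicated().any():
        raise ValueError("duplicate trial ids")
    n_clin = manifest.groupby("visit_id")["clinical_flag"].sum()
    if not (n_clin == 1).all():
        raise ValueError("every visit must contain exactly one clinical trial")
    return Cohort(config.subjects, surfaces, trials, manifest)


def simulate_feedback(
    cohort: Cohort,
    concordance: float,
    seed: int,
    raters: Sequence[str] = ("patient", "therapist"),
) -> pd.DataFrame:
    """Per-visit subjective rankings (rank 1 = best) at a given concordance.

    ``concordance=1`` reproduces the true-performance ranking exactly;
    ``concordance=0`` draws a uniformly random permutation.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 2002]))
    rows = []
    for visit_id, grp in cohort.manifest.groupby("visit_id", sort=True):
        if len(grp) < 2:
            log.info("visit %s has < 2 trials; feedback skipped", visit_id)
            continue
        w = grp["true_wpi"].to_numpy()
        # rank 1 = best (highest performance)
        wpi_rank = (-w).argsort().argsort() + 1
        for rater in raters:
            u = rng.uniform(size=len(grp))
            score = concordance * (-w) / max(np.ptp(w), 1e-12) + (1 - concordance) * u
            fb_rank = score.argsort().argsort() + 1
            for tid, sid, wr, fr in zip(
                grp["trial_id"], grp["subject_id"], wpi_rank, fb_rank
            ):
                rows.append(
                    {
                        "subject_id": sid,
                        "visit_id": visit_id,
                        "rater": rater,
                        "trial_id": tid,
                        "wpi_rank": int(wr),
                        "feedback_rank": int(fr),
                    }
                )
    return pd.DataFrame(rows)


def default_cohort_config(
    n_subjects: int = 3,
    n_visits: int = 2,
    settings_per_visit: int = 3,
    n_strides: int = 20,
    clock_offsets: Iterable[float] = (-1.7, -2.3, -0.9),
) -> CohortConfig:
    """Three-subject study layout: two bilateral implants, one unilateral."""
    offsets = list(clock_offsets)
    subjects = []
    ranges = [
        np.array([[4.1, 5.5], [60.0, 190.0], [60.0, 90.0]]),
        np.array([[2.8, 5.0], [60.0, 180.0], [60.0, 70.0]]),
        np.array([[3.5, 4.9], [60.0, 190.0], [60.0, 80.0]]),
    ]
    for i in range(n_subjects):
        subjects.append(
            SubjectConfig(
                subject_id=f"S{i + 1}",
                hemispheres=1 if i == 2 else 2,
                safe_range=ranges[i % len(ranges)],
                clock_offset_s=offsets[i % len(offsets)],
            )
        )
    return CohortConfig(
        subjects=subjects,
        n_visits=n_visits,
        settings_per_visit=settings_per_visit,
        n_strides=n_strides,
    )
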