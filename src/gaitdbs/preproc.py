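"""Neural preprocessing: clock sync, filtering, artifact blanking, exclusion.

The implanted device streams neural data (500 Hz) and its own
accelerometer (64 Hz) on a clock that is offset from the wearable sensors
that carry the gait events.  Peak-acceleration moments serve as temporal
anchors to estimate that offset.  High-amplitude gamma-range transients
are detected with a dedicated filter chain and blanked (NaN) with a
200 ms buffer; telemetry packet loss is detected as frozen/zero sample
runs and any overlapping gait cycle is excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt
from scipy.signal import correlate as sig_correlate

from .types import GaitCycle, PHASES, Signal, interval_samples

log = logging.getLogger(__name__)

GAMMA_BAND = (75.0, 150.0)
GAMMA_Z_THRESHOLD = 8.0
BLANK_BUFFER_S = 0.2  # added on each side of a flagged run
PACKET_LOSS_MIN_S = 0.05
PACKET_LOSS_MERGE_S = 0.05
PHASE_BLANK_FRACTION = 0.5


class SyncError(RuntimeError):
    """Raised when device and wearable streams cannot be aligned."""


@dataclass
class SyncModel:
    """Estimated clock offset between device and wearable streams.

    ``offset_s`` is defined so that ``wearable_time = device_time +
    offset_s`` (device minus wearable clock origin difference).
    """

    offset_s: float
    anchor_pairs: np.ndarray  # (n, 2): device time, wearable time
    residual_sd_s: float

    def to_wearable_time(self, device_time_s: np.ndarray) -> np.ndarray:
        return np.asarray(device_time_s) + self.offset_s


def _accel_peaks(sig: Signal, min_separation_s: float = 0.35):
    x = sig.data - np.nanmedian(sig.data)
    prom = 0.5 * np.nanstd(x)
    idx, props = find_peaks(
        x, prominence=max(prom, 1e-9), distance=max(int(min_separation_s * sig.rate_hz), 1)
    )
    return idx / sig.rate_hz, x[idx]


def estimate_sync(
    device_accel: Signal,
    wearable_accel: Signal,
    max_offset_s: float = 10.0,
    grid_hz: float = 1000.0,
) -> SyncModel:
    """Estimate the device-wearable clock offset from acceleration peaks.

    Peak times from both streams are turned into smoothed impulse trains
    on a common grid; their cross-correlation gives a coarse offset that
    is refined by the median residual of nearest-peak matches.
    """
    td, ad = _accel_peaks(device_accel)
    tw, aw = _accel_peaks(wearable_accel)
    if td.size < 1 or tw.size < 1:
        raise SyncError("no acceleration peaks found in one of the streams")
    t_max = max(td.max(), tw.max()) + max_offset_s + 1.0
    n = int(t_max * grid_hz) + 1

    def _train(times):
        x = np.zeros(n)
        x[np.clip((times * grid_hz).astype(int), 0, n - 1)] = 1.0
        return gaussian_filter1d(x, sigma=0.03 * grid_hz)

    xd, xw = _train(td), _train(tw)
    max_lag = int(max_offset_s * grid_hz)
    # corr[k] = sum_t xw[t] * xd[t - k]; FFT-based for speed
    full = sig_correlate(xw, xd, mode="full", method="fft")
    lags = np.arange(-(n - 1), n)
    keep = np.abs(lags) <= max_lag
    corr, lags = full[keep], lags[keep]
    if corr.max() <= 1e-12:
        raise SyncError("streams share no correlated peak structure")
    coarse = lags[int(np.argmax(corr))] / grid_hz
    # refine: match each device peak to its nearest wearable peak
    pairs = []
    half_period = 0.3
    for t in td:
        j = int(np.argmin(np.abs(tw - (t + coarse))))
        if abs(tw[j] - (t + coarse)) < half_period:
            pairs.append((t, tw[j]))
    if not pairs:
        raise SyncError("no anchor pairs matched after coarse alignment")
    pairs = np.asarray(pairs)
    resid = pairs[:, 1] - pairs[:, 0]
    offset = float(np.median(resid))
    sd = float(np.std(resid - offset, ddof=1)) if len(pairs) > 1 else 0.0
    return SyncModel(offset_s=offset, anchor_pairs=pairs, residual_sd_s=sd)


def anchor_stats(
    peaks_by_trial: dict[str, tuple[np.ndarray, np.ndarray]]
) -> pd.DataFrame:
    """Summaries of anchor-peak amplitudes and inter-arrival intervals.

    Input maps trial id -> (peak times s, peak amplitudes).  Returns one
    row per trial plus a pooled row, with mean/SD/quartiles for amplitude
    and (where >= 2 peaks) inter-arrival time.
    """

    def _row(name, times, amps):
        iat = np.diff(np.sort(times)) if times.size >= 2 else np.array([])
        q = lambda x, p: float(np.quantile(x, p)) if x.size else np.nan
        return {
            "trial_id": name,
            "n_peaks": int(times.size),
            "amp_mean": float(np.mean(amps)) if amps.size else np.nan,
            "amp_sd": float(np.std(amps, ddof=1)) if amps.size > 1 else np.nan,
            "amp_q25": q(amps, 0.25),
            "amp_q75": q(amps, 0.75),
            "iat_mean": float(np.mean(iat)) if iat.size else np.nan,
            "iat_sd": float(np.std(iat, ddof=1)) if iat.size > 1 else 0.0 if iat.size == 1 else np.nan,
            "iat_q25": q(iat, 0.25),
            "iat_q75": q(iat, 0.75),
        }

    rows = [_row(k, np.asarray(t), np.asarray(a)) for k, (t, a) in peaks_by_trial.items()]
    all_t = np.concatenate([np.asarray(t) for t, _ in peaks_by_trial.values()])
    all_a = np.concatenate([np.asarray(a) for _, a in peaks_by_trial.values()])
    pooled = _row("__pooled__", all_t, all_a)
    # pooled inter-arrival must not span trials
    iats = [
        np.diff(np.sort(np.asarray(t)))
        for t, _ in peaks_by_trial.values()
        if np.asarray(t).size >= 2
    ]
    if iats:
        iat = np.concatenate(iats)
        pooled.update(
            iat_mean=float(np.mean(iat)),
            iat_sd=float(np.std(iat, ddof=1)) if iat.size > 1 else 0.0,
            iat_q25=float(np.quantile(iat, 0.25)),
            iat_q75=float(np.quantile(iat, 0.75)),
        )
    rows.append(pooled)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# filtering


def _finite_segments(x: np.ndarray):
    finite = np.isfinite(x)
    d = np.diff(finite.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if finite.size and finite[0]:
        starts = [0] + starts
    if finite.size and finite[-1]:
        ends = ends + [finite.size]
    return list(zip(starts, ends))


def highpass(
    x: np.ndarray, rate: float, cutoff: float = 1.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth high-pass, restarted per contiguous segment.

    Missing samples (NaN) are preserved; each finite run is filtered
    independently so gaps do not leak transients.  Zero-phase filtering
    doubles the effective order.
    """
    if cutoff >= rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = butter(order, cutoff, btype="highpass", fs=rate, output="sos")
    out = np.full_like(np.asarray(x, dtype=float), np.nan)
    padlen = 3 * (2 * order + 1)
    for i0, i1 in _finite_segments(np.asarray(x, dtype=float)):
        seg = np.asarray(x[i0:i1], dtype=float)
        if seg.size <= padlen:
            out[i0:i1] = seg - np.mean(seg)  # too short to filter stably
            continue
        out[i0:i1] = sosfiltfilt(sos, seg)
    return out


# ---------------------------------------------------------------------------
# artifact masking


@dataclass
class ArtifactMask:
    """Per-sample blanking mask with provenance-tagged intervals."""

    mask: np.ndarray  # boolean, True = blank
    rate_hz: float
    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    @property
    def blanked_fraction(self) -> float:
        return float(np.mean(self.mask)) if self.mask.size else 0.0


def _runs_to_intervals(flags: np.ndarray, rate: float):
    d = np.diff(flags.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if flags.size and flags[0]:
        starts = [0] + starts
    if flags.size and flags[-1]:
        ends = ends + [flags.size]
    return [(s / rate, e / rate) for s, e in zip(starts, ends)]


def gamma_outlier_mask(x: np.ndarray, rate: float = 500.0) -> ArtifactMask:
    """Flag high-amplitude gamma-range transients for blanking.

    Detection chain (detection only; the analysis signal is untouched):
    zero-phase 4 Hz order-4 Butterworth high-pass, 75-150 Hz band-pass,
    per-sample z-score over the whole trial, strict ``|z| > 8`` flagging,
    then a 200 ms buffer on each side of every flagged run with merging of
    overlaps.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < rate:  # < 1 s of data
        log.warning("trial shorter than 1 s; gamma mask left empty")
        return ArtifactMask(np.zeros(n, dtype=bool), rate)
    sos_hp = butter(4, 4.0, btype="highpass", fs=rate, output="sos")
    sos_bp = butter(4, GAMMA_BAND, btype="bandpass", fs=rate, output="sos")
    det = np.full(n, np.nan)
    for i0, i1 in _finite_segments(x):
        if i1 - i0 <= 27:
            continue
        det[i0:i1] = sosfiltfilt(sos_bp, sosfiltfilt(sos_hp, x[i0:i1]))
    finite = np.isfinite(det)
    mu = np.nanmean(det) if finite.any() else 0.0
    sd = np.nanstd(det) if finite.any() else 1.0
    z = (det - mu) / (sd if sd > 0 else 1.0)
    z[~finite] = 0.0
    return mask_from_zscores(z, rate)


def mask_from_zscores(
    z: np.ndarray, rate: float, threshold: float = GAMMA_Z_THRESHOLD
) -> ArtifactMask:
    """Strictly-above-threshold flagging with 200 ms dilation and merging.

    A sample at exactly the threshold is not flagged.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    flagged = np.abs(z) > threshold  # strict inequality
    pad = int(round(BLANK_BUFFER_S * rate))
    mask = np.zeros(n, dtype=bool)
    for s, e in _runs_to_intervals(flagged, rate):
        i0 = max(int(s * rate) - pad, 0)
        i1 = min(int(e * rate) + pad, n)
        mask[i0:i1] = True
    intervals = [(s, e, "gamma_outlier") for s, e in _runs_to_intervals(mask, rate)]
    return ArtifactMask(mask, rate, intervals)


def apply_blanking(x: np.ndarray, mask: ArtifactMask | np.ndarray) -> np.ndarray:
    """Replace masked samples with NaN; all other samples are bit-identical."""
    m = mask.mask if isinstance(mask, ArtifactMask) else np.asarray(mask, dtype=bool)
    x = np.asarray(x, dtype=float)
    if m.shape != x.shape:
        raise ValueError("mask length does not match signal length")
    out = x.copy()
    out[m] = np.nan
    return out


def detect_packet_loss(
    x: np.ndarray, rate: float, min_dur_s: float = PACKET_LOSS_MIN_S
) -> list[tuple[float, float]]:
    """Detect telemetry dropouts as frozen or zero sample runs.

    Runs of exactly repeated values or exact zeros lasting at least
    ``min_dur_s`` are flagged; intervals separated by less than 50 ms are
    merged.  (The streaming firmware repeats the last received sample
    across a gap, so value runs are the low-frequency signature of loss.)
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return []
    frozen = np.concatenate([[False], np.diff(x) == 0.0])
    # a frozen run of k repeats involves k+1 equal samples; include the first
    frozen[:-1] |= frozen[1:]
    zero = x == 0.0
    flags = frozen | zero
    min_len = int(min_dur_s * rate)
    raw = [
        (s, e)
        for s, e in _runs_to_intervals(flags, rate)
        if (e - s) * rate >= min_len
    ]
    merged: list[tuple[float, float]] = []
    for s, e in raw:
        if merged and s - merged[-1][1] < PACKET_LOSS_MERGE_S:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def exclude_contaminated_cycles(
    cycles: list[GaitCycle],
    gamma_mask: ArtifactMask | None,
    packet_intervals: list[tuple[float, float]],
    t0_s: float = 0.0,
) -> tuple[list[GaitCycle], list[tuple[GaitCycle, str]]]:
    """Drop gait cycles whose neural data is too contaminated to analyze.

    A cycle is dropped when packet loss overlaps it at all, or when more
    than half of any single phase is blanked by the gamma mask.  Cycle
    times and mask samples must share a common (synchronized) timeline;
    ``t0_s`` is the time of mask sample 0 on that timeline.
    """
    usable: list[GaitCycle] = []
    dropped: list[tuple[GaitCycle, str]] = []
    for c in cycles:
        reason = None
        for s, e in packet_intervals:
            if s < c.lhs_next and e > c.lhs:
                reason = "packet_loss"
                break
        if reason is None and gamma_mask is not None:
            for phase in PHASES:
                a, b = c.phase_interval(phase)
                sl = interval_samples(a, b, gamma_mask.rate_hz, gamma_mask.mask.size, t0_s)
                seg = gamma_mask.mask[sl]
                if seg.size and np.mean(seg) > PHASE_BLANK_FRACTION:
                    reason = f"gamma_blanking:{phase}"
                    break
        if reason is None:
            usable.append(c)
        else:
            log.info("cycle at t=%.2f dropped (%s)", c.lhs, reason)
            dropped.append((c, reason))
    return usable, dropped
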