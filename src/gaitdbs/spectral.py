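"""Time-frequency power, wavelet coherence, and gait-phase band features.

Power is the squared magnitude of an analytic (complex Morlet) continuous
wavelet transform on a logarithmic frequency grid; coherence is the
magnitude-squared wavelet coherence with scale-dependent smoothing in
time and a fixed smoothing span in scale.  Within each visit, power and
coherence are z-scored per frequency row over all trials pooled, then
averaged over the canonical bands

    delta [2, 4) Hz, theta [4, 8) Hz, alpha [8, 12) Hz, beta [12, 30) Hz

(lower bound inclusive, upper exclusive) and over the four gait phases of
each cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .types import PHASES, GaitCycle, interval_samples

log = logging.getLogger(__name__)

#: canonical bands, lower bound inclusive / upper exclusive
BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}

#: analytic Morlet variant used for all transforms
WAVELET = "cmor1.5-1.0"
VOICES_PER_OCTAVE = 10
#: time-smoothing span for coherence, in cycles of each scale's period
COHERENCE_TIME_CYCLES = 1.0
#: scale-smoothing span for coherence, in octaves
COHERENCE_SCALE_OCTAVES = 0.6


@dataclass
class TimeFrequencyMap:
    """A power or coherence map on a log-frequency grid."""

    kind: str  # "power" | "coherence"
    freqs_hz: np.ndarray  # ascending
    values: np.ndarray  # (n_freq, n_time)
    rate_hz: float
    t0_s: float = 0.0
    normalization: str = "raw"  # "raw" | "z_per_frequency"
    flags: list[str] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.shape[1]) / self.rate_hz


def _freq_grid(fmin: float, fmax: float, voices_per_octave: int) -> np.ndarray:
    n_oct = np.log2(fmax / fmin)
    k = int(np.floor(n_oct * voices_per_octave)) + 1
    return fmax * 2.0 ** (-np.arange(k)[::-1] / voices_per_octave)


def cwt_complex(
    x: np.ndarray,
    rate: float,
    fmin: float = 1.0,
    fmax: float = 30.0,
    voices_per_octave: int = VOICES_PER_OCTAVE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complex Morlet CWT on a log grid; returns (coef, freqs, missing).

    Missing input samples are zero-filled for the transform and then
    propagated to the output with a cone-of-influence-style margin of one
    wavelet period per frequency row (``missing`` is a boolean (n_freq,
    n_time) array marking invalidated cells).
    """
    x = np.asarray(x, dtype=float)
    freqs = _freq_grid(fmin, fmax, voices_per_octave)
    wav = pywt.ContinuousWavelet(WAVELET)
    fc = pywt.central_frequency(wav)
    scales = fc * rate / freqs
    bad = ~np.isfinite(x)
    xf = np.where(bad, 0.0, x)
    coef, _ = pywt.cwt(xf, scales[::-1], wav, sampling_period=1.0 / rate, method="fft")
    coef = coef[::-1]  # ascending frequency order
    missing = np.zeros(coef.shape, dtype=bool)
    if bad.any():
        for i, f in enumerate(freqs):
            margin = max(int(round(rate / f)), 1)
            m = bad.copy()
            # dilate by one period on each side
            kernel = 2 * margin + 1
            m = uniform_filter1d(m.astype(float), size=kernel, mode="constant") > 0
            missing[i] = m
    return coef, freqs, missing


def cwt_power(
    x: np.ndarray,
    rate: float,
    fmin: float = 1.0,
    fmax: float = 30.0,
    voices_per_octave: int = VOICES_PER_OCTAVE,
) -> TimeFrequencyMap:
    """Scalogram |W|^2 of an analytic-wavelet transform."""
    x = np.asarray(x, dtype=float)
    if x.size == 0 or not np.isfinite(x).any():
        return TimeFrequencyMap(
            "power",
            _freq_grid(fmin, fmax, voices_per_octave),
            np.empty((len(_freq_grid(fmin, fmax, voices_per_octave)), 0)),
            rate,
        )
    coef, freqs, missing = cwt_complex(x, rate, fmin, fmax, voices_per_octave)
    power = np.abs(coef) ** 2
    power[missing] = np.nan
    return TimeFrequencyMap("power", freqs, power, rate)


def _smooth_time(W: np.ndarray, freqs: np.ndarray, rate: float) -> np.ndarray:
    """Scale-dependent Gaussian smoothing along time (per frequency row)."""
    out = np.empty_like(W)
    for i, f in enumerate(freqs):
        sigma = max(COHERENCE_TIME_CYCLES * rate / f / 2.0, 1.0)
        if np.iscomplexobj(W):
            out[i] = gaussian_filter1d(W[i].real, sigma) + 1j * gaussian_filter1d(
                W[i].imag, sigma
            )
        else:
            out[i] = gaussian_filter1d(W[i], sigma)
    return out


def _smooth_scale(W: np.ndarray, voices_per_octave: int) -> np.ndarray:
    size = max(int(round(COHERENCE_SCALE_OCTAVES * voices_per_octave)), 1)
    if np.iscomplexobj(W):
        return uniform_filter1d(W.real, size, axis=0) + 1j * uniform_filter1d(
            W.imag, size, axis=0
        )
    return uniform_filter1d(W, size, axis=0)


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    fmin: float = 1.0,
    fmax: float = 30.0,
    voices_per_octave: int = VOICES_PER_OCTAVE,
) -> TimeFrequencyMap:
    """Magnitude-squared wavelet coherence of two equally sampled signals.

    The cross-spectrum and the two auto-spectra are smoothed with the same
    scale-dependent time window and a fixed span in scale before forming
    the coherence ratio; values are clipped to [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must share a common timeline")
    both = np.isfinite(x) & np.isfinite(y)
    if not both.any():
        freqs = _freq_grid(fmin, fmax, voices_per_octave)
        return TimeFrequencyMap("coherence", freqs, np.empty((len(freqs), 0)), rate)
    Wx, freqs, mx = cwt_complex(x, rate, fmin, fmax, voices_per_octave)
    Wy, _, my = cwt_complex(y, rate, fmin, fmax, voices_per_octave)
    Sxy = _smooth_scale(_smooth_time(Wx * np.conj(Wy), freqs, rate), voices_per_octave)
    Sxx = _smooth_scale(_smooth_time(np.abs(Wx) ** 2, freqs, rate), voices_per_octave)
    Syy = _smooth_scale(_smooth_time(np.abs(Wy) ** 2, freqs, rate), voices_per_octave)
    denom = Sxx * Syy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(Sxy) ** 2 / np.where(denom > 0, denom, np.nan)
    coh = np.clip(coh, 0.0, 1.0)
    coh[mx | my] = np.nan
    return TimeFrequencyMap("coherence", freqs, coh, rate)


# ---------------------------------------------------------------------------
# normalization and feature extraction


def zscore_per_frequency(maps: list[TimeFrequencyMap]) -> list[TimeFrequencyMap]:
    """z-score each frequency row over all maps of a visit pooled.

    The mean and SD are computed over all non-missing samples across the
    supplied maps (one per trial); constant rows yield zeros and a flag.
    """
    if not maps:
        raise ValueError("need at least one map")
    freqs = maps[0].freqs_hz
    for m in maps[1:]:
        if not np.allclose(m.freqs_hz, freqs):
            raise ValueError("maps must share a frequency grid")
    pooled = np.concatenate([m.values for m in maps], axis=1)
    mu = np.nanmean(pooled, axis=1)
    sd = np.nanstd(pooled, axis=1)
    out = []
    for m in maps:
        v = (m.values - mu[:, None]) / np.where(sd > 1e-15, sd, 1.0)[:, None]
        flags = list(m.flags)
        if np.any(sd <= 1e-15):
            v[sd <= 1e-15, :] = 0.0
            flags.append("constant_frequency_rows")
            log.info("constant frequency rows found during z-normalization")
        out.append(
            TimeFrequencyMap(
                m.kind, m.freqs_hz, v, m.rate_hz, m.t0_s, "z_per_frequency", flags
            )
        )
    return out


def band_average(tf_map: TimeFrequencyMap, band: str) -> np.ndarray:
    """Unweighted mean over grid frequencies with lo <= f < hi (missing-aware)."""
    lo, hi = BANDS[band]
    rows = (tf_map.freqs_hz >= lo) & (tf_map.freqs_hz < hi)
    if not rows.any():
        raise ValueError(f"frequency grid has no rows in band {band!r} [{lo}, {hi})")
    with np.errstate(invalid="ignore"):
        return np.nanmean(tf_map.values[rows], axis=0)


def phase_average(
    series: np.ndarray,
    rate: float,
    cycles: list[GaitCycle],
    t0_s: float = 0.0,
    max_missing_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Mean band value within each gait phase, per cycle and per trial.

    A phase whose samples are more than half missing yields NaN for that
    cycle; the per-trial feature is the mean over cycles with a finite
    value.  Returns (per-cycle table, per-trial phase means).
    """
    series = np.asarray(series, dtype=float)
    rows = []
    for i, c in enumerate(cycles):
        rec: dict[str, float] = {"cycle": i, "stride_time_s": c.stride_time_s}
        for phase in PHASES:
            a, b = c.phase_interval(phase)
            sl = interval_samples(a, b, rate, series.size, t0_s)
            seg = series[sl]
            if seg.size == 0:
                rec[phase] = np.nan
                continue
            frac_missing = float(np.mean(~np.isfinite(seg)))
            rec[phase] = (
                float(np.nanmean(seg))
                if frac_missing <= max_missing_fraction and np.isfinite(seg).any()
                else np.nan
            )
        rows.append(rec)
    table = pd.DataFrame(rows)
    trial_means = {}
    for phase in PHASES:
        vals = table[phase].to_numpy() if len(table) else np.array([])
        trial_means[phase] = (
            float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
        )
    return table, trial_means


def sort_by_stride_time(stride_times: np.ndarray) -> np.ndarray:
    """Ascending stride-time permutation; ties keep original order."""
    return np.argsort(np.asarray(stride_times), kind="stable")


def build_feature_table(
    features: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Join long-format phase-band features with the cohort manifest.

    ``features`` must carry one row per (trial_id, hemisphere,
    site_or_pair, band, phase) with a ``value`` column; every trial id
    must appear in the manifest.
    """
    orphans = sorted(set(features["trial_id"]) - set(manifest["trial_id"]))
    if orphans:
        raise ValueError(f"trials absent from manifest: {orphans}")
    cols = [
        "trial_id",
        "subject_id",
        "visit_id",
        "amplitude_mA",
        "frequency_Hz",
        "pulse_width_us",
        "clinical_flag",
    ]
    cols = [c for c in cols if c == "trial_id" or c not in features.columns]
    out = features.merge(manifest[cols], on="trial_id", how="left", validate="m:1")
    return out
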