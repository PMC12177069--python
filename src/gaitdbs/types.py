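"""Core domain types shared across the pipeline.

Conventions used throughout the package:

* times are seconds from trial start, intervals are half-open ``[start, end)``;
* samples are 0-based;
* stimulation settings live in raw device units (mA, Hz, microseconds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Gait event labels: left/right heel strike, left/right toe off.
EVENT_LABELS = ("LHS", "RTO", "RHS", "LTO")

#: Gait-cycle phases in order, for a left-referenced cycle:
#: DS1 = [LHS, RTO)  double limb support 1
#: CLS = [RTO, RHS)  contralateral (right) leg swing
#: DS2 = [RHS, LTO)  double limb support 2
#: ILS = [LTO, next LHS)  ipsilateral (left) leg swing
PHASES = ("DS1", "CLS", "DS2", "ILS")

#: Recording sites (bipolar channels) and coherence pairs per hemisphere.
SITES = ("GP", "ctxA", "ctxB")
PAIRS = ("GP-ctxA", "GP-ctxB", "ctxA-ctxB")


@dataclass(frozen=True)
class StimSetting:
    """One point in the stimulation parameter box.

    Parameters are the three programmable axes of a DBS device: pulse
    amplitude (mA), pulse repetition frequency (Hz) and pulse width (us).
    ``clinical`` marks the clinician-optimized baseline setting.
    """

    amplitude_mA: float
    frequency_Hz: float
    pulse_width_us: float
    clinical: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.amplitude_mA, self.frequency_Hz, self.pulse_width_us], dtype=float
        )

    @staticmethod
    def from_array(x: Sequence[float], clinical: bool = False) -> "StimSetting":
        a, f, pw = (float(v) for v in x)
        return StimSetting(a, f, pw, clinical)


@dataclass(frozen=True)
class GaitEvent:
    """A single detected gait event."""

    time_s: float
    label: str  # one of EVENT_LABELS

    def __post_init__(self) -> None:
        if self.label not in EVENT_LABELS:
            raise ValueError(f"unknown event label {self.label!r}")
        if not np.isfinite(self.time_s) or self.time_s < 0:
            raise ValueError(f"event time must be finite and >= 0, got {self.time_s}")


@dataclass
class GaitCycle:
    """One complete gait cycle with its four phase boundaries.

    For ``reference_side == 'left'`` the anchor events are
    LHS -> RTO -> RHS -> LTO -> next LHS; for a right-referenced cycle the
    roles of the feet are mirrored but the field names are kept (``lhs`` is
    then the reference-side heel strike, etc.).
    """

    lhs: float
    rto: float
    rhs: float
    lto: float
    lhs_next: float
    reference_side: str = "left"
    is_turn: bool = False

    def __post_init__(self) -> None:
        if not (self.lhs < self.rto < self.rhs < self.lto < self.lhs_next):
            raise ValueError("cycle events must be strictly increasing")
        if self.reference_side not in ("left", "right"):
            raise ValueError("reference_side must be 'left' or 'right'")

    @property
    def stride_time_s(self) -> float:
        return self.lhs_next - self.lhs

    def phase_interval(self, phase: str) -> tuple[float, float]:
        """Half-open [start, end) interval of one phase."""
        bounds = {
            "DS1": (self.lhs, self.rto),
            "CLS": (self.rto, self.rhs),
            "DS2": (self.rhs, self.lto),
            "ILS": (self.lto, self.lhs_next),
        }
        return bounds[phase]

    def phase_durations(self) -> dict[str, float]:
        return {p: e - s for p, (s, e) in ((p, self.phase_interval(p)) for p in PHASES)}


@dataclass
class Signal:
    """A uniformly sampled channel with its own clock.

    ``t0_s`` is the time of sample 0 on the *common* (wearable) timeline;
    streams that live on an offset device clock carry a nonzero t0 only
    after synchronization.
    """

    data: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")

    @property
    def n(self) -> int:
        return self.data.shape[-1]

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.rate_hz


def interval_samples(
    start_s: float, end_s: float, rate_hz: float, n: int, t0_s: float = 0.0
) -> slice:
    """Sample slice covering the half-open interval [start_s, end_s)."""
    i0 = int(np.ceil((start_s - t0_s) * rate_hz - 1e-9))
    i1 = int(np.ceil((end_s - t0_s) * rate_hz - 1e-9))
    return slice(max(i0, 0), min(max(i1, 0), n))
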