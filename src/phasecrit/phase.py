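"""Instantaneous phase, phase difference and its rate of change.

The quantity of interest downstream is the *rate of change of the phase
difference* between two uniformly sampled signals: the first difference of
the unwrapped difference of their instantaneous (analytic-signal) phases.
Its temporal structure is what the DFA / ML-DFA machinery in
:mod:`phasecrit.dfa` interrogates for long-range temporal correlations.

Phases are computed per signal with the Hilbert transform, unwrapped
separately and subtracted.  The joint arctangent form,

    phi1 - phi2 = atan2(H[s1]*s2 - s1*H[s2], s1*s2 + H[s1]*H[s2]),

is provided as :func:`phase_difference_arctan` for cross-checking; it agrees
with the separate-unwrap path modulo 2*pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .errors import DegenerateSignalError, ParameterError, ShapeError

__all__ = [
    "SampledSignal",
    "WrappedPhase",
    "UnwrappedPhase",
    "PhaseDifference",
    "RateSeries",
    "analytic_phase",
    "unwrap",
    "wrap",
    "phase_difference",
    "phase_difference_arctan",
    "rate_of_change",
    "bandpass",
]


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ShapeError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class SampledSignal:
    """A real-valued, uniformly sampled time series.

    Parameters
    ----------
    values
        Amplitude per sample, arbitrary units.
    sampling_rate
        Sampling rate in Hz, > 0.
    label
        Free-text identifier carried through to results.
    """

    values: np.ndarray
    sampling_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values, "signal values")
        if arr.size < 2:
            raise ShapeError("signal must hold at least 2 samples")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be > 0")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Length of the record in seconds."""
        return self.values.size / self.sampling_rate


@dataclass(frozen=True)
class WrappedPhase:
    """Instantaneous phase per sample, wrapped to [-pi, pi]."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values, "phase values")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class UnwrappedPhase:
    """Instantaneous phase per sample with 2*pi discontinuities removed."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values, "phase values")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class PhaseDifference:
    """Unwrapped phase of signal 1 minus unwrapped phase of signal 2."""

    values: np.ndarray
    sampling_rate: float
    labels: tuple = field(default=("", ""))

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values, "phase difference")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class RateSeries:
    """First difference of a phase-difference series (radians per step).

    One sample shorter than its source; cumulative summation plus the
    source's first value reconstructs the phase difference exactly.
    """

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values, "rate series")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size


def analytic_phase(signal: SampledSignal) -> WrappedPhase:
    """Instantaneous phase via the analytic signal s + i*H[s].

    Raises
    ------
    DegenerateSignalError
        If the signal is constant (phase undefined).
    """
    x = signal.values
    if x.size < 4:
        raise ShapeError("need at least 4 samples for a meaningful phase")
    if np.ptp(x) == 0.0:
        raise DegenerateSignalError(
            f"signal {signal.label!r} is constant; instantaneous phase undefined"
        )
    phases = np.angle(hilbert(x))
    return WrappedPhase(values=phases, sampling_rate=signal.sampling_rate)


def unwrap(phase: WrappedPhase) -> UnwrappedPhase:
    """Remove 2*pi jumps so successive differences lie in (-pi, pi]."""
    return UnwrappedPhase(
        values=np.unwrap(phase.values), sampling_rate=phase.sampling_rate
    )


def wrap(phase: UnwrappedPhase) -> WrappedPhase:
    """Wrap an unwrapped phase back onto [-pi, pi] (round-trip inverse)."""
    wrapped = np.angle(np.exp(1j * phase.values))
    return WrappedPhase(values=wrapped, sampling_rate=phase.sampling_rate)


def _check_aligned(s1: SampledSignal, s2: SampledSignal) -> None:
    if len(s1) != len(s2):
        raise ShapeError(f"signal lengths differ: {len(s1)} vs {len(s2)}")
    if s1.sampling_rate != s2.sampling_rate:
        raise ShapeError(
            f"sampling rates differ: {s1.sampling_rate} vs {s2.sampling_rate}"
        )


def phase_difference(s1: SampledSignal, s2: SampledSignal) -> PhaseDifference:
    """Unwrapped analytic phase of ``s1`` minus that of ``s2``.

    Both phases are unwrapped separately before subtraction, so the result
    is unbounded and free of stacking 2*pi ambiguities.
    """
    _check_aligned(s1, s2)
    p1 = unwrap(analytic_phase(s1)).values
    p2 = unwrap(analytic_phase(s2)).values
    return PhaseDifference(
        values=p1 - p2,
        sampling_rate=s1.sampling_rate,
        labels=(s1.label, s2.label),
    )


def phase_difference_arctan(s1: SampledSignal, s2: SampledSignal) -> WrappedPhase:
    """Joint arctangent form of the pairwise phase difference (wrapped).

    Cross-check for :func:`phase_difference`: agrees with it modulo 2*pi at
    every sample (up to analytic-signal edge effects).
    """
    _check_aligned(s1, s2)
    h1 = np.imag(hilbert(s1.values))
    h2 = np.imag(hilbert(s2.values))
    num = h1 * s2.values - s1.values * h2
    den = s1.values * s2.values + h1 * h2
    return WrappedPhase(values=np.arctan2(num, den), sampling_rate=s1.sampling_rate)


def rate_of_change(diff: PhaseDifference, trim: int = 0) -> RateSeries:
    """One-sample first difference of the phase difference.

    Parameters
    ----------
    diff
        Unwrapped phase-difference series.
    trim
        Samples to drop from each edge before differencing, to discard
        analytic-signal edge artifacts.  Default 0 (no trimming).
    """
    values = diff.values
    if trim:
        if trim < 0 or 2 * trim >= values.size - 1:
            raise ParameterError(f"trim={trim} leaves no samples")
        values = values[trim : values.size - trim]
    if values.size < 2:
        raise ShapeError("need at least 2 samples to differentiate")
    return RateSeries(values=np.diff(values), sampling_rate=diff.sampling_rate)


def bandpass(signal: SampledSignal, low_hz: float, high_hz: float) -> SampledSignal:
    """Zero-phase band-limited copy of the signal.

    Forward–backward second-order Butterworth (4 effective poles per band
    edge after the two passes); ``low_hz``/``high_hz`` are the half-power
    corners.  Zero-phase filtering preserves the phase relationships the
    rest of the pipeline depends on.
    """
    nyquist = signal.sampling_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ParameterError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyquist} Hz"
        )
    sos = butter(
        2, [low_hz, high_hz], btype="bandpass", fs=signal.sampling_rate, output="sos"
    )
    filtered = sosfiltfilt(sos, signal.values)
    return SampledSignal(
        values=filtered,
        sampling_rate=signal.sampling_rate,
        label=f"{signal.label}[{low_hz}-{high_hz}Hz]" if signal.label else "",
    )
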