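"""Waveform-level processing of tone-evoked round-window recordings.

Covers the compound action potential (CAP) measures — peak-to-peak amplitude
within a post-onset search window and the 10 µV visual-detection-free
threshold criterion — and the Auditory Nerve Overlapped Waveform (ANOW), the
low-frequency neural measure obtained by averaging responses to
opposite-polarity tone bursts so that components that invert with stimulus
polarity (cochlear microphonic, stimulus artifact) cancel while the neural
response, which does not invert, survives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import signal as sps
from scipy.optimize import isotonic_regression

__all__ = [
    "EvokedWaveform",
    "LevelSeries",
    "ThresholdResult",
    "average_alternating",
    "cap_amplitude",
    "cap_threshold",
    "anow_waveform",
    "anow_magnitude",
    "bandpass",
    "cap_cycle_ms",
    "cap_repetition_rate",
]

DEFAULT_FS = 96_000.0  # Hz
DEFAULT_CAP_WINDOW_MS = (0.5, 6.0)  # spans guinea-pig CAP N1/P1 latencies


@dataclass(frozen=True)
class EvokedWaveform:
    """A single averaged evoked response.

    samples are in µV; ``t0`` is the stimulus-onset time within the record in
    seconds, so sample ``i`` sits at ``i / fs - t0`` relative to onset.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    stim_freq_hz: float | None = None
    stim_level_db: float | None = None
    polarity: Literal["condensation", "rarefaction", "averaged"] = "averaged"
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D array with >= 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def times_s(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return np.arange(self.samples.size) / self.fs - self.t0


@dataclass(frozen=True)
class LevelSeries:
    """Peak-to-peak CAP amplitude (µV) as a function of stimulus level (dB SPL)."""

    levels: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        amplitudes = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "amplitudes", amplitudes)
        if levels.shape != amplitudes.shape or levels.ndim != 1:
            raise ValueError("levels and amplitudes must be 1-D and the same length")
        if np.unique(levels).size != levels.size:
            raise ValueError("levels must be unique")


@dataclass(frozen=True)
class ThresholdResult:
    """CAP threshold with its status.

    status is 'ok' (interpolated crossing), 'no_threshold' (criterion never
    reached; level_db is NaN) or 'at_or_below_min' (all amplitudes exceed the
    criterion; level_db is the lowest tested level).
    """

    level_db: float
    status: Literal["ok", "no_threshold", "at_or_below_min"] = "ok"
    criterion_uv: float = 10.0


def average_alternating(pos: EvokedWaveform, neg: EvokedWaveform) -> EvokedWaveform:
    """Sample-wise mean of condensation/rarefaction responses.

    Cancels any component that inverts with stimulus polarity (cochlear
    microphonic, stimulus artifact), leaving the polarity-insensitive neural
    response.
    """
    if pos.samples.shape != neg.samples.shape:
        raise ValueError("waveforms must have the same length")
    if pos.fs != neg.fs:
        raise ValueError("waveforms must share a sampling rate")
    return replace(pos, samples=0.5 * (pos.samples + neg.samples), polarity="averaged")


def cap_amplitude(
    w: EvokedWaveform, search_window_ms: tuple[float, float] = DEFAULT_CAP_WINDOW_MS
) -> float:
    """Peak-to-peak amplitude (µV) within a post-onset search window.

    The window is given in ms relative to stimulus onset and must lie within
    the record.
    """
    lo_ms, hi_ms = search_window_ms
    if hi_ms <= lo_ms:
        raise ValueError("search window must have positive extent")
    t_ms = w.times_s() * 1e3
    mask = (t_ms >= lo_ms) & (t_ms <= hi_ms)
    if not mask.any():
        raise ValueError("search window contains no samples")
    seg = w.samples[mask]
    return float(seg.max() - seg.min())


def cap_threshold(
    series: LevelSeries, criterion_uv: float = 10.0, monotonize: bool = True
) -> ThresholdResult:
    """Sound level (dB SPL) at which the CAP reaches the criterion amplitude.

    The growth function is monotonized by an isotonic fit if measurement noise
    made it non-monotone, then the threshold is the level at which the
    (linearly interpolated) amplitude equals ``criterion_uv``.  A level whose
    amplitude equals the criterion exactly is returned as-is.
    """
    order = np.argsort(series.levels)
    levels = series.levels[order]
    amps = series.amplitudes[order]
    if monotonize and np.any(np.diff(amps) < 0):
        amps = isotonic_regression(amps).x

    exact = np.flatnonzero(amps == criterion_uv)
    if exact.size:
        return ThresholdResult(float(levels[exact[0]]), "ok", criterion_uv)
    above = amps >= criterion_uv
    if not above.any():
        return ThresholdResult(math.nan, "no_threshold", criterion_uv)
    i = int(np.argmax(above))
    if i == 0:
        return ThresholdResult(float(levels[0]), "at_or_below_min", criterion_uv)
    frac = (criterion_uv - amps[i - 1]) / (amps[i] - amps[i - 1])
    return ThresholdResult(
        float(levels[i - 1] + frac * (levels[i] - levels[i - 1])), "ok", criterion_uv
    )


def anow_waveform(
    pos: EvokedWaveform,
    neg: EvokedWaveform,
    f_hz: float,
    trim_start_ms: float = 5.0,
    trim_end_ms: float = 8.3,
) -> EvokedWaveform:
    """Auditory Nerve Overlapped Waveform for a low-frequency tone burst.

    Half the sum of the two polarity responses (cancelling polarity-inverting
    components), with the onset/offset transients trimmed — the first 5 ms and
    final 8.3 ms of a 33.3 ms record, retaining 20 ms — and the retained
    segment ramped on and off with raised-cosine ramps of duration ``1/f`` s.
    """
    if f_hz <= 0:
        raise ValueError("f_hz must be positive")
    avg = average_alternating(pos, neg)
    fs = avg.fs
    n = avg.samples.size
    i0 = round(trim_start_ms * 1e-3 * fs)
    i1 = n - round(trim_end_ms * 1e-3 * fs)
    if i1 - i0 < 2:
        raise ValueError("record too short for the requested trims")
    kept = avg.samples[i0:i1].copy()
    retained_s = kept.size / fs
    ramp_s = 1.0 / f_hz
    if 2.0 * ramp_s >= retained_s:
        raise ValueError(
            f"ramps of {ramp_s * 1e3:.2f} ms overlap within the "
            f"{retained_s * 1e3:.1f} ms retained window"
        )
    n_ramp = round(ramp_s * fs)
    env = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    kept[:n_ramp] *= env
    kept[-n_ramp:] *= env[::-1]
    return replace(avg, samples=kept, t0=avg.t0 - i0 / fs, stim_freq_hz=f_hz)


def anow_magnitude(w: EvokedWaveform, f_hz: float | None = None) -> float:
    """RMS magnitude (µV) of the unramped interior of an ANOW waveform.

    The quantification of ANOW magnitude is not standardized; the RMS of the
    steady-state segment (excluding the 1/f ramps) is used here as a
    documented stand-in.
    """
    f = f_hz if f_hz is not None else w.stim_freq_hz
    if f is None or f <= 0:
        raise ValueError("tone frequency required to locate the ramps")
    n_ramp = round(w.fs / f)
    interior = w.samples[n_ramp : w.samples.size - n_ramp]
    if interior.size == 0:
        raise ValueError("no unramped interior")
    return float(np.sqrt(np.mean(interior**2)))


def bandpass(
    w: EvokedWaveform, lo_hz: float = 100.0, hi_hz: float = 3000.0, order: int = 4
) -> EvokedWaveform:
    """Zero-phase band-pass, mirroring the recording chain's 0.1–3 kHz filter."""
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=w.fs, output="sos")
    return replace(w, samples=sps.sosfiltfilt(sos, w.samples))


def cap_cycle_ms(
    burst_ms: float = 13.9, n_polarities: int = 2, n_silent: int = 3
) -> float:
    """Duration of one CAP stimulus cycle.

    One cycle holds a tone burst of each polarity interleaved with silent
    periods of the same duration: (2 + 3) x 13.9 ms = 69.5 ms by default.
    """
    return burst_ms * (n_polarities + n_silent)


def cap_repetition_rate(
    burst_ms: float = 13.9, n_polarities: int = 2, n_silent: int = 3
) -> float:
    """CAP stimulus repetition rate in cycles per second (14.39/s by default)."""
    return 1000.0 / cap_cycle_ms(burst_ms, n_polarities, n_silent)
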