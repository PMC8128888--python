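"""Otoacoustic-emission extraction: DPOAE, double-evoked SFOAE, noise floors.

Distortion-product OAEs are measured with a two-tone stimulus (f2/f1 = 1.22,
L1/L2 = 60/50 dB SPL) and read out at the cubic distortion frequency
2*f1 - f2.  Stimulus-frequency OAEs use the double-evoked paradigm: the
residual ``probe + suppressor - both`` cancels everything a linear system
produces, leaving the emission component that the suppressor (50 Hz above the
probe) removed from the combined condition.  Noise floors are the standard
error of the per-repetition amplitudes, converted to dB SPL.

Amplitudes are sinusoid peak amplitudes referenced directly to 20 µPa
(``dB = 20 log10(A / 20 µPa)``); the synthesizers in
:mod:`cochmap.simulate` share the convention, so injected levels round-trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PressureRecording",
    "P_REF_PA",
    "NOISE_FLOOR_CLAMP_DB",
    "pa_to_db_spl",
    "db_spl_to_pa",
    "tone_phasor",
    "tone_amplitude",
    "dpoae_frequency",
    "dpoae_amplitude",
    "sfoae_residual",
    "sfoae_amplitude",
    "noise_floor",
]

P_REF_PA = 20e-6
NOISE_FLOOR_CLAMP_DB = -120.0  # sentinel when repetition variance is numerically zero


@dataclass(frozen=True)
class PressureRecording:
    """Ear-canal pressure record in Pa with its stimulus descriptor."""

    samples: np.ndarray
    fs: float
    stimulus: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D array")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


def pa_to_db_spl(amplitude_pa: float) -> float:
    """Peak amplitude in Pa to dB SPL re 20 µPa; 0 maps to -inf."""
    if amplitude_pa <= 0:
        return -math.inf
    return 20.0 * math.log10(amplitude_pa / P_REF_PA)


def db_spl_to_pa(level_db: float) -> float:
    return P_REF_PA * 10.0 ** (level_db / 20.0)


def _analysis_slice(
    n: int, fs: float, f_hz: float, window_s: tuple[float, float] | None
) -> tuple[int, int]:
    """Start/stop indices truncated to an integer number of cycles of f."""
    if window_s is None:
        i0, i1 = 0, n
    else:
        i0 = int(round(window_s[0] * fs))
        i1 = int(round(window_s[1] * fs))
        if not 0 <= i0 < i1 <= n:
            raise ValueError("analysis window outside the record")
    n_win = i1 - i0
    n_cycles = math.floor(n_win * f_hz / fs)
    if n_cycles < 1:
        raise ValueError(
            f"analysis window shorter than one cycle of {f_hz} Hz"
        )
    n_keep = int(math.floor(n_cycles * fs / f_hz))
    return i0, i0 + n_keep


def tone_phasor(
    rec: PressureRecording, f_hz: float, window_s: tuple[float, float] | None = None
) -> complex:
    """Complex amplitude (peak Pa) of the least-squares sinusoid at ``f_hz``.

    The window is truncated to an integer number of cycles so that the fit is
    orthogonal to DC and to any other integer-cycle component.  The phasor is
    ``a - i b`` for a fit ``a cos + b sin``, i.e. the signal is
    ``Re{phasor * exp(i 2 pi f t)}``.
    """
    if f_hz <= 0:
        raise ValueError("f_hz must be positive")
    if f_hz >= rec.fs / 2:
        raise ValueError("f_hz must be below the Nyquist frequency")
    i0, i1 = _analysis_slice(rec.samples.size, rec.fs, f_hz, window_s)
    seg = rec.samples[i0:i1]
    t = np.arange(i0, i1) / rec.fs
    w = 2.0 * np.pi * f_hz
    design = np.column_stack([np.cos(w * t), np.sin(w * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, seg, rcond=None)
    return complex(coef[0], -coef[1])


def tone_amplitude(
    rec: PressureRecording, f_hz: float, window_s: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Amplitude (dB SPL) and phase (rad) of the tone at exactly ``f_hz``."""
    phasor = tone_phasor(rec, f_hz, window_s)
    return pa_to_db_spl(abs(phasor)), math.atan2(phasor.imag, phasor.real)


def dpoae_frequency(f1_hz: float, f2_hz: float) -> float:
    """Cubic distortion-product frequency 2*f1 - f2."""
    if not f1_hz < f2_hz:
        raise ValueError("requires f1 < f2")
    return 2.0 * f1_hz - f2_hz


def dpoae_amplitude(
    recs: Sequence[PressureRecording],
    f1_hz: float,
    f2_hz: float,
    window_s: tuple[float, float] | None = None,
    ratio_tol: float = 0.05,
    expected_ratio: float = 1.22,
    noise_mode: Literal["complex", "magnitude"] = "complex",
) -> tuple[float, float]:
    """DPOAE amplitude at 2*f1 - f2 and its noise floor, both in dB SPL.

    The repetitions are averaged coherently before the amplitude fit; the
    noise floor is the standard error of the per-repetition phasors (see
    :func:`noise_floor`).
    """
    if len(recs) < 2:
        raise ValueError("need >= 2 repetitions for a DPOAE noise floor")
    if abs(f2_hz / f1_hz - expected_ratio) > ratio_tol:
        raise ValueError(
            f"f2/f1 = {f2_hz / f1_hz:.3f} outside {expected_ratio} +/- {ratio_tol}"
        )
    fdp = dpoae_frequency(f1_hz, f2_hz)
    n = min(r.samples.size for r in recs)
    fs = recs[0].fs
    if any(r.fs != fs for r in recs):
        raise ValueError("repetitions must share a sampling rate")
    mean_rec = PressureRecording(
        np.mean([r.samples[:n] for r in recs], axis=0), fs, dict(recs[0].stimulus)
    )
    amp_db, _ = tone_amplitude(mean_rec, fdp, window_s)
    phasors = [tone_phasor(PressureRecording(r.samples[:n], fs), fdp, window_s)
               for r in recs]
    return amp_db, noise_floor(phasors, mode=noise_mode)


def sfoae_residual(
    probe_alone: PressureRecording,
    suppressor_alone: PressureRecording,
    both: PressureRecording,
) -> PressureRecording:
    """Double-evoked residual ``probe + suppressor - both``.

    Exactly zero for a linear ear; what survives is the emission component
    present with the probe alone but suppressed in the combined condition.
    """
    n = probe_alone.samples.size
    if suppressor_alone.samples.size != n or both.samples.size != n:
        raise ValueError("conditions must have equal length")
    if not probe_alone.fs == suppressor_alone.fs == both.fs:
        raise ValueError("conditions must share a sampling rate")
    res = probe_alone.samples + suppressor_alone.samples - both.samples
    return PressureRecording(res, probe_alone.fs, {"condition": "residual"})


def sfoae_amplitude(
    probe_alone: PressureRecording,
    suppressor_alone: PressureRecording,
    both: PressureRecording,
    probe_f_hz: float,
    window_s: tuple[float, float] | None = None,
) -> float:
    """SFOAE amplitude (dB SPL): the residual's component at the probe frequency."""
    res = sfoae_residual(probe_alone, suppressor_alone, both)
    amp_db, _ = tone_amplitude(res, probe_f_hz, window_s)
    return amp_db


def noise_floor(
    repetition_amplitudes: Sequence[complex] | np.ndarray,
    mode: Literal["complex", "magnitude"] = "complex",
) -> float:
    """Standard error of per-repetition amplitudes, converted to dB SPL.

    In "complex" mode (default) the SE combines the real and imaginary parts,
    which is the noise level contaminating the coherent mean; "magnitude"
    mode takes the SE of the magnitudes instead.  Identical repetitions give
    an SE of zero, reported as the clamp sentinel (-120 dB SPL).
    """
    amps = np.asarray(repetition_amplitudes)
    n = amps.size
    if n < 2:
        raise ValueError("need >= 2 repetitions")
    if mode == "complex":
        se = math.sqrt(
            (np.var(amps.real, ddof=1) + np.var(amps.imag, ddof=1)) / n
        )
    elif mode == "magnitude":
        se = float(np.std(np.abs(amps), ddof=1) / math.sqrt(n))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if se <= P_REF_PA * 10 ** (NOISE_FLOOR_CLAMP_DB / 20.0):
        return NOISE_FLOOR_CLAMP_DB
    return pa_to_db_spl(se)
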