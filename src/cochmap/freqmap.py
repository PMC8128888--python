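"""Cochlear frequency-place map and perfusion-front kinematics.

The guinea-pig cochlea maps characteristic frequency (CF) to position along
the basilar membrane following a Greenwood-type law

    CF(x) = A * (10**(a * x / L) - k)        [kHz]

with ``x`` the distance from the *apical* end in mm.  During an apex-to-base
perfusion at constant flow speed ``v`` (mm/min along scala tympani) the
neurotoxin front is at ``x(t) = v * (t - t0)``, so the perfusion time at which
a tone-evoked response collapses can be translated into the cochlear place,
and hence the CF, of the response's origin.

Distances are always measured from the apex because the perfusion runs
apex-to-base; beware sources that quote the same map base-referenced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrequencyPlaceMap",
    "PerfusionModel",
    "place_from_time",
    "time_from_place",
    "cf_from_place",
    "place_from_cf",
    "cf_from_time",
    "time_from_cf",
    "minutes_per_octave",
    "octave_shift",
]


@dataclass(frozen=True)
class FrequencyPlaceMap:
    """Parametric CF-versus-place map of the guinea-pig cochlea.

    Parameters
    ----------
    scale_khz
        Frequency scale factor ``A`` in kHz.
    slope_decades
        Decades of frequency spanned over the full cochlear length (``a``).
    offset
        Dimensionless integration constant ``k``; ``k > 0`` flattens the map
        toward the apex.
    length_mm
        Cochlear length ``L`` in mm.
    """

    scale_khz: float = 0.35
    slope_decades: float = 2.1
    offset: float = 0.85
    length_mm: float = 18.5

    def __post_init__(self) -> None:
        if self.scale_khz <= 0 or self.slope_decades <= 0 or self.length_mm <= 0:
            raise ValueError("scale_khz, slope_decades and length_mm must be positive")
        if not 0 <= self.offset < 1:
            # k >= 1 would make CF(0) <= 0
            raise ValueError("offset k must lie in [0, 1)")

    @property
    def cf_apex_khz(self) -> float:
        """CF at the apical end, ``A * (1 - k)``."""
        return self.scale_khz * (1.0 - self.offset)

    @property
    def cf_base_khz(self) -> float:
        """CF at the basal end, ``CF(L)``."""
        return float(cf_from_place(self.length_mm, self))


@dataclass(frozen=True)
class PerfusionModel:
    """Constant-speed perfusion front along scala tympani.

    ``start_offset_min`` is the dead time between the nominal perfusion start
    and the front entering the mapped region (0 by default: the pump schedule
    is servo-controlled to hold the front speed constant from t = 0).
    """

    flow_mm_per_min: float = 0.5
    start_offset_min: float = 0.0

    def __post_init__(self) -> None:
        if self.flow_mm_per_min <= 0:
            raise ValueError("flow_mm_per_min must be positive")
        if self.start_offset_min < 0:
            raise ValueError("start_offset_min must be non-negative")


def place_from_time(t_min, model: PerfusionModel = PerfusionModel()):
    """Front position (mm from apex) at perfusion time ``t_min`` minutes."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < model.start_offset_min):
        raise ValueError(
            f"t_min < start_offset_min ({model.start_offset_min}): "
            "front has not entered the cochlea"
        )
    x = (t - model.start_offset_min) * model.flow_mm_per_min
    return x if x.ndim else float(x)


def time_from_place(x_mm, model: PerfusionModel = PerfusionModel()):
    """Perfusion time (min) at which the front reaches ``x_mm`` from the apex."""
    x = np.asarray(x_mm, dtype=float)
    if np.any(x < 0):
        raise ValueError("x_mm must be non-negative")
    t = x / model.flow_mm_per_min + model.start_offset_min
    return t if t.ndim else float(t)


def cf_from_place(x_mm, fmap: FrequencyPlaceMap = FrequencyPlaceMap()):
    """Characteristic frequency (kHz) at ``x_mm`` from the apex."""
    x = np.asarray(x_mm, dtype=float)
    if np.any(x < 0) or np.any(x > fmap.length_mm):
        raise ValueError(f"x_mm outside [0, {fmap.length_mm}] mm")
    cf = fmap.scale_khz * (
        np.power(10.0, fmap.slope_decades * x / fmap.length_mm) - fmap.offset
    )
    return cf if cf.ndim else float(cf)


def place_from_cf(f_khz, fmap: FrequencyPlaceMap = FrequencyPlaceMap()):
    """Analytic inverse of the map: place (mm from apex) of CF ``f_khz``."""
    f = np.asarray(f_khz, dtype=float)
    if np.any(f < fmap.cf_apex_khz * (1.0 - 1e-12)):
        raise ValueError(f"f_khz below apical CF {fmap.cf_apex_khz:.4g} kHz")
    x = (fmap.length_mm / fmap.slope_decades) * np.log10(f / fmap.scale_khz + fmap.offset)
    x = np.clip(x, 0.0, None)
    return x if x.ndim else float(x)


def cf_from_time(
    t_min,
    model: PerfusionModel = PerfusionModel(),
    fmap: FrequencyPlaceMap = FrequencyPlaceMap(),
):
    """CF (kHz) of the place the perfusion front occupies at ``t_min``."""
    return cf_from_place(place_from_time(t_min, model), fmap)


def time_from_cf(
    f_khz,
    model: PerfusionModel = PerfusionModel(),
    fmap: FrequencyPlaceMap = FrequencyPlaceMap(),
):
    """Perfusion time (min) at which the front reaches the CF place of ``f_khz``."""
    return time_from_place(place_from_cf(f_khz, fmap), model)


def minutes_per_octave(
    model: PerfusionModel = PerfusionModel(),
    fmap: FrequencyPlaceMap = FrequencyPlaceMap(),
) -> float:
    """Minutes of perfusion per octave of CF, in the exponential regime.

    For the pure exponential part of the map (CF >> A*k) an octave spans
    ``L * log10(2) / a`` mm, a constant, so at flow ``v`` the front crosses one
    octave every ``L * log10(2) / (a * v)`` minutes.  Near the apex the offset
    ``k`` compresses octaves slightly; this function returns the basal
    (asymptotic) constant used for rule-of-thumb conversions.
    """
    mm_per_octave = fmap.length_mm * math.log10(2.0) / fmap.slope_decades
    return mm_per_octave / model.flow_mm_per_min


def octave_shift(
    t_reference,
    t_test,
    model: PerfusionModel = PerfusionModel(),
    fmap: FrequencyPlaceMap = FrequencyPlaceMap(),
):
    """Octave shift of CF place between two perfusion times.

    Positive when ``t_test`` is earlier than ``t_reference``, i.e. the test
    response collapsed sooner and therefore originated more apically, at a
    lower CF, than the reference.
    """
    shift = np.log2(
        np.asarray(cf_from_time(t_reference, model, fmap))
        / np.asarray(cf_from_time(t_test, model, fmap))
    )
    return shift if shift.ndim else float(shift)
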