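"""Amplitude-versus-perfusion-time trajectories and reduction-time tuning curves.

As the neurotoxin front travels apex-to-base it silences auditory-nerve
excitation at successively more basal (higher-CF) places, so the CAP evoked
by a given tone collapses over a window of perfusion time.  The perfusion
times at which the normalized amplitude falls to 80%, 50% and 20% of its
pre-perfusion baseline delimit, respectively, the apical edge, the centre and
the basal edge of the cochlear region generating the response.  Collected
across stimulus levels these form a *reduction-time tuning curve*: the 50%
time of the threshold-level (10 dB SL) response is the tip, and each higher
level contributes an (80%, 20%) edge pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AmplitudeTimeSeries",
    "ReductionTimeTuningCurve",
    "normalize_to_baseline",
    "reduction_time",
    "build_tuning_curve",
    "group_average_tc",
    "reduction_time_table",
]

BASELINE_WINDOW_MIN = (-5.0, 5.0)
TIP_LEVEL_DB_SL = 10.0


@dataclass(frozen=True)
class AmplitudeTimeSeries:
    """CAP amplitude trajectory over perfusion time for one ear/frequency/level.

    ``amplitudes`` are raw µV peak-to-peak until :func:`normalize_to_baseline`
    is applied, after which they are unitless fractions of the pre-perfusion
    baseline and ``normalized`` is True.
    """

    ear_id: str
    group: Literal["operated", "control"]
    freq_khz: float
    level_db_sl: float
    times_min: np.ndarray
    amplitudes: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "amplitudes", a)
        if t.shape != a.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("times and amplitudes must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times_min must be strictly increasing")
        if self.group not in ("operated", "control"):
            raise ValueError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class ReductionTimeTuningCurve:
    """80/50/20% reduction times across levels for one ear and tone frequency.

    ``tip_time_min`` is the 50% time at 10 dB SL.  ``edges`` maps each higher
    level (dB SL) to its (t80, t20) pair, t80 <= t20.
    """

    ear_id: str
    group: str
    freq_khz: float
    tip_time_min: float
    edges: dict[float, tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ear_id": self.ear_id,
                "group": self.group,
                "freq_khz": self.freq_khz,
                "level_db_sl": TIP_LEVEL_DB_SL,
                "point": "t50",
                "time_min": self.tip_time_min,
            }
        ]
        for level, (t80, t20) in sorted(self.edges.items()):
            for point, t in (("t80", t80), ("t20", t20)):
                rows.append(
                    {
                        "ear_id": self.ear_id,
                        "group": self.group,
                        "freq_khz": self.freq_khz,
                        "level_db_sl": level,
                        "point": point,
                        "time_min": t,
                    }
                )
        return pd.DataFrame(rows)


def normalize_to_baseline(
    series: AmplitudeTimeSeries,
    window_min: tuple[float, float] = BASELINE_WINDOW_MIN,
) -> AmplitudeTimeSeries:
    """Divide amplitudes by their mean over the baseline window (−5 to +5 min).

    At 0.5 mm/min the front needs >10 min to reach even the 2 kHz place, so
    samples in this window still reflect the intact cochlea.
    """
    lo, hi = window_min
    mask = (series.times_min >= lo) & (series.times_min <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"need >= 2 baseline samples in [{lo}, {hi}] min, found {int(mask.sum())}"
        )
    baseline = float(series.amplitudes[mask].mean())
    if baseline <= 0:
        raise ValueError("baseline mean must be positive")
    return replace(series, amplitudes=series.amplitudes / baseline, normalized=True)


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p / (1.0 - p))


def reduction_time(
    series: AmplitudeTimeSeries,
    fraction: float,
    k_sustained: int = 2,
    interpolation: Literal["logit", "linear"] = "logit",
    median3: bool = False,
) -> float:
    """Perfusion time (min) at which the normalized amplitude falls to ``fraction``.

    The crossing must be *sustained*: the first sample below ``fraction`` that
    stays below for at least ``k_sustained`` consecutive samples marks the
    crossing, which rejects single-sample noise dips.  The crossing time is
    interpolated between the bracketing samples — by default on the logit
    scale, which is exact for logistic declines and reduces to the linear rule
    whenever a bracketing amplitude lies outside (0, 1).  A sample exactly at
    ``fraction`` (before any sustained crossing) is taken at face value.

    Returns NaN when the trajectory never sustains a crossing.  A crossing at
    or before the first sample, or before perfusion start, is flagged with a
    warning (the front cannot have caused it).
    """
    if not series.normalized:
        raise ValueError("series must be normalized to baseline first")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if k_sustained < 1:
        raise ValueError("k_sustained must be >= 1")
    t = series.times_min
    a = series.amplitudes
    if median3:
        a = _median3(a)

    n = a.size
    idx = None
    for i in range(n):
        if a[i] == fraction:
            return float(t[i])
        if a[i] < fraction and np.all(a[i : i + k_sustained] < fraction):
            idx = i
            break
    if idx is None:
        return math.nan
    if idx == 0:
        warnings.warn(
            f"{series.ear_id} {series.freq_khz} kHz: already below "
            f"{fraction:.0%} at the first sample",
            stacklevel=2,
        )
        return float(t[0])

    t0, t1 = t[idx - 1], t[idx]
    a0, a1 = a[idx - 1], a[idx]
    if interpolation == "logit" and 0.0 < a1 < 1.0 and 0.0 < a0 < 1.0:
        g0, g1, gf = _logit(a0), _logit(a1), _logit(fraction)
        tc = t0 + (t1 - t0) * (g0 - gf) / (g0 - g1)
    else:
        tc = t0 + (t1 - t0) * (a0 - fraction) / (a0 - a1)
    if tc < 0:
        warnings.warn(
            f"{series.ear_id} {series.freq_khz} kHz: {fraction:.0%} crossing "
            f"at {tc:.2f} min precedes perfusion start",
            stacklevel=2,
        )
    return float(tc)


def _median3(a: np.ndarray) -> np.ndarray:
    out = a.copy()
    if a.size >= 3:
        stacked = np.stack([a[:-2], a[1:-1], a[2:]])
        out[1:-1] = np.median(stacked, axis=0)
    return out


def build_tuning_curve(
    series_set: Iterable[AmplitudeTimeSeries],
    k_sustained: int = 2,
    interpolation: Literal["logit", "linear"] = "logit",
) -> ReductionTimeTuningCurve:
    """Assemble a reduction-time tuning curve for one ear x frequency.

    Requires the 10 dB SL series (the tip); each higher level contributes a
    (t80, t20) edge pair.  Levels where either crossing cannot be determined
    are omitted with a warning, mirroring the exclusion of edges whose SNR was
    insufficient.
    """
    by_level: dict[float, AmplitudeTimeSeries] = {}
    ear_id = group = None
    freq = None
    for s in series_set:
        if ear_id is None:
            ear_id, group, freq = s.ear_id, s.group, s.freq_khz
        elif (s.ear_id, s.freq_khz) != (ear_id, freq):
            raise ValueError("all series must belong to one ear and frequency")
        norm = s if s.normalized else normalize_to_baseline(s)
        by_level[s.level_db_sl] = norm
    if TIP_LEVEL_DB_SL not in by_level:
        raise ValueError(f"missing the {TIP_LEVEL_DB_SL:g} dB SL (tip) series")

    tip = reduction_time(by_level[TIP_LEVEL_DB_SL], 0.5, k_sustained, interpolation)
    if math.isnan(tip):
        raise ValueError(f"{ear_id} {freq} kHz: no 50% reduction at the tip level")

    edges: dict[float, tuple[float, float]] = {}
    for level in sorted(by_level):
        if level == TIP_LEVEL_DB_SL:
            continue
        t80 = reduction_time(by_level[level], 0.8, k_sustained, interpolation)
        t20 = reduction_time(by_level[level], 0.2, k_sustained, interpolation)
        if math.isnan(t80) or math.isnan(t20):
            warnings.warn(
                f"{ear_id} {freq} kHz {level:g} dB SL: missing 80% or 20% "
                "crossing; level omitted",
                stacklevel=2,
            )
            continue
        if t80 > t20:
            warnings.warn(
                f"{ear_id} {freq} kHz {level:g} dB SL: edge order inverted by "
                "noise; reordered",
                stacklevel=2,
            )
            t80, t20 = t20, t80
        edges[level] = (t80, t20)
    return ReductionTimeTuningCurve(ear_id, group, freq, tip, edges)


def group_average_tc(
    tcs: Sequence[ReductionTimeTuningCurve], group: str | None = None
) -> pd.DataFrame:
    """Average tuning curves across ears, per level and point (t80/t50/t20).

    Returns one row per (level, point) with mean, SEM and the number of ears
    contributing; the SEM needs at least 2 values and is NaN otherwise.
    """
    if group is not None:
        tcs = [tc for tc in tcs if tc.group == group]
    if not tcs:
        raise ValueError("no tuning curves to average")
    long = pd.concat([tc.to_frame() for tc in tcs], ignore_index=True)
    out = (
        long.groupby(["freq_khz", "level_db_sl", "point"])["time_min"]
        .agg(mean_min="mean", sem_min=lambda v: v.sem() if len(v) > 1 else math.nan,
             n="count")
        .reset_index()
    )
    return out


def reduction_time_table(
    series_iterable: Iterable[AmplitudeTimeSeries],
    fraction: float = 0.5,
    level_db_sl: float = TIP_LEVEL_DB_SL,
    k_sustained: int = 2,
    interpolation: Literal["logit", "linear"] = "logit",
) -> pd.DataFrame:
    """Extract the 50% reduction times at the tip level for every ear x frequency.

    Returns a tidy frame (ear_id, group, freq_khz, t50_min), the input to the
    permutation tests.
    """
    rows = []
    for s in series_iterable:
        if s.level_db_sl != level_db_sl:
            continue
        norm = s if s.normalized else normalize_to_baseline(s)
        rows.append(
            {
                "ear_id": s.ear_id,
                "group": s.group,
                "freq_khz": s.freq_khz,
                "t50_min": reduction_time(norm, fraction, k_sustained, interpolation),
            }
        )
    if not rows:
        raise ValueError(f"no series at {level_db_sl:g} dB SL")
    return pd.DataFrame(rows)
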