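"""Synthetic apex-to-base perfusion experiments.

Generates data with the statistical structure of the animal study so every
pipeline stage is testable without recordings: a 5-operated / 8-control ear
cohort, per-frequency 50% reduction times centred on the perfusion-front
arrival time at each tone's CF place, apical (earlier) shifts in the operated
group, ear-level offsets shared across frequency (inducing the strong
across-frequency correlation seen in real ears), a non-responder mechanism so
that some operated ears can be control-like at all frequencies, sigmoidal
amplitude declines, and additive measurement noise.

The configured ``group_shift_min`` values are *group-mean* shifts: each
responding operated ear is shifted by ``shift / responder_prob`` so that the
expected control-minus-operated group difference equals the configured value
regardless of the responder probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import freqmap
from .config import SimulationConfig
from .freqmap import FrequencyPlaceMap, PerfusionModel
from .oae import PressureRecording, db_spl_to_pa
from .permutation import ReductionTimeTable
from .reduction import AmplitudeTimeSeries
from .signals import EvokedWaveform

__all__ = [
    "SyntheticStudy",
    "simulate_t50_table",
    "simulate_trajectories",
    "simulate_waveforms",
    "cap_waveform_pair",
    "make_dpoae_recordings",
    "make_sfoae_recordings",
]

LN4 = math.log(4.0)


@dataclass(frozen=True)
class SyntheticStudy:
    """One simulated perfusion experiment.

    ``table`` holds the ground-truth 50% reduction times (the trajectory
    centres); ``truth`` is a per-ear frame with group, responder flag and the
    shared ear offset; ``series`` are the noisy amplitude trajectories from
    which the pipeline re-extracts reduction times.
    """

    series: list[AmplitudeTimeSeries]
    table: ReductionTimeTable
    truth: pd.DataFrame
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        """Long-format trajectory table (the CSV consumed by `extract`)."""
        frames = []
        for s in self.series:
            frames.append(
                pd.DataFrame(
                    {
                        "ear_id": s.ear_id,
                        "group": s.group,
                        "freq_khz": s.freq_khz,
                        "level_db_sl": s.level_db_sl,
                        "time_min": s.times_min,
                        "amplitude_uv": s.amplitudes,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _draw_noise(rng: np.random.Generator, sd: float, size, tail: str) -> np.ndarray:
    if sd == 0:
        return np.zeros(size)
    if tail == "laplace":
        return rng.laplace(0.0, sd / math.sqrt(2.0), size)
    return rng.normal(0.0, sd, size)


def simulate_t50_table(
    cfg: SimulationConfig,
    fmap: FrequencyPlaceMap = FrequencyPlaceMap(),
    model: PerfusionModel = PerfusionModel(),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[ReductionTimeTable, pd.DataFrame]:
    """Draw a ground-truth 50% reduction-time table.

    t50(ear, f) = arrival_time(f) + u_ear - operated * z_ear * shift_f / p + eps
    with u_ear ~ N(0, ear_sd^2) shared across frequency, z_ear the responder
    flag (Bernoulli(p), or exactly ``n_nonresponders`` zeros when configured)
    and eps ~ N(0, resid_sd^2) independent per cell.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_op, n_ctrl = cfg.n_operated, cfg.n_control
    n_ears = n_op + n_ctrl
    freqs = np.asarray(cfg.freqs_khz)
    shifts = np.asarray(cfg.group_shift_min)

    arrival = np.asarray(freqmap.time_from_cf(freqs, model, fmap))
    u = rng.normal(0.0, cfg.ear_sd_min, n_ears) if cfg.ear_sd_min else np.zeros(n_ears)

    if cfg.n_nonresponders is not None:
        z = np.ones(n_op)
        z[rng.choice(n_op, size=cfg.n_nonresponders, replace=False)] = 0.0
    else:
        z = (rng.random(n_op) < cfg.responder_prob).astype(float)
    eff_shift = shifts / cfg.responder_prob if cfg.responder_prob > 0 else shifts * 0.0

    eps = (
        rng.normal(0.0, cfg.resid_sd_min, (n_ears, freqs.size))
        if cfg.resid_sd_min
        else np.zeros((n_ears, freqs.size))
    )
    t50 = arrival[None, :] + u[:, None] + eps
    t50[:n_op] -= z[:, None] * eff_shift[None, :]

    ear_ids = tuple(
        [f"op{i + 1}" for i in range(n_op)] + [f"ct{i + 1}" for i in range(n_ctrl)]
    )
    groups = tuple(["operated"] * n_op + ["control"] * n_ctrl)
    table = ReductionTimeTable(ear_ids, groups, tuple(float(f) for f in freqs), t50)
    truth = pd.DataFrame(
        {
            "ear_id": ear_ids,
            "group": groups,
            "responder": list(z.astype(bool)) + [True] * n_ctrl,
            "ear_offset_min": u,
        }
    )
    return table, truth


def _trajectory(
    times: np.ndarray, center: float, s_lo: float, s_hi: float
) -> np.ndarray:
    """Two-sided logistic decline: slope s_lo before the centre, s_hi after.

    Continuous at the centre (value 0.5); t80 = c - s_lo*ln4, t20 = c + s_hi*ln4.
    """
    s = np.where(times < center, s_lo, s_hi)
    return 1.0 / (1.0 + np.exp((times - center) / s))


def simulate_trajectories(
    cfg: SimulationConfig,
    fmap: FrequencyPlaceMap = FrequencyPlaceMap(),
    model: PerfusionModel = PerfusionModel(),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    levels_db_sl: tuple[float, ...] | None = None,
) -> SyntheticStudy:
    """Simulate raw amplitude trajectories for every ear x frequency x level.

    Each trajectory is a logistic decline centred on the ear's ground-truth
    t50, sampled on the configured ~1-min grid, scaled to the baseline µV
    amplitude, with additive amplitude noise.  At levels above 10 dB SL the
    response region widens: the 80% point moves earlier by
    ``delta_lo * (SL-10)/10`` min and the 20% point later by
    ``delta_hi * (SL-10)/10`` min, with the basal (20%) side moving more.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    table, truth = simulate_t50_table(cfg, fmap, model, rng=rng)
    levels = levels_db_sl if levels_db_sl is not None else cfg.levels_db_sl
    n_steps = int(round((cfg.t_stop_min - cfg.t_start_min) / cfg.dt_min)) + 1
    times = cfg.t_start_min + cfg.dt_min * np.arange(n_steps)
    s0 = cfg.logistic_slope_min

    series: list[AmplitudeTimeSeries] = []
    for i, ear in enumerate(table.ear_ids):
        for j, f in enumerate(table.freqs_khz):
            c = table.t50[i, j]
            for level in levels:
                widen = max(level - 10.0, 0.0) / 10.0
                s_lo = s0 + cfg.delta_lo_min_per_10db * widen / LN4
                s_hi = s0 + cfg.delta_hi_min_per_10db * widen / LN4
                a = _trajectory(times, c, s_lo, s_hi)
                a = a + _draw_noise(rng, cfg.noise_sd, a.shape, cfg.noise_tail)
                series.append(
                    AmplitudeTimeSeries(
                        ear_id=ear,
                        group=table.groups[i],
                        freq_khz=f,
                        level_db_sl=float(level),
                        times_min=times.copy(),
                        amplitudes=cfg.baseline_uv * a,
                    )
                )
    return SyntheticStudy(series=series, table=table, truth=truth, config=cfg)


def _biphasic_template(fs: float, onset_s: float, dur_s: float) -> np.ndarray:
    """Unit-normalized N1/P1 CAP shape: negative trough then positive peak."""
    t = np.arange(round(dur_s * fs)) / fs
    shape = -np.exp(-(((t - onset_s - 1.2e-3) / 0.35e-3) ** 2)) + 0.7 * np.exp(
        -(((t - onset_s - 2.2e-3) / 0.55e-3) ** 2)
    )
    return shape / (shape.max() - shape.min())


def cap_waveform_pair(
    amplitude_uv: float,
    stim_freq_hz: float = 4000.0,
    fs: float = 96_000.0,
    dur_s: float = 0.0139,
    cm_uv: float = 5.0,
    noise_uv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[EvokedWaveform, EvokedWaveform]:
    """Condensation/rarefaction CAP pair with a polarity-inverting component.

    The neural template (peak-to-peak ``amplitude_uv``) is common to both
    polarities; a cochlear-microphonic-like sinusoid at the stimulus frequency
    inverts between them and cancels under alternating-polarity averaging.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    neural = amplitude_uv * _biphasic_template(fs, onset_s=0.0, dur_s=dur_s)
    t = np.arange(neural.size) / fs
    cm = cm_uv * np.sin(2.0 * np.pi * stim_freq_hz * t)
    make = lambda sign, pol: EvokedWaveform(
        neural + sign * cm + (rng.normal(0, noise_uv, neural.size) if noise_uv else 0.0),
        fs=fs,
        stim_freq_hz=stim_freq_hz,
        polarity=pol,
    )
    return make(+1.0, "condensation"), make(-1.0, "rarefaction")


def make_dpoae_recordings(
    f1_hz: float = 1000.0,
    f2_hz: float = 1220.0,
    l1_db: float = 60.0,
    l2_db: float = 50.0,
    emission_db: float = 20.0,
    n_reps: int = 12,
    fs: float = 96_000.0,
    dur_s: float = 1.0,
    noise_pa: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[PressureRecording]:
    """Ear-canal recordings of the two-tone DPOAE stimulus plus an injected
    emission at 2*f1 - f2, with optional independent noise per repetition."""
    if rng is None:
        rng = np.random.default_rng(0)
    t = np.arange(round(dur_s * fs)) / fs
    fdp = 2.0 * f1_hz - f2_hz
    base = (
        db_spl_to_pa(l1_db) * np.cos(2 * np.pi * f1_hz * t)
        + db_spl_to_pa(l2_db) * np.cos(2 * np.pi * f2_hz * t)
        + db_spl_to_pa(emission_db) * np.cos(2 * np.pi * fdp * t)
    )
    stim = {"f1_hz": f1_hz, "f2_hz": f2_hz, "L1_db": l1_db, "L2_db": l2_db}
    out = []
    for _ in range(n_reps):
        noise = rng.normal(0.0, noise_pa, t.size) if noise_pa else 0.0
        out.append(PressureRecording(base + noise, fs, dict(stim)))
    return out


def _ramped_tone(
    f_hz: float, level_db: float, t: np.ndarray, fs: float, rise_s: float = 0.010
) -> np.ndarray:
    tone = db_spl_to_pa(level_db) * np.cos(2 * np.pi * f_hz * t)
    n_ramp = round(rise_s * fs)
    env = np.ones_like(t)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    env[:n_ramp] = ramp
    env[-n_ramp:] = ramp[::-1]
    return tone * env


def make_sfoae_recordings(
    probe_f_hz: float = 4000.0,
    probe_db: float = 40.0,
    suppressor_offset_hz: float = 50.0,
    suppressor_db: float = 60.0,
    emission_db: float = 0.0,
    fs: float = 96_000.0,
    dur_s: float = 0.25,
    rise_s: float = 0.010,
    noise_pa: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[PressureRecording, PressureRecording, PressureRecording]:
    """Double-evoked SFOAE condition triple (probe, suppressor, both).

    The ear is linear except for an emission at the probe frequency that is
    present with the probe alone and fully suppressed when the suppressor
    (``probe + 50`` Hz, 60 dB SPL) is also on — so the residual recovers it.
    Set ``emission_db=-inf`` (or a huge negative value) for a strictly linear
    ear.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    t = np.arange(round(dur_s * fs)) / fs
    sup_f = probe_f_hz + suppressor_offset_hz
    probe = _ramped_tone(probe_f_hz, probe_db, t, fs, rise_s)
    sup = _ramped_tone(sup_f, suppressor_db, t, fs, rise_s)
    emission = (
        db_spl_to_pa(emission_db) * np.cos(2 * np.pi * probe_f_hz * t + 1.0)
        if np.isfinite(emission_db)
        else np.zeros_like(t)
    )

    def rec(samples: np.ndarray, condition: str) -> PressureRecording:
        noise = rng.normal(0.0, noise_pa, t.size) if noise_pa else 0.0
        return PressureRecording(
            samples + noise,
            fs,
            {"probe_f_hz": probe_f_hz, "suppressor_f_hz": sup_f, "condition": condition},
        )

    return (
        rec(probe + emission, "probe_alone"),
        rec(sup, "suppressor_alone"),
        rec(probe + sup, "both"),
    )


def simulate_waveforms(cfg: SimulationConfig | None = None, seed: int = 0) -> dict:
    """Deterministic waveform fixtures for the signal/OAE modules.

    Returns CAP polarity pairs at two scales, a DPOAE repetition set and an
    SFOAE condition triple, all generated from one seeded stream.
    """
    rng = np.random.default_rng(seed)
    cap_full = cap_waveform_pair(50.0, rng=rng)
    cap_half = cap_waveform_pair(25.0, rng=rng)
    return {
        "cap_pair_50uv": cap_full,
        "cap_pair_25uv": cap_half,
        "dpoae_reps": make_dpoae_recordings(noise_pa=2e-5, rng=rng),
        "sfoae_triple": make_sfoae_recordings(emission_db=0.0, rng=rng),
        "seed": seed,
    }
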