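# Methods

This note documents the models, estimators and numerical choices behind
`cochmap`, and what the synthetic-data generator does and does not emulate.

## Frequency-place map and perfusion kinematics

The guinea-pig map is the Greenwood form `CF(x) = A·(10^(a·x/L) − k)` with
defaults `A = 0.35` kHz, `a = 2.1` decades, `k = 0.85`, `L = 18.5` mm and `x`
measured in mm **from the apex** (the perfusion direction; many map sources
quote base-referenced distances — convert before overriding the defaults).
The constants are the standard guinea-pig parameterization; they reproduce
the two rule-of-thumb conversions this workflow relies on: at a front speed
of 0.5 mm/min, `minutes_per_octave` = `L·log₁₀2/(a·v)` ≈ 5.30 min/octave
(≈ 5), and a 50% reduction time 5 min earlier than normal corresponds to
≈ 1 octave (0.99 at an 8 kHz reference CF) more apical place.

Two caveats are intrinsic to the `k > 0` offset. First, octave spacing is
only asymptotically constant: `minutes_per_octave` returns the basal
(exponential-regime) constant, while `octave_shift` evaluates the exact CF
ratio and therefore gives slightly larger shifts near the apex (the identity
`minutes_per_octave × octave_shift = Δt` is exact only on a `k = 0` map, and
is property-tested in exactly that form). Second, `CF(0) = A(1−k) > 0`, so
`place_from_cf` is only defined down to the apical CF.

The perfusion model is a sharp front at constant speed `v` with an optional
dead time (`start_offset_min`, default 0). Non-constant flow profiles and
scala-area corrections are out of scope: hydrops does not change the scala
tympani cross-section, so constant pump-rate servoing to constant front
speed is the appropriate abstraction.

## Waveform measures

CAP amplitude is max − min within a configurable post-onset search window
(default 0.5–6 ms, spanning guinea-pig N1/P1 latencies; the exact peak pair
used in the original recordings is not standardized, so the window is a
documented choice). CAP threshold is the level evoking 10 µV peak-to-peak,
linearly interpolated between the bracketing 5 dB steps after an isotonic
monotonization of noisy growth functions — interpolation avoids step-size
bias and the isotonic fit (scipy's PAVA) makes the bracketing well defined.

ANOW waveforms are 0.5·(pos + neg) — cancelling polarity-inverting hair-cell
and artifact components — with the first 5 ms and final 8.3 ms of the
33.3 ms record removed (20 ms retained) and raised-cosine on/off ramps of
duration 1/f s. Ramp shape is a choice (only "ramped" is specified
upstream); raised-cosine is the field default. ANOW *magnitude* is the RMS
of the unramped interior — a documented stand-in, since the original
quantification (peak, RMS, or 2f spectral magnitude) is not stated; no
fidelity is claimed for low-frequency threshold values derived from it.

One stimulus-arithmetic convention worth recording: the CAP stimulus cycle
is 69.5 ms = 5 × 13.9 ms, i.e. one tone burst of *each polarity* plus three
silent periods of the same duration (a 14.39/s repetition rate). Reading
"a burst plus three silences" as 4 × 13.9 ms does not reproduce the printed
cycle length.

## Reduction-time extraction

Trajectories are normalized by the mean amplitude over −5 to +5 min re
perfusion start (≥ 2 baseline samples required). The fraction crossing
(80/50/20%) uses a *sustained-crossing* rule — the first sample below the
fraction that stays below for k = 2 consecutive samples — to reject
single-sample noise dips at the ~6 dB SNR typical of threshold-level CAPs.

The crossing time is interpolated between the bracketing ~1-min samples on
the **logit scale** by default. Logit-linear interpolation is exact for
logistic declines and recovers 80/50/20% times to well under 0.02 min at
1-min sampling, where amplitude-linear interpolation leaves a systematic
~0.07 min error at realistic slopes; whenever a bracketing amplitude lies
outside (0, 1) the rule falls back to plain linear interpolation
(`interpolation="linear"` forces it globally). A sample exactly at the
fraction is taken at face value. No pre-smoothing is applied by default; a
3-point median filter is available by config. Crossings at or before the
first sample, or at negative times, are flagged with warnings — the front
cannot have caused them.

Tuning curves require the 10 dB SL (tip) series; higher levels contribute
(t80, t20) edge pairs, with levels omitted (warning) when a crossing never
occurs, and the t80 ≤ t20 ordering enforced by reordering in the rare
noise-inverted case. Group averages are per-level means with SEM reported
only where ≥ 2 ears contribute.

## Permutation statistics

The per-frequency statistic is OSD = mean(control t₅₀) − mean(operated t₅₀).
The exact test enumerates all C(N+M, N) assignments (1287 for 5 + 8), so p
is a multiple of 1/1287 and at least 1/1287 (the observed assignment is in
the enumeration). Monte-Carlo tests draw uniform random N-subsets (the index
set of the N smallest of N+M iid uniforms — equivalent to permuting the ear
list and taking the first N), vectorized in chunks up to the configured
n_perm (default 10⁵, up to 10⁷).

Exceedance is PD ≥ OSD with ties counting as exceedances; the comparison
carries ~1e−9 relative slack so floating-point summation order cannot drop
an exact tie (assignment statistics that genuinely differ are separated by
many orders of magnitude more). The default p estimator is the raw
count/n_perm for fidelity with the workflow being reproduced — it can return
exactly 0 — and a (count+1)/(n_perm+1) variant is available. The default
test is one-sided (positive tail: operated earlier); the two-sided variant
uses |PD| ≥ |OSD| (a doubling rule was the other candidate; the magnitude
rule was chosen and is documented here).

Grand multi-frequency tests compare Σ_f OSD_f against Σ_f PD_f with either
independent permutations per frequency (method 1; 1287⁵ ≈ 3.5·10¹⁵
assignments, so Monte-Carlo only) or one shared permutation (method 2,
algebraically a single-frequency test on per-ear row sums). Method 1 draws
each frequency's permutations from an RNG stream keyed by (master seed,
frequency), so results are invariant to frequency order; method 2 and the
single-frequency MC test share the master-seed stream, which makes the
identical-columns identity (method-2 p = single-frequency p) hold exactly.
On data whose ear effects are correlated across frequency — as in real
cohorts — method 2 is systematically the more conservative, and the package
reproduces that ordering on its synthetic studies.

## OAE extraction

Tone amplitudes are least-squares sinusoid fits at exactly the analysis
frequency over a window truncated to an integer number of cycles (making the
fit orthogonal to DC and other integer-cycle tones); DPOAE analysis is at
2f₁−f₂ with the f₂/f₁ ratio checked against 1.22 ± 0.05, repetitions
averaged coherently before the fit. SFOAE uses the double-evoked residual
probe + suppressor − both (suppressor 50 Hz above the probe), which is
identically zero for a linear ear. Noise floors are the standard error of
per-repetition amplitudes — on **complex** amplitudes by default (the noise
contaminating the coherent mean); an SE-of-magnitudes mode is switchable.
Zero-variance repetition sets clamp to a −120 dB SPL sentinel.

dB SPL here refers the sinusoid *peak* amplitude directly to 20 µPa
(`20·log₁₀(A/20 µPa)`), for both synthesis and analysis, so injected levels
round-trip exactly; absolute levels against an RMS-referenced meter would
read 3.01 dB lower. Hardware calibration (probe transfer functions,
calibration-tube analysis) is out of scope and treated as ideal.

## Synthetic-data generator

The generator emulates the study conditions: 5 operated + 8 control ears;
frequencies 2, 4, 6, 8, 12 kHz; ground-truth 50% times

    t₅₀(ear, f) = t_arrival(f) + u_ear − 1[operated]·z_ear·(shift_f / p) + ε

with `t_arrival(f)` the front-arrival time at the CF place of `f`,
`u_ear ~ N(0, 2.0² min²)` shared across frequency (inducing the strong
across-frequency ear correlation), `z_ear` a Bernoulli(p = 0.8) responder
flag per operated ear (or exactly `n_nonresponders` zeros when configured),
and `ε ~ N(0, 0.5² min²)` per cell. The configured shifts (5.8, 3.8, 4.3,
2.4, 3.4 min at 2–12 kHz) are *group-mean* shifts: responders shift by
shift/p so the expected control-minus-operated difference equals the
configured value for any responder probability, and with exactly one
non-responder in five the realized group difference equals it exactly. The
ear and cell SDs are not reported quantities; they are chosen once for
plausible across-ear spread and ~6 dB-SNR extraction noise and documented
here as assumptions.

Amplitude trajectories are two-sided logistic declines (slope 0.8 min at
10 dB SL; sigmoid-like declines are observed but no functional form is
reported, so the logistic is a modelling choice) sampled every 1 min from
−10 to +45 min, scaled to a 40 µV baseline, with additive Gaussian amplitude
noise (SD 0.05 of baseline; a heavier-tailed Laplace option exists). Above
10 dB SL the response region widens asymmetrically — the 80% point moves
earlier by 0.5 min and the 20% point later by 1.5 min per 10 dB — mirroring
the normal-ear behaviour in which the basal edge moves more with level than
the apical edge. The 50% point is held fixed across level, a simplification
(in normal ears it drifts basally at high levels).

What the generator does **not** emulate: cochlear micromechanics or kainate
diffusion kinetics (the front is sharp and constant-speed by construction);
level-dependent CAP latency or waveform shape changes; slow amplitude drift
or non-stationary noise; any operated-ear change in trajectory *slope* (only
its timing shifts). Passing tests therefore validate the estimators under
the stated statistical structure, not the biophysics of real recordings.

One interaction worth knowing: when a strongly shifted operated ear's
decline begins before +5 min it overlaps the baseline-normalization window,
which re-scales the trace and biases the extracted crossing slightly late —
exactly as it would in a real recording normalized the same way. The
generator-consistency test therefore checks trajectories clear of the
baseline window; the parameter-recovery check, which includes such ears,
still recovers the configured shifts within Monte-Carlo error.

## Problem sizes and determinism

Default statistical settings: n_perm = 10⁵ Monte-Carlo permutations
(configurable to 10⁷), exact enumeration alongside whenever C(N+M, N) is
enumerable. The test suite's calibration checks use 2000 exchangeable-null
datasets for type-I error (the exact one-sided test rejects at
0.0497 = 64/1287 nominal atoms below α = 0.05) and 500 replicate studies
for full-pipeline parameter recovery. All randomness flows from explicit
seeds (numpy Generators); a pipeline rerun with the same config reproduces
every artifact byte-for-byte apart from the timestamped log.

## Known limitations

- The map constants are a stand-in validated only against the two printed
  conversions; species other than guinea pig are unsupported.
- ANOW magnitude and the CAP peak-pair convention are documented guesses.
- The paper-fidelity p estimator can report p = 0 at finite n_perm; use the
  plus-one estimator when a strictly positive estimate is required.
- Printed group p-values of the original animal study are not reproducible
  desk-side (per-ear reduction times were never published); the pipeline
  reproduces the *procedure* and its calibration, not those numbers.
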