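# Methods

This note documents the statistical procedures, the synthetic-data models
that stand in for animal recordings, the numerical choices, and the known
limitations of `infrakit`.

## Activity records

Locomotor counts are held as evenly binned series (wheel: 5-min bins, PIR:
1-min bins) with a boolean gap mask. Gaps are never encoded as zeros —
a zero PIR count *is* data (it defines a sleep minute) — and masked bins
are excluded from every statistic. Bins are left-closed/right-open with
the timestamp at the left edge; internal time is floating-point hours from
record start. Rebinned series mask a coarse bin iff any constituent bin is
masked, conserving unmasked totals for gap-free records. Serialized counts
use `repr` round-tripping and are re-parsed with Python's correctly
rounded `float()`, so file round trips are bit-exact.

## Lomb–Scargle periodogram and significance

Power is the classical Scargle statistic: the sum-of-squares reduction of
a least-squares sine+cosine fit at each trial frequency, divided by the
sample variance of the (mean-centered, unmasked) counts. Under white
Gaussian noise each frequency's power is approximately unit-mean
exponential, which is what the significance threshold assumes. The grid
is uniform in frequency from `1/96 h⁻¹` to `1/20 h⁻¹` (oversampling factor
10 relative to the Fourier spacing `1/T_span`), with the exact short-period
edge appended so band edges at 20 h lie on the grid.

The family-wise threshold solves `1 − (1 − e^{−z})^M = α`. `M` defaults to
a Horne–Baliunas-style count of independent frequencies scaled by the
fraction of the 0-to-Nyquist axis actually searched; the unscaled estimate
is appropriate only for full-spectrum scans and would be far too
conservative on a 20–96 h band. Monte-Carlo calibration on white noise
puts the realized family-wise rate at ≈0.04 for a nominal α = 0.05
(slightly conservative, as expected for an oversampled, correlated grid).
`n_independent` can be overridden, and `permutation_sig_level` provides a
circular-shift null that preserves the count autocorrelation, to bound the
analytic threshold's error on real data.

%ASD sums `P(f)` over significant grid points per band and normalizes by
the significant sum over the full range. Interior band boundaries are
half-open `[lo, hi)` so a point on the 27-h divider is counted once. With
no significant point the partition is NA, not 0/0. Because the power is
variance-normalized, %ASD is exactly invariant under uniform count
rescaling.

The trough-anchored split smooths the baseline periodogram with a
5-grid-point centered moving average, takes the dominant peak, and walks
toward longer periods to the first local minimum (ties toward the smaller
period). If no minimum occurs before the top of the grid, the midpoint
between peak and top is used and flagged. The significant density of the
target periodogram is then split below/above that trough.

## Wavelet analysis

The CWT is computed in the frequency domain (FFT with zero padding to
twice the series length) using bandpass-normalized analytic wavelets on a
geometric period grid with exactly 24 voices per octave
(`p[i+1]/p[i] = 2^{1/24}`). The default family is the generalized Morse
wavelet with γ = 3, β = 20 (time-bandwidth P² = 60, Morlet-like); an
analytic Morlet (ω₀ = 6) is one flag away. The scale for period `T` is
`s = T·ω_p/2π` with `ω_p` the wavelet's peak frequency.

Counts are gap-filled by linear interpolation and z-scored before the
transform, making scalograms invariant to affine transforms of the counts.
Validity is tracked explicitly: a time–scale cell is invalid when it lies
within one wavelet e-folding footprint (the time at which the wavelet
envelope decays to 1/e of its peak, computed numerically per family —
factor ≈ 5.9 scale units for Morse(3, 20)) of a record edge or of an
interpolated gap. The ridge is the per-time argmax of power over valid
scales, with an optional centered running median (12 h is a sensible
display window); ridge points with no valid scale carry no period. Note
that near record edges only short scales remain valid, so a ridge there
reflects whatever dominates those scales — interpret ridges inside the
cone of the period of interest.

Scale-averaged band power weights each scale by `1/s` (standard scale
averaging, so equal oscillation energy contributes equally regardless of
period) and reports the weighted mean over scales in the band per time
point.

Choosing β: the default β = 20 gives sharp period resolution for slowly
drifting rhythms, at the cost of a multi-day footprint. Detecting period
*modulation* faster than that footprint (e.g. relative-coordination wobble
at the beat period) requires a low time-bandwidth setting such as β = 3.

## Sleep analysis

Sleep scoring is the immobility rule validated against EEG in mice: a
1-min PIR bin with exactly zero counts scores 1 (sleep), anything else 0;
masked bins stay masked, and sleep + wake minutes always equal unmasked
minutes. The 4-day cycling window is the span maximizing the ratio of
scale-averaged infradian (44–52 h) to circadian (22–26 h) power of the
record (computed on a 6-min rebin for speed); candidate starts advance in
whole days so the window respects the record's day grid, ties go to the
earliest start, and a best ratio below 1 flags the selection
low-confidence. Days within the window are labeled by folding daily sleep
totals at the cycle period: the phase with less sleep is "active"
(mania-like), which for a 48-h cycle makes labels alternate strictly;
all-equal phases raise rather than guessing. Since zeitgeber time is
undefined in constant darkness, `find_activity_onset` (first 30-min run of
above-median activity after ≥6 h without one) is provided to re-anchor day
boundaries on real data.

## Open-field analysis

Total distance is the sum of frame-to-frame Euclidean displacements.
For spatial d the trace is reduced to microevents: frame 0, then the first
frame at/after each successive 2-cm mark of cumulative path length
(a 1e-9 relative tolerance absorbs floating-point accumulation). Path
length `L_k` sums straight-line distances between microevents `k` apart.
The microevent list is truncated so the interval count is a multiple of 8,
making all four resolutions span the same stretch of path — without this,
per-k remainder dropping gives even a perfectly straight line a nonzero
slope. Spatial d is the negative OLS slope of `log2 L_k` on `log2 k` over
k ∈ {1, 2, 4, 8} (exactly 0 when all `L_k` are equal); the `1 − slope`
convention, which places a straight line at d = 1 as in the original
fractal formulation, is selectable. Single missing frames in loaded traces
are bridged linearly; gaps longer than 5 frames invalidate the trace.

## Synthetic generators

The generators define the test conditions for the whole pipeline; their
defaults are the regimes reported for 48-h cycling animals.

**Two-oscillator locomotor model.** Counts per bin are Poisson (optionally
negative-binomial) draws with rate

    rate(t) = baseline · exp[a_scn·g(φ_scn) + a_do(t)·g(φ_do)],

where `g(φ) = max(cos φ, 0)` is a half-rectified cosine gate producing
actogram-like on/off bouts. The circadian phase advances at `2π/24 h`; the
DO phase integrates `2π/T_do(t)` with

    T_do(t) = trajectory(t) + coordination_gain · sin(φ_scn − φ_do),

the minimal model of relative coordination. Trajectories may be constant,
linear ramps (gradual emergence), or piecewise steps. Defaults:
`baseline_rate` 20 counts/bin, amplitudes ≈ 2 (peak/trough rate ratio
≈ e² ≈ 7, typical of wheel-running contrast), seed-reproducible to the
bit. The gate waveform has harmonics — for a 48-h DO the second harmonic
lands at exactly 24 h, inside the circadian band — so a "pure" 48-h
oscillator caps the infradian %ASD near 74%, not 100%. That is a property
of any sharply gated rhythm, not an artifact.

**Beat measurement.** Two gates multiply, so the count rate contains a
genuine difference-frequency line at `1/|1/24 − 1/T_do|`. A plain daily
average cannot isolate it: the DO fundamental leaks through a 24-h boxcar,
and in strictly daily totals it aliases exactly onto the beat frequency.
`beat_envelope` therefore removes both component fundamentals (plus two
harmonics each) by harmonic regression and smooths the residual over 24 h;
the dominant period of that envelope matches the closed form to well
under 1%.

**PIR sleep–wake.** Per-day two-state Markov chain at 1-min resolution
with geometric bouts (mean sleep bout 10 min) whose stationary sleep
occupancy equals the day's programmed fraction — 0.35 on active days, 0.70
on inactive days, alternating on the 48-h cycle (active first). Wake
minutes emit `1 + Poisson(2)` counts, sleep minutes zero. Bout
autocorrelation makes single-day occupancy noisy (±3–4%); recovery to ±2
points holds for means over several days/seeds. The generator has no
within-day circadian structure of wakefulness; it emulates occupancy, not
bout architecture or ultradian sleep cycles.

**Open-field paths.** Correlated random walk: fixed 0.15 cm steps at
30 fps (≈27 m per 10-min session, typical for mice), heading increments
wrapped-normal with dispersion `turning_sd`, reflected at the 50-cm arena
walls via a triangle-wave fold (which preserves step lengths except
exactly at wall contacts). `turning_sd = 0` gives a straight path
(spatial d = 0); spatial d increases monotonically with dispersion.

What the generators do *not* emulate: pharmacokinetics of the inducing
drug, non-stationary amplitude/noise of real recordings beyond the
provided ramps, animal-to-animal waveform differences, or within-day
sleep architecture. Passing tests therefore demonstrate correctness of
the *analysis* under known ground truth, not biological realism of every
feature.

## Problem sizes and determinism

Test and acceptance runs use 20–60-day simulated records at native bin
widths (≈8–17k bins), 2000-replicate null calibrations, and 50-seed path
batches; these sizes give stable statistics while keeping the full suite
in the tens of seconds. Every stochastic step draws from
`numpy.random.default_rng` with an explicit seed; identical configuration,
inputs and seed reproduce all pipeline outputs byte-identically (the run
log contains no timestamps for this reason).

## Known limitations

- The analytic significance threshold assumes exchangeable Gaussian-like
  noise; strongly autocorrelated counts need the permutation null.
- %ASD depends on the significance mask: near-threshold peaks can move a
  few percent of density between bands across recordings.
- The ridge is a hard argmax; two components of near-equal power produce
  ridge switching rather than averaging.
- The Tro procedure assumes a unimodal dominant ultradian peak at
  baseline; multi-peaked baselines can anchor the trough ambiguously.
- Wall folding slightly shortens steps at contact frames, so simulated
  total distance is marginally below `step × (frames−1)` for wall-hitting
  paths.
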