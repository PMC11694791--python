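"""Synthetic generators for every input the analysis pipeline consumes.

The central object is a two-oscillator locomotor model: a circadian
component (period ~24 h, the SCN clock) and a second, dopamine-oscillator
(DO) component whose period can sit anywhere in the infradian 27-96 h
range, drift over time ("emergence" as a gradual amplitude/period ramp),
and be modulated by its phase relationship to the circadian oscillator
(relative coordination).  The bin rate is multiplicative log-linear,

    rate(t) = baseline * exp[ a_scn * g(phi_scn) + a_do(t) * g(phi_do) ],

with ``g`` a half-rectified cosine gate, so activity shows actogram-like
off/on structure while each component's instantaneous period is known
analytically.  The DO phase integrates ``2*pi / T_do(t)`` with

    T_do(t) = trajectory(t) + coordination_gain * sin(phi_scn - phi_do),

the minimal model of relative coordination.  Counts per bin are Poisson
(or negative-binomial) draws; generators are bit-reproducible for a fixed
seed.

Two slow oscillators with nearby, non-harmonic frequencies beat: their
combined activity envelope waxes and wanes with period
``1 / |1/T_a - 1/T_b|``.  :func:`beat_period` provides this closed form
with harmonic/phase-lock flagging, and :func:`activity_envelope` the
sliding daily-activity trace on which the beat is measured.

The PIR sleep-wake generator produces alternating short-sleep ("active",
default 35% of the day asleep) and long-sleep ("inactive", 70%) days on a
48-h cycle via a two-state semi-Markov chain with geometric bout lengths;
the open-field generator is a correlated random walk with a wrapped-normal
turning-angle dispersion knob controlling tortuosity, reflected at the
arena walls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .openfield import PathTrace
from .timeseries import ActivityRecord

__all__ = [
    "OscillatorSpec",
    "SleepPatternSpec",
    "PathSpec",
    "BeatResult",
    "constant",
    "ramp",
    "piecewise",
    "simulate_locomotor",
    "simulate_pir_sleepwake",
    "simulate_path",
    "beat_period",
    "activity_envelope",
]

Trajectory = Callable[[np.ndarray], np.ndarray]


# ---------------------------------------------------------------------------
# trajectory helpers
# ---------------------------------------------------------------------------

def constant(value: float) -> Trajectory:
    """Time-constant trajectory."""
    def f(t):
        return np.full_like(np.asarray(t, float), value)
    return f


def ramp(v0: float, v1: float, t0: float, t1: float) -> Trajectory:
    """Linear ramp from ``v0`` (before ``t0`` h) to ``v1`` (after ``t1`` h)."""
    def f(t):
        t = np.asarray(t, float)
        return v0 + (v1 - v0) * np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return f


def piecewise(segments) -> Trajectory:
    """Step trajectory from ``[(start_hour, value), ...]`` (sorted)."""
    starts = np.array([s for s, _ in segments], float)
    vals = np.array([v for _, v in segments], float)
    def f(t):
        t = np.asarray(t, float)
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(vals) - 1)
        return vals[idx]
    return f


def _as_traj(x) -> Trajectory:
    return x if callable(x) else constant(float(x))


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class OscillatorSpec:
    """Two-oscillator locomotor model parameters.

    Amplitudes are log-rate gains (dimensionless); ``baseline_rate`` is
    the expected count per bin when both gates are closed.  Period
    trajectories are in hours and may be constants or callables of time
    (hours).  ``coordination_gain`` is the hours of DO period modulation
    per unit ``sin(phi_scn - phi_do)``.
    """

    scn_period: float = 24.0
    scn_amplitude: float = 2.0
    do_period_trajectory: object = 48.0
    do_amplitude_trajectory: object = 0.0
    coordination_gain: float = 0.0
    baseline_rate: float = 20.0
    noise: str = "poisson"           # "poisson" | "negbin"
    negbin_dispersion: float = 2.0   # variance = mu + mu^2 / dispersion
    gap_fraction: float = 0.0
    seed: int = 0


@dataclass
class SleepPatternSpec:
    """Alternating-day sleep occupancy on an infradian cycle."""

    cycle_period: float = 48.0
    active_day_sleep_fraction: float = 0.35
    inactive_day_sleep_fraction: float = 0.70
    bout_length_minutes: float = 10.0
    wake_count_rate: float = 2.0     # extra Poisson counts per wake minute
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.active_day_sleep_fraction <
                self.inactive_day_sleep_fraction < 1) and not (
                self.active_day_sleep_fraction ==
                self.inactive_day_sleep_fraction):
            if not (0 < self.active_day_sleep_fraction <= 1
                    and 0 < self.inactive_day_sleep_fraction <= 1):
                raise ValueError("sleep fractions must lie in (0, 1]")


@dataclass
class PathSpec:
    """Correlated-random-walk open-field path parameters."""

    step_cm: float = 0.15
    turning_sd: float = 0.5          # rad, wrapped-normal heading dispersion
    duration_s: float = 600.0
    fps: float = 30.0
    arena_cm: float = 50.0
    seed: int = 0


@dataclass(frozen=True)
class BeatResult:
    """Beat period of two oscillators with lock/harmonic flags."""

    period: float                    # hours; inf when phase-locked (equal)
    locked: bool
    harmonic_ratio: int | None = None


# ---------------------------------------------------------------------------
# locomotor generator
# ---------------------------------------------------------------------------

def simulate_locomotor(spec: OscillatorSpec, days: float,
                       bin_minutes: float = 5.0,
                       channel: str = "wheel") -> ActivityRecord:
    """Simulate a binned locomotor count series from the two-oscillator model.

    The DO phase is integrated forward with an Euler step of one bin;
    counts are drawn per bin from the configured noise model.  Fixed seed
    gives bit-identical output.
    """
    if days < 1:
        raise ValueError("need at least one day")
    dt = bin_minutes / 60.0
    n = int(round(days * 24.0 / dt))
    t = (np.arange(n) + 0.5) * dt

    phi_scn = 2 * np.pi * t / spec.scn_period
    traj = _as_traj(spec.do_period_trajectory)(t)
    if np.any(traj <= 0):
        raise ValueError("DO period trajectory must stay positive")
    phi_do = np.empty(n)
    phi_do[0] = 0.0
    for i in range(n - 1):
        t_eff = traj[i] + spec.coordination_gain * math.sin(phi_scn[i] - phi_do[i])
        if t_eff <= 0:
            raise ValueError("coordination drove the DO period non-positive")
        phi_do[i + 1] = phi_do[i] + dt * 2 * np.pi / t_eff

    gate = lambda phi: np.maximum(np.cos(phi), 0.0)
    a_do = _as_traj(spec.do_amplitude_trajectory)(t)
    if np.any(a_do < 0) or spec.scn_amplitude < 0:
        raise ValueError("amplitudes must be non-negative")
    rate = spec.baseline_rate * np.exp(
        spec.scn_amplitude * gate(phi_scn) + a_do * gate(phi_do))

    rng = np.random.default_rng(spec.seed)
    if spec.noise == "poisson":
        counts = rng.poisson(rate).astype(float)
    elif spec.noise == "negbin":
        r = spec.negbin_dispersion
        counts = rng.negative_binomial(r, r / (r + rate)).astype(float)
    else:
        raise ValueError(f"unknown noise model {spec.noise!r}")

    mask = np.zeros(n, bool)
    if spec.gap_fraction > 0:
        n_gap = int(round(spec.gap_fraction * n))
        while n_gap > 0:
            span = int(min(n_gap, rng.integers(1, max(2, n // 50))))
            start = int(rng.integers(0, n - span + 1))
            mask[start:start + span] = True
            n_gap -= span
    return ActivityRecord(counts=counts, bin_width=bin_minutes,
                          gap_mask=mask, channel=channel)


# ---------------------------------------------------------------------------
# PIR sleep-wake generator
# ---------------------------------------------------------------------------

def simulate_pir_sleepwake(spec: SleepPatternSpec, days: int) -> ActivityRecord:
    """Simulate a 1-min PIR record with programmed daily sleep occupancy.

    Each 24-h day draws a two-state (sleep/wake) Markov chain at 1-min
    resolution whose stationary sleep occupancy equals that day's
    programmed fraction (active and inactive days alternate on the 48-h
    cycle, active first); sleep bouts are geometric with the configured
    mean length.  Sleep minutes emit zero counts; wake minutes emit
    ``1 + Poisson(wake_count_rate)``.
    """
    if spec.cycle_period == 48.0 and days % 2:
        raise ValueError("days must be even for a 48-h cycle")
    rng = np.random.default_rng(spec.seed)
    days_per_cycle = max(1, int(round(spec.cycle_period / 24.0)))
    minutes = []
    state = None
    for d in range(days):
        phase = d % days_per_cycle
        f = (spec.active_day_sleep_fraction if phase == 0
             else spec.inactive_day_sleep_fraction)
        f = min(max(f, 1e-9), 1.0)
        if f >= 1.0:
            day = np.ones(1440, int)
            state = 1
        else:
            p_ws = 1.0 / spec.bout_length_minutes          # sleep -> wake
            p_sw = f * p_ws / (1.0 - f)                    # wake -> sleep
            p_sw = min(p_sw, 1.0)
            if state is None:
                state = int(rng.random() < f)
            day = np.empty(1440, int)
            u = rng.random(1440)
            for m in range(1440):
                day[m] = state
                flip = u[m] < (p_ws if state == 1 else p_sw)
                if flip:
                    state = 1 - state
        minutes.append(day)
    asleep = np.concatenate(minutes)
    counts = np.where(asleep == 1, 0,
                      1 + rng.poisson(spec.wake_count_rate, asleep.size))
    return ActivityRecord(counts=counts.astype(float), bin_width=1.0,
                          gap_mask=np.zeros(asleep.size, bool), channel="pir")


# ---------------------------------------------------------------------------
# open-field path generator
# ---------------------------------------------------------------------------

def simulate_path(spec: PathSpec) -> PathTrace:
    """Correlated random walk in the arena, reflected at the walls.

    Heading increments are wrapped-normal with standard deviation
    ``turning_sd``; ``turning_sd = 0`` gives a straight path.  Reflection
    is implemented by folding the unbounded trajectory into the arena
    (triangle-wave map), which preserves step lengths and local turning
    structure.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fps))
    theta0 = rng.uniform(0, 2 * np.pi)
    dtheta = rng.normal(0.0, spec.turning_sd, n - 1) if spec.turning_sd > 0 \
        else np.zeros(n - 1)
    theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])
    steps = spec.step_cm * np.column_stack([np.cos(theta), np.sin(theta)])
    raw = np.concatenate([[[spec.arena_cm / 2, spec.arena_cm / 2]],
                          steps]).cumsum(axis=0)[: n]
    L = spec.arena_cm
    folded = L - np.abs(np.mod(raw, 2 * L) - L)
    return PathTrace(xy=folded, fps=spec.fps, arena_cm=spec.arena_cm)


# ---------------------------------------------------------------------------
# beat model
# ---------------------------------------------------------------------------

def beat_period(period_a: float, period_b: float,
                harmonic_tol: float = 1e-9) -> BeatResult:
    """Closed-form beat period of two oscillators, ``1 / |1/a - 1/b|``.

    Equal periods are phase-locked (infinite beat period); integer period
    ratios (2:1, 3:1, ...) are harmonious — the oscillators repeat their
    mutual phase pattern every cycle of the slower one — and are flagged
    locked with the ratio recorded.
    """
    if period_a <= 0 or period_b <= 0:
        raise ValueError("periods must be positive")
    slow, fast = max(period_a, period_b), min(period_a, period_b)
    ratio = slow / fast
    if abs(period_a - period_b) / slow < harmonic_tol:
        return BeatResult(period=math.inf, locked=True, harmonic_ratio=1)
    beat = 1.0 / abs(1.0 / period_a - 1.0 / period_b)
    if abs(ratio - round(ratio)) < max(harmonic_tol, 1e-12) * ratio * 10:
        return BeatResult(period=beat, locked=True,
                          harmonic_ratio=int(round(ratio)))
    return BeatResult(period=beat, locked=False)


def beat_envelope(record: ActivityRecord, component_periods,
                  n_harmonics: int = 2,
                  window_hours: float = 24.0) -> ActivityRecord:
    """Isolate the beat (difference-frequency) modulation of two rhythms.

    The component oscillations themselves — the circadian and DO
    fundamentals plus ``n_harmonics`` harmonics of each — are removed by
    harmonic regression; the residual is smoothed over ``window_hours``.
    What remains for two coupled rhythmic processes is their slow in-and-
    out-of-phase modulation, whose dominant period is the closed-form
    beat period ``1/|1/T_a - 1/T_b|``.  Without the notch the component
    fundamentals leak through any daily average (and, in strictly daily
    totals, alias exactly onto the beat frequency), masking the beat for
    DO periods beyond 48 h.
    """
    t, y = record.times_hours, record.counts.astype(float)
    cols = [np.ones_like(t)]
    for period in component_periods:
        for h in range(1, n_harmonics + 1):
            w = 2 * np.pi * h * t / period
            cols += [np.cos(w), np.sin(w)]
    x = np.column_stack(cols)
    good = ~record.gap_mask
    beta, *_ = np.linalg.lstsq(x[good], y[good], rcond=None)
    resid = np.where(good, y - x @ beta, 0.0)
    k = max(1, int(round(window_hours * 60.0 / record.bin_width)))
    env = np.convolve(resid, np.ones(k) / k, mode="same")
    return ActivityRecord(counts=env - env.min(), bin_width=record.bin_width,
                          gap_mask=record.gap_mask.copy(),
                          channel=record.channel)


def activity_envelope(record: ActivityRecord,
                      window_hours: float = 24.0) -> ActivityRecord:
    """Sliding daily-activity envelope of a count series.

    Centered moving average of the counts over ``window_hours`` (masked
    bins excluded), returned as a record on the same bin grid so that it
    can be fed straight back into the periodogram.  The dominant period
    of this envelope for a two-oscillator series is the beat period.
    """
    k = max(1, int(round(window_hours * 60.0 / record.bin_width)))
    good = (~record.gap_mask).astype(float)
    vals = np.where(record.gap_mask, 0.0, record.counts)
    kern = np.ones(k)
    num = np.convolve(vals, kern, mode="same")
    den = np.convolve(good, kern, mode="same")
    env = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return ActivityRecord(counts=env, bin_width=record.bin_width,
                          gap_mask=record.gap_mask.copy(),
                          channel=record.channel)
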