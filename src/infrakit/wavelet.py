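"""Continuous wavelet scalograms of activity and ridge tracking.

Infradian rhythms emerge gradually and drift in period, so a single
periodogram misses their time course.  The tool of choice is the analytic
continuous wavelet transform on a geometric scale grid (24 voices per
octave): its magnitude-squared ("scalogram") gives time-resolved power per
period, the per-time argmax across periods is the *ridge* — the
instantaneous dominant period — and averages over a scale band (e.g.
circadian 22-26 h vs infradian 44-52 h) give band-limited rhythmic
strength over time.

The default wavelet is the generalized Morse family with gamma=3, beta=20
(time-bandwidth P^2 = beta*gamma = 60, Morlet-like in shape); an analytic
Morlet (omega0 = 6) is available as an option.  Both are evaluated in the
frequency domain and applied by FFT.  Counts are gap-filled by linear
interpolation and z-scored before the transform; times closer to a record
edge or to an interpolated gap than one wavelet e-folding footprint are
flagged invalid (the cone of influence and its gap analogue), and ridge
points there carry no period.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .timeseries import ActivityRecord

__all__ = [
    "Scalogram",
    "Ridge",
    "BandPower",
    "cwt_scalogram",
    "extract_ridge",
    "scale_averaged_power",
]

VOICES_PER_OCTAVE = 24


@dataclass(frozen=True)
class Scalogram:
    """Time x period wavelet power with validity information.

    ``power[i, j]`` is magnitude-squared at ``periods[i]``, ``times[j]``;
    ``valid`` is False inside the cone of influence at the record edges or
    within one wavelet footprint of an interpolated gap; ``coi[j]`` is the
    longest period still valid at time ``j`` w.r.t. the record edges.
    """

    times: np.ndarray
    periods: np.ndarray
    power: np.ndarray
    valid: np.ndarray
    coi: np.ndarray
    wavelet: str = "morse"

    @property
    def period_range(self) -> tuple[float, float]:
        return float(self.periods.min()), float(self.periods.max())


@dataclass(frozen=True)
class Ridge:
    """Instantaneous peak period per time point."""

    times: np.ndarray
    peak_period: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class BandPower:
    """Scale-averaged power over a period band, per time point."""

    times: np.ndarray
    band: tuple
    value: np.ndarray

    def mean(self, t_lo: float | None = None, t_hi: float | None = None) -> float:
        sel = np.ones_like(self.times, bool)
        if t_lo is not None:
            sel &= self.times >= t_lo
        if t_hi is not None:
            sel &= self.times < t_hi
        v = self.value[sel]
        return float(np.nanmean(v)) if v.size else float("nan")


# ---------------------------------------------------------------------------
# wavelet definitions (frequency domain, angular frequency omega)
# ---------------------------------------------------------------------------

def _morse_hat(omega: np.ndarray, gamma: float, beta: float) -> np.ndarray:
    """Generalized Morse wavelet, bandpass-normalized (peak value 2)."""
    wp = (beta / gamma) ** (1.0 / gamma)  # peak frequency
    out = np.zeros_like(omega)
    pos = omega > 0
    w = omega[pos]
    # evaluate in log space to avoid overflow at large beta
    out[pos] = 2.0 * np.exp(beta * (np.log(w) - np.log(wp)) - w**gamma + wp**gamma)
    return out


def _morlet_hat(omega: np.ndarray, omega0: float) -> np.ndarray:
    out = np.zeros_like(omega)
    pos = omega > 0
    out[pos] = 2.0 * np.exp(-0.5 * (omega[pos] - omega0) ** 2)
    return out


def _peak_frequency(wavelet: str, gamma: float, beta: float, omega0: float) -> float:
    if wavelet == "morse":
        return (beta / gamma) ** (1.0 / gamma)
    if wavelet == "morlet":
        return omega0
    raise ValueError(f"unknown wavelet family {wavelet!r}")


@lru_cache(maxsize=8)
def _efolding_factor(wavelet: str, gamma: float, beta: float,
                     omega0: float) -> float:
    """Time (units of scale) at which |psi(t)| falls to e^-1 of |psi(0)|.

    Evaluated numerically from a dense inverse transform of the unit-scale
    wavelet; defines the cone-of-influence slope.  For the analytic Morlet
    this reproduces the classical sqrt(2)*scale e-folding.
    """
    n = 1 << 16
    dt = 0.01
    omega = 2 * np.pi * np.fft.fftfreq(n, dt)
    if wavelet == "morse":
        hat = _morse_hat(omega, gamma, beta)
    else:
        hat = _morlet_hat(omega, omega0)
    psi = np.fft.ifft(hat)
    amp = np.abs(psi)
    target = amp[0] / np.e
    idx = np.argmax(amp[: n // 2] < target)
    return float(idx * dt)


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------

def cwt_scalogram(record: ActivityRecord, period_range=(18.0, 96.0),
                  wavelet: str = "morse", gamma: float = 3.0,
                  beta: float = 20.0, omega0: float = 6.0,
                  standardize: bool = True) -> Scalogram:
    """Analytic-wavelet scalogram on a 24-voices-per-octave period grid.

    Adjacent grid periods satisfy ``p[i+1]/p[i] = 2**(1/24)`` exactly.
    Gaps are linearly interpolated before the transform; the affected
    times are flagged invalid out to one wavelet footprint per scale.
    """
    lo, hi = float(period_range[0]), float(period_range[1])
    if not (0 < lo < hi):
        raise ValueError("invalid period range")
    if record.duration_hours < 2 * hi:
        raise ValueError(
            f"record ({record.duration_hours:.0f} h) shorter than twice the "
            f"longest requested period ({hi} h)")

    dt = record.bin_width / 60.0  # hours
    times = record.times_hours
    y = record.counts.astype(float).copy()
    mask = record.gap_mask
    if mask.any():
        if mask.all():
            raise ValueError("record is entirely masked")
        good = ~mask
        y[mask] = np.interp(times[mask], times[good], y[good])
    if standardize:
        sd = y.std()
        y = (y - y.mean()) / (sd if sd > 0 else 1.0)

    n = y.size
    nfft = next_fast_len(2 * n)  # zero-pad to suppress wrap-around
    omega = 2 * np.pi * np.fft.fftfreq(nfft, dt)
    yhat = fft(y, nfft)

    n_oct = np.log2(hi / lo)
    n_scales = int(np.floor(n_oct * VOICES_PER_OCTAVE)) + 1
    periods = lo * 2.0 ** (np.arange(n_scales) / VOICES_PER_OCTAVE)
    wp = _peak_frequency(wavelet, gamma, beta, omega0)
    scales = periods * wp / (2 * np.pi)

    power = np.empty((n_scales, n), float)
    for i, s in enumerate(scales):
        if wavelet == "morse":
            hat = _morse_hat(s * omega, gamma, beta)
        else:
            hat = _morlet_hat(s * omega, omega0)
        w = ifft(yhat * hat)[:n]
        power[i] = np.abs(w) ** 2

    factor = _efolding_factor(wavelet, gamma, beta, omega0)
    footprint = factor * scales  # hours, per scale
    edge_dist = np.minimum(times - times[0], times[-1] - times)
    with np.errstate(divide="ignore"):
        coi = np.where(factor > 0, edge_dist * (2 * np.pi) / (wp * factor), np.inf)

    valid = footprint[:, None] <= edge_dist[None, :]
    if mask.any():
        gap_dist = _distance_to_mask(times, mask)
        valid &= footprint[:, None] <= gap_dist[None, :]
    return Scalogram(times=times, periods=periods, power=power, valid=valid,
                     coi=coi, wavelet=wavelet)


def _distance_to_mask(times: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-sample distance (hours) to the nearest masked sample."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return np.full(times.size, np.inf)
    tm = times[idx]
    pos = np.searchsorted(tm, times)
    left = np.where(pos > 0, times - tm[np.clip(pos - 1, 0, tm.size - 1)], np.inf)
    right = np.where(pos < tm.size, tm[np.clip(pos, 0, tm.size - 1)] - times, np.inf)
    return np.minimum(left, right)


# ---------------------------------------------------------------------------
# ridge and band power
# ---------------------------------------------------------------------------

def extract_ridge(scal: Scalogram, smooth_hours: float = 0.0,
                  power_floor: float = 0.0) -> Ridge:
    """Per-time argmax of power across periods, inside the valid cone.

    ``smooth_hours`` > 0 applies a centered running-median of that window
    to the ridge trace (12 h is a sensible display choice); the floor
    marks times whose best power does not exceed ``power_floor`` invalid.
    """
    p = np.where(scal.valid, scal.power, -np.inf)
    best = np.argmax(p, axis=0)
    best_power = p[best, np.arange(p.shape[1])]
    valid = np.isfinite(best_power) & (best_power > power_floor)
    period = np.where(valid, scal.periods[best], np.nan)

    if smooth_hours > 0:
        dt = float(np.median(np.diff(scal.times))) if scal.times.size > 1 else 1.0
        half = max(1, int(round(smooth_hours / dt / 2)))
        sm = period.copy()
        for j in np.flatnonzero(valid):
            seg = period[max(0, j - half): j + half + 1]
            seg = seg[np.isfinite(seg)]
            if seg.size:
                sm[j] = np.median(seg)
        period = sm
    return Ridge(times=scal.times, peak_period=period, valid=valid)


def scale_averaged_power(scal: Scalogram, band: tuple) -> BandPower:
    """Scale-weighted mean power over the period band, per time point.

    Standard scale averaging weights each scale by ``1/s`` so that equal
    oscillation energy at different periods contributes equally; the value
    reported is the weighted mean over scales in the band.  Invalid cells
    are excluded; times with no valid cell in the band are NaN.
    """
    lo, hi = float(band[0]), float(band[1])
    if not (lo < hi):
        raise ValueError("empty band")
    plo, phi = scal.period_range
    if lo < plo - 1e-9 or hi > phi + 1e-9:
        raise ValueError("band outside scalogram period range")
    rows = (scal.periods >= lo - 1e-12) & (scal.periods <= hi + 1e-12)
    if not rows.any():
        raise ValueError("band contains no scales")
    w = (1.0 / scal.periods[rows])[:, None] * np.ones(scal.times.size)
    w = np.where(scal.valid[rows], w, 0.0)
    num = (w * scal.power[rows]).sum(axis=0)
    den = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(den > 0, num / den, np.nan)
    return BandPower(times=scal.times, band=(lo, hi), value=value)
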