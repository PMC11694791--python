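"""Lomb-Scargle spectral analysis of locomotor rhythms.

The quantities computed here follow actigraphy practice for detecting
infradian (>24 h) periodicities in wheel-running and PIR count series:

* a Lomb-Scargle periodogram ``P(f)`` on a frequency-uniform grid covering
  a requested period range (masked bins are simply excluded, which the
  Lomb-Scargle method handles natively as uneven sampling);
* an analytic family-wise significance threshold at a stated ``alpha``
  (classical exponential-tail false-alarm probability with an effective
  number of independent frequencies), plus a circular-shift permutation
  null for verification;
* the %ASD statistic: the percentage of the summed *significant* power
  falling into period bands (circadian 20-27 h vs infradian 27-96 h by
  default, normalized over the full 20-96 h range);
* the highest significant peak in a search range; and
* the trough-anchored ("Tro") power split used for clock-deficient
  animals whose ultradian period varies (typically 2-8 h): the divider is
  the periodogram trough following the dominant baseline peak rather than
  a fixed 27-h mark.

Normalization: power is the classical Scargle-normalized statistic, i.e.
the least-squares sine+cosine fit improvement divided by the sample
variance, so that white Gaussian noise gives approximately unit-mean
exponentially distributed power.  This makes %ASD invariant under uniform
rescaling of the counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lombscargle as _scipy_ls

from .timeseries import ActivityRecord

__all__ = [
    "Periodogram",
    "BandPartition",
    "TroughSplit",
    "lomb_scargle",
    "significance_level",
    "n_independent_frequencies",
    "permutation_sig_level",
    "percent_asd",
    "highest_peak",
    "trough_after_peak",
    "find_trough",
    "composite_matrix",
]

DEFAULT_BANDS = (20.0, 27.0, 96.0)
DEFAULT_ALPHA = 1e-3


@dataclass(frozen=True)
class Periodogram:
    """Lomb-Scargle periodogram on a frequency-uniform grid.

    ``periods`` run from long to short (increasing frequency); ``power``
    is Scargle-normalized (unit-mean exponential under white noise);
    ``sig_level`` is the family-wise power threshold at ``alpha``.
    """

    periods: np.ndarray
    power: np.ndarray
    sig_level: float
    alpha: float
    n_effective: int

    def __post_init__(self):
        p = np.asarray(self.periods, float)
        w = np.asarray(self.power, float)
        if p.shape != w.shape:
            raise ValueError("periods/power length mismatch")
        dp = np.diff(p)
        if not (np.all(dp < 0) or np.all(dp > 0)):
            raise ValueError("period grid must be strictly monotone")
        if np.any(w < 0):
            raise ValueError("power must be non-negative")
        if not (0 < self.alpha < 1) or self.sig_level <= 0:
            raise ValueError("invalid alpha or sig_level")
        object.__setattr__(self, "periods", p)
        object.__setattr__(self, "power", w)

    @property
    def significant(self) -> np.ndarray:
        return self.power > self.sig_level

    @property
    def period_range(self) -> tuple[float, float]:
        return float(self.periods.min()), float(self.periods.max())

    def grid_step_at(self, period: float) -> float:
        """Local period spacing of the frequency-uniform grid at ``period``."""
        df = abs(np.diff(1.0 / self.periods).mean())
        return period * period * df


@dataclass(frozen=True)
class BandPartition:
    """%ASD per period band; NaN everywhere when nothing is significant."""

    band_edges: tuple
    asd_percent: np.ndarray
    total_sig_density: float

    @property
    def defined(self) -> bool:
        return self.total_sig_density > 0


@dataclass(frozen=True)
class TroughSplit:
    """Split of significant density at the post-peak trough period."""

    tro: float
    asd_below_pct: float
    asd_above_pct: float
    peak_period: float
    fallback: bool = False  # True when no trough was found before 24 h


# ---------------------------------------------------------------------------
# periodogram
# ---------------------------------------------------------------------------

def lomb_scargle(record: ActivityRecord, period_range=(20.0, 96.0),
                 oversample: float = 10.0, alpha: float = DEFAULT_ALPHA,
                 n_independent: int | None = None) -> Periodogram:
    """Scargle-normalized periodogram of a (possibly gapped) record.

    The frequency grid is uniform from ``1/period_range[1]`` to
    ``1/period_range[0]`` with spacing ``1/(oversample * span)``.  Masked
    bins are excluded before the transform.  With fewer than three full
    cycles of the longest requested period in the unmasked span a warning
    is emitted (the long-period end is then poorly constrained).
    """
    lo, hi = float(period_range[0]), float(period_range[1])
    if not (0 < lo < hi):
        raise ValueError("empty or invalid period_range")
    t, y = record.unmasked()
    n = t.size
    if n < 8:
        raise ValueError("fewer than 8 unmasked bins")
    span = t[-1] - t[0]
    if span < 3 * hi:
        import warnings
        warnings.warn(
            f"unmasked span {span:.1f} h covers fewer than 3 cycles of the "
            f"longest requested period ({hi} h)", stacklevel=2)

    f_lo, f_hi = 1.0 / hi, 1.0 / lo
    df = 1.0 / (oversample * span)
    n_grid = max(2, int(math.ceil((f_hi - f_lo) / df)) + 1)
    freqs = f_lo + df * np.arange(n_grid)
    freqs = freqs[freqs <= f_hi + 1e-12]
    if freqs[-1] < f_hi - 1e-12:  # keep the exact short-period edge on grid
        freqs = np.append(freqs, f_hi)

    yc = y - y.mean()
    var = yc.dot(yc) / (n - 1)
    if var <= 0:
        power = np.zeros_like(freqs)
    else:
        power = _scipy_ls(t, yc, 2 * np.pi * freqs) / var
        power = np.maximum(power, 0.0)

    m = n_independent if n_independent is not None else \
        n_independent_frequencies(n, span, (f_lo, f_hi))
    z = significance_level(n, alpha, m)
    return Periodogram(periods=1.0 / freqs, power=power, sig_level=z,
                       alpha=alpha, n_effective=n)


def n_independent_frequencies(n_effective: int, span_hours: float,
                              freq_range: tuple) -> int:
    """Effective number of independent frequencies in a searched band.

    The Horne-Baliunas estimate ``-6.362 + 1.193 N + 0.00098 N^2`` counts
    independent frequencies over the full 0-to-Nyquist axis; a periodogram
    restricted to a band contains the corresponding fraction of them.
    """
    n = n_effective
    m_full = max(1.0, -6.362 + 1.193 * n + 0.00098 * n * n)
    f_ny = n / (2.0 * span_hours)
    frac = min(1.0, (freq_range[1] - freq_range[0]) / f_ny)
    return max(1, int(round(m_full * frac)))


def significance_level(n_effective: int, alpha: float,
                       n_independent: int) -> float:
    """Family-wise power threshold via the exponential false-alarm tail.

    For Scargle-normalized power each frequency is approximately unit-mean
    exponential under Gaussian noise, so the maximum over ``M`` independent
    frequencies exceeds ``z`` with probability ``1 - (1 - e^{-z})^M``;
    inverting at ``alpha`` gives the threshold.
    """
    if n_effective <= 2:
        raise ValueError("need more than 2 effective samples")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    m = max(1, int(n_independent))
    return -math.log(-math.expm1(math.log1p(-alpha) / m))


def permutation_sig_level(record: ActivityRecord, period_range=(20.0, 96.0),
                          oversample: float = 10.0, alpha: float = DEFAULT_ALPHA,
                          n_perm: int = 200, seed: int = 0) -> float:
    """Circular-shift permutation null for the family-wise max power.

    Bounds the discrepancy between the analytic threshold and the actual
    null for autocorrelated counts.  Returns the (1 - alpha) quantile of
    the max power over ``n_perm`` circular shifts.
    """
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        shift = int(rng.integers(1, record.n_bins))
        shifted = record.with_counts(np.roll(record.counts, shift),
                                     np.roll(record.gap_mask, shift))
        pg = lomb_scargle(shifted, period_range, oversample, alpha,
                          n_independent=1)
        maxima[i] = pg.power.max()
    return float(np.quantile(maxima, 1.0 - alpha))


# ---------------------------------------------------------------------------
# band statistics
# ---------------------------------------------------------------------------

def percent_asd(pg: Periodogram, band_edges=DEFAULT_BANDS) -> BandPartition:
    """Percentage of significant spectral density per period band.

    Sums ``P(f)`` over grid points whose power exceeds the significance
    threshold within each ``[edge_i, edge_{i+1}]`` band, normalized by the
    significant sum over the full edge span and expressed as a percentage.
    When no grid point is significant the partition is undefined (NaN),
    mirroring the "no significant amplitude" case rather than reporting
    0/0.
    """
    edges = np.asarray(band_edges, float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("band_edges must be increasing with >= 2 entries")
    plo, phi = pg.period_range
    if edges[0] < plo - 1e-6 or edges[-1] > phi + 1e-6:
        raise ValueError("band edges outside periodogram range")
    sig = pg.significant
    p, w = pg.periods, pg.power
    in_span = (p >= edges[0] - 1e-12) & (p <= edges[-1] + 1e-12)
    total = w[sig & in_span].sum()
    if total <= 0:
        pct = np.full(edges.size - 1, np.nan)
        return BandPartition(tuple(edges), pct, 0.0)
    pct = np.empty(edges.size - 1)
    for i in range(edges.size - 1):
        # half-open [lo, hi) except the last band, closed at the top edge
        lo, hi = edges[i], edges[i + 1]
        if i == edges.size - 2:
            band = (p >= lo - 1e-12) & (p <= hi + 1e-12)
        else:
            band = (p >= lo - 1e-12) & (p < hi - 1e-12)
        pct[i] = 100.0 * w[sig & band].sum() / total
    return BandPartition(tuple(edges), pct, float(total))


def highest_peak(pg: Periodogram, search_range: tuple | None = None) -> float:
    """Period of the globally maximal *significant* power in range.

    Returns NaN when no grid point in the search range is significant.
    """
    lo, hi = search_range if search_range is not None else pg.period_range
    plo, phi = pg.period_range
    if lo < plo - 1e-6 or hi > phi + 1e-6:
        raise ValueError("search range outside periodogram range")
    sel = (pg.periods >= lo - 1e-12) & (pg.periods <= hi + 1e-12) & pg.significant
    if not sel.any():
        return float("nan")
    idx = np.flatnonzero(sel)
    return float(pg.periods[idx[np.argmax(pg.power[idx])]])


# ---------------------------------------------------------------------------
# trough-anchored split
# ---------------------------------------------------------------------------

def _smooth(w: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return w
    pad = k // 2
    ext = np.r_[np.repeat(w[0], pad), w, np.repeat(w[-1], pad)]
    kernel = np.ones(k) / k
    return np.convolve(ext, kernel, mode="valid")


def find_trough(baseline_pg: Periodogram, smooth_points: int = 5
                ) -> tuple[float, float, bool]:
    """Locate the trough following the dominant periodogram peak.

    Power is lightly smoothed (centered moving average over
    ``smooth_points`` grid points) before the search; the trough is the
    first local minimum at periods above the dominant-peak period, ties
    broken toward the smaller period.  When no local minimum occurs below
    the top of the grid the midpoint between the peak and the top period
    is returned with ``fallback=True``.

    Returns ``(tro, peak_period, fallback)``.
    """
    order = np.argsort(baseline_pg.periods)  # ascending period
    p = baseline_pg.periods[order]
    w = _smooth(baseline_pg.power[order], smooth_points)
    i_peak = int(np.argmax(w))
    peak_period = float(p[i_peak])
    for i in range(i_peak + 1, p.size - 1):
        if w[i] < w[i - 1] and w[i] <= w[i + 1]:
            return float(p[i]), peak_period, False
    top = float(p[-1])
    return 0.5 * (peak_period + top), peak_period, True


def trough_after_peak(target_pg: Periodogram, baseline_pg: Periodogram,
                      smooth_points: int = 5) -> TroughSplit:
    """%ASD split of ``target_pg`` at the baseline-derived trough.

    ``baseline_pg`` should span the ultradian-to-circadian range (up to
    24 h) of a 96-h baseline window; the trough after its dominant peak
    becomes the animal-specific divider, and the significant density of
    ``target_pg`` is partitioned into the segments below (0 h to Tro) and
    above (Tro to 24 h) that divider.
    """
    tro, peak_period, fallback = find_trough(baseline_pg, smooth_points)
    sig = target_pg.significant
    p, w = target_pg.periods, target_pg.power
    total = w[sig].sum()
    if total <= 0:
        below = above = float("nan")
    else:
        below = 100.0 * w[sig & (p <= tro)].sum() / total
        above = 100.0 * w[sig & (p > tro)].sum() / total
    return TroughSplit(tro=tro, asd_below_pct=below, asd_above_pct=above,
                       peak_period=peak_period, fallback=fallback)


# ---------------------------------------------------------------------------
# composite display
# ---------------------------------------------------------------------------

def composite_matrix(pgs: list, n_points: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Stack periodograms row-wise, each normalized to its own maximum.

    Rows are interpolated onto a common frequency-uniform grid spanning
    the intersection of the inputs' period ranges.  Rows with no
    significant power are set to NaN (displayed gray in composite
    heatmaps).  Returns ``(period_grid, matrix)``.
    """
    if not pgs:
        return np.empty(0), np.empty((0, 0))
    lo = max(pg.period_range[0] for pg in pgs)
    hi = min(pg.period_range[1] for pg in pgs)
    freqs = np.linspace(1.0 / hi, 1.0 / lo, n_points)
    grid = 1.0 / freqs
    rows = []
    for pg in pgs:
        order = np.argsort(1.0 / pg.periods)
        fsrc = (1.0 / pg.periods)[order]
        wsrc = pg.power[order]
        row = np.interp(freqs, fsrc, wsrc)
        if pg.significant.any() and row.max() > 0:
            row = row / row.max()
        else:
            row = np.full_like(row, np.nan)
        rows.append(row)
    return grid, np.vstack(rows)
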