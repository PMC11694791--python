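import numpy as np
import pytest

import infrakit as ik
from infrakit import ActivityRecord
from infrakit.spectral import n_independent_frequencies

from conftest import tone_record


def ls_oracle(t, y, period):
    """Independent least-squares statistic: fit a sine+cosine pair by
    normal equations and report the sum-of-squares reduction over twice
    the sample variance."""
    yc = y - y.mean()
    x = np.column_stack([np.cos(2 * np.pi * t / period),
                         np.sin(2 * np.pi * t / period)])
    beta, *_ = np.linalg.lstsq(x, yc, rcond=None)
    r = yc - x @ beta
    var = yc @ yc / (yc.size - 1)
    return (yc @ yc - r @ r) / (2 * var)


class TestLombScargle:
    def test_single_tone_recovery(self):
        rec = tone_record([48.0], [1.0], days=28)
        pg = ik.lomb_scargle(rec)
        peak = pg.periods[np.argmax(pg.power)]
        assert abs(peak - 48.0) <= pg.grid_step_at(48.0)
        assert pg.power.max() > 10 * pg.sig_level

    def test_constant_series_nothing_significant(self):
        rec = ActivityRecord(counts=np.full(288 * 28, 7.0), bin_width=5.0)
        pg = ik.lomb_scargle(rec, alpha=1e-3)
        assert not pg.significant.any()

    def test_too_few_bins(self):
        rec = ActivityRecord(counts=np.ones(5), bin_width=5.0)
        with pytest.raises(ValueError):
            ik.lomb_scargle(rec, (1, 2))

    def test_empty_period_range(self):
        rec = tone_record([24.0], [1.0], days=10)
        with pytest.raises(ValueError):
            ik.lomb_scargle(rec, (30.0, 30.0))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_least_squares_oracle_gapped(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(60, 500))
        t = np.arange(n) * (5 / 60.0)
        y = (rng.normal(0, 1, n)
             + rng.uniform(0.5, 3) * np.sin(2 * np.pi * t / rng.uniform(3, 15)))
        mask = rng.random(n) < 0.2
        rec = ActivityRecord(counts=y - y.min(), bin_width=5.0, gap_mask=mask)
        with pytest.warns(UserWarning):
            pg = ik.lomb_scargle(rec, (2, 20), oversample=4)
        tt, yy = rec.unmasked()
        trial = rng.choice(pg.periods.size, min(20, pg.periods.size), replace=False)
        for i in trial:
            z = ls_oracle(tt, yy, pg.periods[i])
            assert abs(z - pg.power[i]) <= 1e-8 * max(z, 1e-12)


class TestSignificance:
    def test_alpha_to_one_threshold_to_zero(self):
        assert ik.significance_level(100, 1 - 1e-12, 1) < 1e-11

    def test_threshold_monotone_in_alpha(self):
        zs = [ik.significance_level(200, a, 100)
              for a in (0.2, 0.1, 0.05, 0.01, 0.001)]
        assert all(b > a for a, b in zip(zs, zs[1:]))

    def test_monte_carlo_calibration(self):
        """Family-wise exceedance at alpha=0.05 on white noise lands near
        the nominal rate (loose band; the acceptance suite runs 2000)."""
        rng = np.random.default_rng(7)
        n, bw = 400, 5.0
        hits = 0
        reps = 400
        for _ in range(reps):
            y = rng.normal(0, 1, n)
            rec = ActivityRecord(counts=y - y.min(), bin_width=bw)
            with np.errstate(all="ignore"):
                pg = ik.lomb_scargle(rec, (2, 16), oversample=10, alpha=0.05)
            hits += pg.power.max() > pg.sig_level
        assert 0.02 <= hits / reps <= 0.09

    def test_permutation_threshold_same_ballpark(self):
        rec = tone_record([], [], days=6, bin_minutes=5, noise_sd=1.0,
                          offset=10.0, seed=1)
        z_perm = ik.permutation_sig_level(rec, (2, 16), alpha=0.05,
                                          n_perm=100, seed=0)
        t, y = rec.unmasked()
        m = n_independent_frequencies(y.size, t[-1] - t[0], (1 / 16, 1 / 2))
        z_an = ik.significance_level(y.size, 0.05, m)
        assert 0.5 * z_an < z_perm < 2.0 * z_an


class TestPercentASD:
    def test_all_mass_in_one_infradian_peak(self):
        rec = tone_record([48.0], [3.0], days=28, noise_sd=0.3)
        part = ik.percent_asd(ik.lomb_scargle(rec))
        assert part.asd_percent[0] == pytest.approx(0.0, abs=1e-9)
        assert part.asd_percent[1] == pytest.approx(100.0, abs=1e-9)

    def test_partition_sums_to_100(self):
        rec = tone_record([24.0, 48.0], [1.0, 1.0], days=28, noise_sd=0.5)
        part = ik.percent_asd(ik.lomb_scargle(rec))
        assert part.defined
        assert part.asd_percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_two_equal_tones_match_direct_summation(self):
        rec = tone_record([24.0, 48.0], [1.0, 1.0], days=28, noise_sd=0.2)
        pg = ik.lomb_scargle(rec)
        part = ik.percent_asd(pg, (20, 27, 96))
        sig = pg.power > pg.sig_level
        total = pg.power[sig].sum()
        circ = pg.power[sig & (pg.periods < 27)].sum()
        assert part.asd_percent[0] == pytest.approx(100 * circ / total, abs=1e-9)

    def test_nothing_significant_gives_nan(self):
        rec = ActivityRecord(counts=np.full(288 * 28, 3.0), bin_width=5.0)
        part = ik.percent_asd(ik.lomb_scargle(rec, alpha=1e-3))
        assert not part.defined
        assert np.isnan(part.asd_percent).all()

    def test_scale_invariance(self):
        rec = tone_record([30.0], [2.0], days=28, noise_sd=0.5)
        part1 = ik.percent_asd(ik.lomb_scargle(rec))
        part2 = ik.percent_asd(ik.lomb_scargle(rec.with_counts(rec.counts * 37)))
        np.testing.assert_allclose(part1.asd_percent, part2.asd_percent,
                                   atol=1e-9)

    def test_band_edges_outside_range_rejected(self):
        rec = tone_record([48.0], [1.0], days=28)
        with pytest.raises(ValueError):
            ik.percent_asd(ik.lomb_scargle(rec), (10, 27, 96))

    def test_grid_refinement_stability(self):
        rec = tone_record([24.0, 48.0], [1.0, 0.7], days=28, noise_sd=0.3)
        a = ik.percent_asd(ik.lomb_scargle(rec, oversample=10)).asd_percent
        b = ik.percent_asd(ik.lomb_scargle(rec, oversample=20)).asd_percent
        assert np.all(np.abs(a - b) < 1.0)


class TestHighestPeak:
    def test_pure_tone(self):
        rec = tone_record([48.0], [2.0], days=28, noise_sd=0.2)
        pg = ik.lomb_scargle(rec)
        assert abs(ik.highest_peak(pg) - 48.0) <= pg.grid_step_at(48.0)

    def test_larger_amplitude_wins(self):
        rec = tone_record([24.0, 48.0], [1.0, 2.0], days=28, noise_sd=0.2)
        pg = ik.lomb_scargle(rec)
        sig = pg.power > pg.sig_level
        idx = np.flatnonzero(sig)
        direct = pg.periods[idx[np.argmax(pg.power[idx])]]
        assert ik.highest_peak(pg) == direct
        assert abs(direct - 48.0) <= pg.grid_step_at(48.0)

    def test_white_noise_below_threshold_is_nan(self):
        rec = tone_record([], [], days=28, noise_sd=1.0, offset=10.0, seed=2)
        pg = ik.lomb_scargle(rec, alpha=1e-3)
        if not pg.significant.any():
            assert np.isnan(ik.highest_peak(pg))

    def test_peak_lies_in_band_with_positive_asd(self):
        rec = tone_record([70.0], [2.0], days=28, noise_sd=0.4)
        pg = ik.lomb_scargle(rec)
        part = ik.percent_asd(pg)
        peak = ik.highest_peak(pg)
        band = 0 if peak < 27 else 1
        assert part.asd_percent[band] > 0


class TestTroughSplit:
    def test_single_ultradian_tone_geometry(self):
        rec = tone_record([4.0], [3.0], days=4, noise_sd=0.3)
        pg = ik.lomb_scargle(rec, (2, 24), oversample=10)
        split = ik.trough_after_peak(pg, pg)
        assert abs(split.peak_period - 4.0) < 0.3
        assert 4.0 < split.tro <= 8.0
        assert split.asd_below_pct > 95.0

    def test_smoothing_noop_on_noiseless_input(self):
        rec = tone_record([4.0], [3.0], days=4, noise_sd=0.0, offset=5.0)
        pg = ik.lomb_scargle(rec, (2, 24), oversample=10)
        t1, _, _ = ik.find_trough(pg, smooth_points=1)
        t5, _, _ = ik.find_trough(pg, smooth_points=5)
        assert abs(t1 - t5) <= 2 * pg.grid_step_at(t1)

    def test_period_shift_moves_density_above_trough(self):
        hits = 0
        for s in range(8):
            base = ik.simulate_locomotor(ik.OscillatorSpec(
                scn_amplitude=0.0, do_period_trajectory=4.0,
                do_amplitude_trajectory=2.0, seed=300 + s), 4)
            treat = ik.simulate_locomotor(ik.OscillatorSpec(
                scn_amplitude=0.0, do_period_trajectory=6.0,
                do_amplitude_trajectory=2.0, seed=400 + s), 4)
            pgb = ik.lomb_scargle(base, (2, 24))
            pgt = ik.lomb_scargle(treat, (2, 24))
            hits += (ik.trough_after_peak(pgt, pgb).asd_above_pct
                     > ik.trough_after_peak(pgb, pgb).asd_above_pct)
        assert hits == 8

    def test_no_trough_falls_back_to_midpoint(self):
        # monotone rising power profile: peak at the top, no interior minimum
        periods = 1.0 / np.linspace(1 / 24, 1 / 2, 200)
        power = 1.0 / periods[::-1].copy()[::-1]  # increasing with period
        pg = ik.Periodogram(periods=periods, power=np.linspace(0.1, 5, 200),
                            sig_level=1.0, alpha=1e-3, n_effective=100)
        tro, peak, fallback = ik.find_trough(pg)
        assert fallback
        assert peak < tro < 24.0


def test_composite_rows_normalized_to_own_max():
    pgs = [ik.lomb_scargle(tone_record([p], [2.0], days=28, noise_sd=0.3,
                                       seed=p), (20, 96))
           for p in (30, 48, 72)]
    grid, mat = ik.composite_matrix(pgs, n_points=200)
    assert mat.shape == (3, 200)
    np.testing.assert_allclose(np.nanmax(mat, axis=1), 1.0)
    # each row's max sits near its programmed period
    for row, p in zip(mat, (30, 48, 72)):
        assert abs(grid[np.nanargmax(row)] - p) < 0.1 * p
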