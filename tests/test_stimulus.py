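import numpy as np
import pytest
from scipy import stats

from dendroclust import stimulus as st
from dendroclust.metrics import boxcar_correlation, orientation_difference


class TestWaveGenerator:
    def test_deterministic(self):
        a = st.generate_wave_movie(duration_ms=10e3, seed=5)
        b = st.generate_wave_movie(duration_ms=10e3, seed=5)
        assert np.array_equal(a.frames, b.frames)

    def test_zero_rate_means_dark_field(self):
        m = st.generate_wave_movie(duration_ms=5e3, wave_rate=0.0, seed=1)
        assert np.all(m.frames == 0.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            st.generate_wave_movie(duration_ms=-5.0, seed=1)
        with pytest.raises(ValueError):
            st.sample_waves(80.0, 1e3, seed=1)   # extent below 100 degrees

    def test_closed_form_matches_reference(self):
        waves = st.sample_waves(140.0, 30e3, rate_per_min=60.0, seed=2)
        rfs = st.sample_receptive_fields(4, 5.3, 13.4, seed=3)
        ws = st.WaveStimulus(rfs, 140.0, waves=waves)
        fast = ws.drive(0.0, 30e3, 50.0)
        ref = st.wave_drive_series(waves, rfs, np.arange(0, 30e3, 50.0) + 25.0)
        assert np.max(np.abs(fast - ref)) < 5e-3

    def test_closed_form_matches_raster(self):
        waves = st.sample_waves(140.0, 30e3, rate_per_min=60.0, seed=2)
        rfs = st.sample_receptive_fields(4, 5.3, 13.4, seed=3)
        movie = st.generate_wave_movie(140.0, 30e3, waves=waves)
        raster = st.movie_drive_series(movie, rfs)
        analytic = st.WaveStimulus(rfs, 140.0, waves=waves).drive(0, 30e3, 50.0)
        r = np.corrcoef(raster.ravel(), analytic.ravel())[0, 1]
        assert r > 0.99


class TestWhiteNoise:
    def test_no_temporal_correlation(self):
        m = st.generate_white_noise_movie(duration_ms=30e3, seed=4)
        f = m.frames.reshape(m.n_frames, -1)
        lag1 = np.mean([np.corrcoef(f[:-1, i], f[1:, i])[0, 1]
                        for i in range(0, f.shape[1], 97)])
        assert abs(lag1) < 0.05

    def test_spatial_smoothing_scale(self):
        """Autocorrelation of a 2-deg-filtered white field has std sqrt(2)*2 deg,
        i.e. FWHM ~ 6.7 deg; measured at ~1-deg pixels."""
        m = st.generate_white_noise_movie(duration_ms=10e3, pixel_scale=1.0, seed=6)
        f = m.frames
        # spatial autocorrelation along one axis, averaged over frames/rows
        ac = []
        for lag in range(0, 9):
            a = f[:, :, :-lag or None]
            b = f[:, :, lag:]
            ac.append(np.mean((a - a.mean()) * (b - b.mean())) / f.var())
        ac = np.array(ac)
        # Gaussian autocorr: exp(-lag^2/(2*(sqrt(2)*2)^2)) in pixels of 1 deg
        expected = np.exp(-np.arange(9) ** 2 / (2 * 8.0))
        assert np.allclose(ac, expected, atol=0.1)

    def test_drive_distribution_is_exact(self):
        """Sampled WN drives match the projected-raster distribution."""
        rfs = st.sample_receptive_fields(6, 5.3, 13.4, seed=7)
        wn = st.WhiteNoiseStimulus(rfs, seed=8, target_drive_std=None)
        drive = wn.drive(0, 30 * 60e3, 50.0)
        movie = st.generate_white_noise_movie(duration_ms=60e3, seed=9)
        proj = st.movie_drive_series(movie, rfs)
        # same per-synapse std (exactness of the covariance construction)
        assert np.allclose(drive.std(axis=1), proj.std(axis=1), rtol=0.15)


class TestReceptiveFields:
    def test_centres_inside_truncation_circle(self):
        rfs = st.sample_receptive_fields(500, 26.0, 20.0, seed=1)
        norms = [np.hypot(*rf.center) for rf in rfs]
        assert max(norms) <= st.RF_TRUNCATION_RADIUS

    def test_centre_spread_matches_sigma_p(self):
        rfs = st.sample_receptive_fields(4000, 5.3, 13.4, seed=2)
        xs = np.array([rf.center[0] for rf in rfs])
        assert xs.std() == pytest.approx(5.3, rel=0.05)

    def test_orientations_uniform(self):
        rfs = st.sample_receptive_fields(10000, 5.3, 13.4, seed=3)
        th = np.array([rf.theta for rf in rfs])
        counts, _ = np.histogram(th, bins=12, range=(0, 360))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            st.sample_receptive_fields(0, 5.3, 13.4)
        with pytest.raises(ValueError):
            st.GaborRF(center=(60.0, 0.0), theta=0.0, diameter=13.4)


class TestRasterFilter:
    def test_two_lobe_filter_integrates_to_zero(self):
        rf = st.GaborRF(center=(3.0, -2.0), theta=30.0, diameter=13.4)
        img = st.rasterize_filter(rf)
        assert abs(img.sum()) < 1e-9

    def test_half_turn_negates_filter(self):
        a = st.rasterize_filter(st.GaborRF(center=(0, 0), theta=20.0, diameter=13.4))
        b = st.rasterize_filter(st.GaborRF(center=(0, 0), theta=200.0, diameter=13.4))
        assert np.allclose(a, -b, atol=1e-12)

    def test_on_off_polarity(self):
        on = st.rasterize_filter(st.GaborRF(center=(0, 0), theta=0.0,
                                            diameter=20.0, kind="on"))
        off = st.rasterize_filter(st.GaborRF(center=(0, 0), theta=0.0,
                                             diameter=20.0, kind="off"))
        assert np.all(on >= 0) and np.all(off <= 0)
        assert np.allclose(on, -off)

    def test_support_check(self):
        rf = st.GaborRF(center=(30.0, 30.0), theta=0.0, diameter=30.0)
        with pytest.raises(ValueError):
            st.rasterize_filter(rf, extent=100.0)


class TestRFNoise:
    def test_forced_zero_scale_is_identity(self, rng):
        img = st.rasterize_filter(st.GaborRF(center=(0, 0), theta=0.0, diameter=13.4))
        out = st.add_rf_noise(img, rng, forced_scale=0.0)
        assert np.array_equal(out, img)

    def test_noised_overlap_between_zero_and_one(self, rng):
        img = st.rasterize_filter(st.GaborRF(center=(0, 0), theta=0.0, diameter=13.4))
        overlaps = []
        for _ in range(20):
            noisy = st.add_rf_noise(img, rng)
            overlaps.append(np.corrcoef(img.ravel(), noisy.ravel())[0, 1])
        assert 0.0 < np.mean(overlaps) < 1.0


class TestLNEncoding:
    def test_flat_movie_gives_baseline_rate(self):
        """A dark field encodes as homogeneous Poisson at a = 0.2 Hz."""
        movie = st.generate_wave_movie(duration_ms=60e3, wave_rate=0.0, seed=0)
        rfs = st.sample_receptive_fields(20, 5.3, 13.4, seed=1)
        # loop the 1-min movie statistics by encoding repeatedly
        rates = []
        for s in range(30):
            tr = st.ln_encode(movie, rfs, seed=100 + s)
            rates.append(tr.event_rate_per_min())
        mean_rate = np.mean(rates)
        expected = 0.2 * 60.0
        n_events = mean_rate * len(rates) * len(rfs)
        se = expected / np.sqrt(n_events)
        assert abs(mean_rate - expected) < 3 * se + 0.2   # binning bias margin

    def test_b_zero_ignores_stimulus(self):
        movie = st.generate_wave_movie(duration_ms=30e3, seed=2)
        rfs = st.sample_receptive_fields(5, 5.3, 13.4, seed=3)
        a = st.ln_encode(movie, rfs, b=0.0, seed=4)
        flat = st.StimulusMovie(frames=np.zeros_like(movie.frames),
                                pixel_scale=movie.pixel_scale,
                                frame_interval=movie.frame_interval,
                                extent=movie.extent)
        b = st.ln_encode(flat, rfs, b=9.4, seed=4)
        assert np.array_equal(a.data, b.data)

    def test_event_wellformedness(self):
        tr = st.correlated_poisson(3, 30.0, 0.2, 5 * 60e3, seed=5)
        dense = tr.to_dense(5.0)
        # every event lasts exactly x_dur (runs are multiples of 10 steps)
        for k in range(3):
            x = np.concatenate([[0], dense[k], [0]])
            starts = np.where(np.diff(x) == 1)[0]
            ends = np.where(np.diff(x) == -1)[0]
            assert np.all((ends - starts) % 10 == 0)

    def test_orientation_correlation_structure(self):
        """Wave-driven LN correlations decrease monotonically over 30-deg
        orientation-difference bins; white noise stays flat (ferret preset)."""
        rng = np.random.default_rng(11)
        rfs = st.sample_receptive_fields(40, 5.3, 13.4, rng=rng)
        ws = st.WaveStimulus(rfs, loop_ms=3600e3, rate_per_min=60.0,
                             rng=np.random.default_rng(12))
        drive = ws.drive(0, 3600e3, 50.0)
        ev = st.events_from_rate(0.2 * np.exp(9.4 * drive), 50.0,
                                 np.random.default_rng(13))
        corr = boxcar_correlation(st.EventTrain(ev, 50.0))
        th = np.array([rf.theta for rf in rfs])
        iu = np.triu_indices(len(rfs), 1)
        dth = orientation_difference(th[iu[0]], th[iu[1]])
        c = corr[iu]
        bins = [np.nanmean(c[(dth >= lo) & (dth < lo + 30)]) for lo in (0, 30, 60)]
        assert bins[0] > bins[1] > bins[2]

        wn = st.WhiteNoiseStimulus(rfs, rng=np.random.default_rng(14))
        dwn = wn.drive(0, 3600e3, 50.0)
        evn = st.events_from_rate(0.2 * np.exp(9.4 * dwn), 50.0,
                                  np.random.default_rng(15))
        cwn = boxcar_correlation(st.EventTrain(evn, 50.0))[iu]
        lo_b = np.nanmean(cwn[dth < 30])
        hi_b = np.nanmean(cwn[dth >= 60])
        assert abs(lo_b - hi_b) < 0.03


class TestCorrelatedPoisson:
    def test_perfect_copy(self):
        tr = st.correlated_poisson(4, 15.0, 1.0, 10 * 60e3, seed=1)
        assert np.array_equal(tr.data[0], tr.data[1])
        assert np.array_equal(tr.data[0], tr.data[3])

    def test_independent_limit(self):
        tr = st.correlated_poisson(2, 60.0, 0.0, 3600e3, seed=2)
        r = np.corrcoef(tr.data[0], tr.data[1])[0, 1]
        assert abs(r) < 0.02

    def test_target_correlation_recovered(self):
        tr = st.correlated_poisson(2, 15.0, 0.35, 4 * 3600e3, seed=3)
        r = np.corrcoef(tr.data[0], tr.data[1])[0, 1]
        assert r == pytest.approx(0.35, abs=0.03)

    def test_rate_preserved_across_c(self):
        for c in (0.0, 0.3, 0.8):
            tr = st.correlated_poisson(3, 15.0, c, 3600e3, seed=4)
            assert tr.event_rate_per_min().mean() == pytest.approx(15.0, rel=0.1)

    def test_invalid_correlation(self):
        with pytest.raises(ValueError):
            st.correlated_poisson(2, 15.0, 1.5, 1e3)
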