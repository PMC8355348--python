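import numpy as np
import pytest

from thetaburst import (
    LFPSignal,
    PhaseSeries,
    band_power,
    detect_theta_epochs,
    instantaneous_phase,
    multitaper_psd,
    phase_histogram,
    phase_histogram_squared_difference,
    rayleigh_test,
    silverman_modality_test,
)

RATE = 1250.0


def sine(freq, duration, rate=RATE, amplitude=1.0):
    t = np.arange(int(duration * rate)) / rate
    return LFPSignal(amplitude * np.sin(2 * np.pi * freq * t), rate)


class TestThetaEpochs:
    def test_pure_theta_covers_record(self):
        ep = detect_theta_epochs(sine(8.0, 60.0))
        assert ep.total_duration > 58.0

    def test_pure_delta_gives_no_epochs(self):
        ep = detect_theta_epochs(sine(2.0, 60.0))
        assert ep.total_duration == 0.0

    def test_switch_point_located_within_one_window(self):
        t1 = np.arange(int(30 * RATE)) / RATE
        sig = np.concatenate(
            [np.sin(2 * np.pi * 2.0 * t1), np.sin(2 * np.pi * 8.0 * t1)]
        )
        ep = detect_theta_epochs(LFPSignal(sig, RATE), window=1.0)
        assert len(ep.intervals) == 1
        start = ep.intervals[0][0]
        assert abs(start - 30.0) <= 1.0

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            detect_theta_epochs(LFPSignal(np.ones(100), rate=10.0))


class TestInstantaneousPhase:
    def test_trough_zero_convention(self):
        # s(t) = cos(2 pi 8 t): peak at t=0 -> 180 deg; trough at 1/16 s -> 0/360
        t = np.arange(int(4 * RATE)) / RATE
        lfp = LFPSignal(np.cos(2 * np.pi * 8.0 * t), RATE)
        ph = instantaneous_phase(lfp)
        mid_peak = ph.at(np.array([2.0]))[0]       # t=2 s is a peak (16 cycles)
        assert abs(mid_peak - 180.0) < 2.0
        trough = ph.at(np.array([2.0 + 1.0 / 16.0]))[0]
        assert min(trough, 360.0 - trough) < 2.0

    def test_unwrapped_slope_matches_frequency(self):
        ph = instantaneous_phase(sine(8.0, 4.0))
        un = np.unwrap(np.radians(ph.phase))
        sl = np.polyfit(ph.t[500:-500], np.degrees(un[500:-500]), 1)[0]
        assert sl == pytest.approx(8.0 * 360.0, rel=0.01)

    def test_chirp_trough_times_match_signal_minima(self):
        t = np.arange(int(20 * RATE)) / RATE
        freq = 6.0 + (9.0 - 6.0) * t / t[-1]
        inst = np.cumsum(freq) / RATE
        sig = -np.cos(2 * np.pi * inst)  # minima where phase = 0 mod 360
        ph = instantaneous_phase(LFPSignal(sig, RATE))
        # phase zero-crossings (wrap points) inside the record
        wrapped = np.radians(ph.phase)
        crossings = np.where(np.diff(np.unwrap(wrapped) % (2 * np.pi)) < -np.pi)[0]
        from scipy.signal import argrelmin
        minima = argrelmin(sig, order=20)[0]
        minima = minima[(minima > 2 * RATE) & (minima < 18 * RATE)]
        for m in minima[::5]:
            assert np.min(np.abs(crossings - m)) <= 1

    def test_all_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(LFPSignal(np.zeros(1000), RATE))


class TestRayleigh:
    def test_perfect_concentration(self):
        out = rayleigh_test(np.full(100, 123.0))
        assert out["R"] == pytest.approx(1.0)
        assert out["p"] < 1e-30

    def test_perfect_uniformity(self):
        out = rayleigh_test(np.linspace(0, 360, 100, endpoint=False))
        assert out["R"] == pytest.approx(0.0, abs=1e-9)
        assert out["p"] > 0.99

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test(np.array([1.0, 2.0, 3.0]))

    def test_power_monotone_in_kappa(self, rng):
        power = []
        for kappa in (0.2, 0.5, 1.0, 2.0):
            rej = 0
            for _ in range(200):
                ph = np.degrees(rng.vonmises(0.0, kappa, size=30)) % 360
                if rayleigh_test(ph)["p"] < 0.05:
                    rej += 1
            power.append(rej / 200)
        assert all(b >= a for a, b in zip(power, power[1:]))
        assert power[-1] > 0.95


def make_phase_series(duration=200.0, freq=7.0, rate=RATE):
    t = np.arange(int(duration * rate)) / rate
    phase = (360.0 * freq * t) % 360.0
    return t, PhaseSeries(t=t, phase=phase)


class TestPhaseHistogram:
    def test_concentrated_events(self):
        t, ph = make_phase_series()
        # events at phase 99 deg (a bin centre): 7 t mod 1 = 99/360
        cycle = 1.0 / 7.0
        events = (np.arange(100) * 3 + 1) * cycle + (99.0 / 360.0) * cycle
        h = phase_histogram(events, ph, None, smooth_sd_bins=0)
        peak_bin = np.argmax(h.probability)
        assert h.bin_edges[peak_bin] <= 99.0 <= h.bin_edges[peak_bin + 1]
        assert h.probability[peak_bin] == pytest.approx(1.0)
        assert abs(h.mean_phase - 99.0) < 2.0
        assert h.resultant_length > 0.999

    def test_probability_sums_to_one(self, rng):
        t, ph = make_phase_series()
        events = np.sort(rng.uniform(1, 190, 500))
        h = phase_histogram(events, ph, None)
        assert np.nansum(h.probability) == pytest.approx(1.0, abs=1e-9)

    def test_occupancy_correction_flattens_distorted_phase(self, rng):
        # phase dwells longer on rising phases (sawtooth-like distortion);
        # uniform-in-time events must still give a flat corrected histogram
        duration = 400.0
        t = np.arange(int(duration * 250)) / 250.0
        lin = (7.0 * t) % 1.0
        distorted = 360.0 * lin**1.5  # nonuniform occupancy across phase
        ph = PhaseSeries(t=t, phase=distorted)
        events = np.sort(rng.uniform(1, duration - 1, 10_000))
        h = phase_histogram(events, ph, None, smooth_sd_bins=0)
        expected = 1.0 / 20.0
        ci = 4.0 * np.sqrt(expected * (1 - expected) / 10_000)
        # occupancy-weighted counts have extra variance; allow 2x binomial CI
        assert np.all(np.abs(h.probability - expected) < 2 * ci)
        # and without the correction the histogram is clearly non-flat
        raw, _ = np.histogram(ph.at(events), bins=20, range=(0, 360))
        raw = raw / raw.sum()
        assert np.max(np.abs(raw - expected)) > 4 * ci

    def test_von_mises_mean_recovery(self, rng):
        t, ph = make_phase_series(duration=300.0)
        mu = 344.0
        phases = np.degrees(rng.vonmises(np.radians(mu), 1.0, size=500)) % 360
        # place events at times whose phase matches the drawn phase:
        # 7 t = 4k + 1 sits at phase 0, then advance by the phase fraction
        cycle_starts = (np.arange(500) * 4 + 1) / 7.0
        events = cycle_starts + (phases / 360.0) / 7.0
        h = phase_histogram(np.sort(events), ph, None)
        err = (h.mean_phase - mu + 180) % 360 - 180
        assert abs(err) < 10.0
        assert h.rayleigh_p < 1e-6

    def test_squared_difference(self):
        t, ph = make_phase_series()
        ev = np.sort(np.arange(100) * 1.9 + 0.3)
        h1 = phase_histogram(ev, ph, None)
        h2 = phase_histogram(ev, ph, None)
        np.testing.assert_allclose(phase_histogram_squared_difference(h1, h2), 0.0)
        h3 = phase_histogram(ev + 0.5 / 7.0, ph, None)  # shift by half cycle
        d = phase_histogram_squared_difference(h1, h3)
        assert d.sum() > 0


class TestSilverman:
    def test_unimodal_not_rejected(self, rng):
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            ph = np.degrees(r.vonmises(1.0, 2.0, size=200)) % 360
            p = silverman_modality_test(ph, n_boot=120, seed=seed)
            if p > 0.1:
                hits += 1
        assert hits >= 3

    def test_antipodal_mixture_rejected(self, rng):
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            a = r.vonmises(0.0, 8.0, size=100)
            b = r.vonmises(np.pi, 8.0, size=100)
            ph = np.degrees(np.concatenate([a, b])) % 360
            p = silverman_modality_test(ph, n_boot=120, seed=seed)
            if p < 0.05:
                hits += 1
        assert hits >= 3

    def test_degenerate_point_mass(self):
        assert silverman_modality_test(np.full(50, 10.0)) == 1.0


class TestMultitaper:
    def test_peak_at_tone_frequency(self):
        t = np.arange(int(60 * RATE)) / RATE
        out = multitaper_psd(LFPSignal(np.sin(2 * np.pi * 7.0 * t), RATE))
        f = out["frequencies"]
        assert abs(f[np.argmax(out["psd"])] - 7.0) <= RATE / 1024

    def test_white_noise_band_power_scales_with_bandwidth(self, rng):
        sig = LFPSignal(rng.standard_normal(int(120 * RATE)), RATE)
        out = multitaper_psd(sig)
        f, p = out["frequencies"], out["psd"]
        bp_narrow = band_power(f, p, 100.0, 150.0)
        bp_wide = band_power(f, p, 100.0, 300.0)
        assert bp_wide / bp_narrow == pytest.approx(4.0, rel=0.05)

    def test_two_tone_power_ratio(self):
        t = np.arange(int(60 * RATE)) / RATE
        sig = 2.0 * np.sin(2 * np.pi * 7.0 * t) + 1.0 * np.sin(2 * np.pi * 30.0 * t)
        out = multitaper_psd(LFPSignal(sig, RATE))
        f, p = out["frequencies"], out["psd"]
        p7 = band_power(f, p, 5.0, 9.0)
        p30 = band_power(f, p, 28.0, 32.0)
        assert p7 / p30 == pytest.approx(4.0, rel=0.10)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            multitaper_psd(LFPSignal(np.ones(100), RATE), window=1024)
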