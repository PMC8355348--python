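import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thetaburst import (
    SpikeTrain,
    accommodation,
    burst_length_histogram,
    burst_rate_stats,
    post_event_conditional,
    segment_bursts,
)
from thetaburst.synthetic_data import (
    CONTROL_CELL,
    SynthConfig,
    expected_mean_isi_ms,
    simulate_session,
)


def brute_force_segment(times, max_isi_ms=15.0):
    """Independent run-scanner oracle: walk the train, grow a run while the
    next ISI is within threshold, close runs of >= 2 spikes as bursts."""
    bursts, singles = [], []
    run = []
    for t in times:
        if not run:
            run = [t]
        elif (t - run[-1]) * 1000.0 <= max_isi_ms:
            run.append(t)
        else:
            if len(run) >= 2:
                bursts.append(run)
            else:
                singles.append(run[0])
            run = [t]
    if run:
        (bursts if len(run) >= 2 else singles).append(run if len(run) >= 2 else run[0])
    return bursts, singles


class TestSegmentation:
    def test_forced_partition(self):
        seg = segment_bursts(SpikeTrain("u", [0.0, 0.010, 0.020, 0.100]))
        assert seg.n_bursts == 1 and seg.n_single == 1
        b = seg.bursts[0]
        assert b.onset == 0.0 and b.n_spikes == 3
        np.testing.assert_allclose(b.isis, [10.0, 10.0])

    def test_threshold_is_inclusive(self):
        seg = segment_bursts(SpikeTrain("u", [0.0, 0.015]))
        assert seg.n_bursts == 1 and seg.bursts[0].n_spikes == 2

    def test_just_above_threshold_splits(self):
        seg = segment_bursts(SpikeTrain("u", [0.0, 0.0151]))
        assert seg.n_bursts == 0 and seg.n_single == 2

    def test_empty_train(self):
        seg = segment_bursts(SpikeTrain("u", []))
        assert seg.n_bursts == 0 and seg.n_single == 0

    def test_oracle_equivalence_random_trains(self, rng):
        for _ in range(200):
            n = int(rng.integers(0, 500))
            times = np.cumsum(rng.exponential(0.012, size=n)) if n else np.empty(0)
            seg = segment_bursts(SpikeTrain("u", times))
            bursts, singles = brute_force_segment(times)
            assert seg.n_bursts == len(bursts)
            for got, want in zip(seg.bursts, bursts):
                np.testing.assert_array_equal(got.spike_times, want)
            np.testing.assert_array_equal(seg.single_spikes, singles)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        isis=st.lists(st.floats(min_value=1e-4, max_value=0.2), max_size=120),
        max_isi=st.floats(min_value=1.0, max_value=40.0),
    )
    def test_partition_conserves_counts(self, isis, max_isi):
        times = np.cumsum(np.asarray(isis))
        seg = segment_bursts(SpikeTrain("u", times), max_isi_ms=max_isi)
        assert seg.n_spikes_total == times.size
        merged = np.sort(np.concatenate([seg.single_spikes] +
                                        [b.spike_times for b in seg.bursts]))
        np.testing.assert_array_equal(merged, times)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        isis=st.lists(st.floats(min_value=1e-3, max_value=0.1), min_size=2, max_size=60),
        factor=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_scaling_invariance(self, isis, factor):
        times = np.cumsum(np.asarray(isis))
        a = segment_bursts(SpikeTrain("u", times), max_isi_ms=15.0)
        b = segment_bursts(SpikeTrain("u", times * factor), max_isi_ms=15.0 * factor)
        assert a.n_bursts == b.n_bursts and a.n_single == b.n_single
        for ba, bb in zip(a.bursts, b.bursts):
            np.testing.assert_allclose(bb.isis, ba.isis * factor, rtol=1e-9)


class TestRates:
    def test_simple_rates(self):
        times = []
        t = 0.0
        for _ in range(12):  # 12 two-spike bursts
            times += [t, t + 0.010]
            t += 1.0
        for _ in range(48):  # 48 singles
            times.append(t)
            t += 0.25
        seg = segment_bursts(SpikeTrain("u", np.array(times)))
        stats = burst_rate_stats(seg, 60.0)
        assert stats["burst_rate"] == pytest.approx(0.2)
        assert stats["single_rate"] == pytest.approx(0.8)
        assert stats["all_rate"] == pytest.approx((24 + 48) / 60.0)

    def test_empty_segmentation_rates(self):
        seg = segment_bursts(SpikeTrain("u", []))
        stats = burst_rate_stats(seg, 60.0)
        assert stats["burst_rate"] == 0 and stats["all_rate"] == 0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            burst_rate_stats(segment_bursts(SpikeTrain("u", [1.0])), 0.0)

    def test_control_preset_recovers_generator_rates(self, control_session):
        cfg, session, _ = control_session
        segs = [segment_bursts(u) for u in session.units]
        rates = np.array([burst_rate_stats(s, cfg.duration)["burst_rate"] for s in segs])
        sem = rates.std(ddof=1) / np.sqrt(rates.size)
        assert abs(rates.mean() - CONTROL_CELL.burst_event_rate) < max(2 * sem, 0.02)


class TestLengthHistogram:
    def test_per_cell_normalization(self):
        times = np.array([0.0, 0.01, 1.0, 1.01, 2.0, 2.01, 3.0, 3.01, 3.02])
        seg = segment_bursts(SpikeTrain("u", times))
        out = burst_length_histogram([seg])
        np.testing.assert_allclose(out["per_cell"][0], [0.75, 0.25, 0, 0, 0])

    def test_all_doublets(self):
        times = np.array([0.0, 0.01, 1.0, 1.01])
        out = burst_length_histogram([segment_bursts(SpikeTrain("u", times))])
        np.testing.assert_allclose(out["per_cell"][0], [1.0, 0, 0, 0, 0])

    def test_cell_without_bursts_warns(self):
        good = segment_bursts(SpikeTrain("a", [0.0, 0.01]))
        empty = segment_bursts(SpikeTrain("b", [0.0, 1.0]))
        with pytest.warns(UserWarning):
            out = burst_length_histogram([good, empty])
        assert out["per_cell"].shape[0] == 1

    def test_geometric_pmf_recovered(self, rng):
        # emit isolated bursts with geometric lengths; the empirical
        # histogram must match the pmf within a binomial CI at n = 1e4
        support = np.arange(2, 8)
        p = 0.55 ** (support - 2)
        p /= p.sum()
        lengths = rng.choice(support, size=10_000, p=p)
        times = []
        t = 0.0
        for n in lengths:
            times.extend(t + 0.005 * np.arange(n))
            t += 1.0
        seg = segment_bursts(SpikeTrain("u", np.asarray(times)))
        out = burst_length_histogram([seg])
        emp = out["per_cell"][0]
        expected = np.concatenate([p[:4], [p[4:].sum()]])
        n = len(lengths)
        ci = 3.0 * np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(emp - expected) <= ci)


class TestAccommodation:
    def test_single_burst_orders(self):
        seg = segment_bursts(SpikeTrain("u", [0.0, 0.005, 0.015]))
        prof = accommodation([seg])
        assert prof.mean_isi_by_order[(3, 1)][0] == pytest.approx(5.0)
        assert prof.mean_isi_by_order[(3, 2)][0] == pytest.approx(10.0)
        assert prof.accommodation_rate == pytest.approx(5.0)

    def test_flat_profile_zero_slope(self):
        times = []
        t = 0.0
        for _ in range(20):
            times.extend([t, t + 0.007, t + 0.014])
            t += 1.0
        prof = accommodation([segment_bursts(SpikeTrain("u", np.array(times)))])
        assert prof.accommodation_rate == pytest.approx(0.0, abs=1e-9)

    def test_no_bursts_raises(self):
        with pytest.raises(ValueError):
            accommodation([segment_bursts(SpikeTrain("u", [0.0, 1.0]))])

    def test_control_preset_slope_recovery(self, control_session):
        cfg, session, _ = control_session
        segs = [segment_bursts(u) for u in session.units]
        prof = accommodation(segs)
        assert abs(prof.accommodation_rate - CONTROL_CELL.isi_slope_ms) < 0.2
        expect = expected_mean_isi_ms(CONTROL_CELL)
        assert abs(prof.overall_mean_isi - expect) < 0.15

    def test_mutant_inverse_coupling(self, mutant_session):
        cfg, session, _ = mutant_session
        segs = [segment_bursts(u) for u in session.units]
        prof = accommodation(segs)
        assert abs(prof.accommodation_rate) < 0.3
        assert prof.mean_isi_by_length[5] < prof.mean_isi_by_length[2]


class TestPostEventConditional:
    def test_deterministic_latency(self):
        times = []
        t = 0.0
        for _ in range(20):
            times.extend([t, t + 0.010])        # burst
            times.append(t + 0.010 + 0.080)     # single, 80 ms after burst end
            t += 1.0
        seg = segment_bursts(SpikeTrain("u", np.array(times)))
        out = post_event_conditional(seg, "burst", "single")
        centers = out["bin_centers_ms"]
        below = centers < 77.5
        assert np.all(out["probability"][below] == 0)
        idx80 = np.argmin(np.abs(centers - 82.5))
        assert out["probability"][idx80] == pytest.approx(1.0)

    def test_poisson_hazard_closed_form(self, rng):
        lam = 3.0
        times = np.cumsum(rng.exponential(1.0 / lam, size=20_000))
        # rescale any burst-forming short ISIs away by thinning below 16 ms
        keep = np.concatenate([[True], np.diff(times) > 0.016])
        times = times[keep]
        seg = segment_bursts(SpikeTrain("u", times))
        assert seg.n_bursts == 0
        out = post_event_conditional(seg, "single", "single", window_ms=200, bin_ms=5)
        # dead-time-conditioned exponential: hazard of bins past 16 ms is
        # 1 - exp(-lam * bin)
        centers = out["bin_centers_ms"]
        usable = (centers > 20) & (centers < 120)
        expect = 1.0 - np.exp(-lam * 0.005)
        got = out["probability"][usable]
        assert abs(got.mean() - expect) < 0.2 * expect

    def test_suppression_minimum_in_expected_window(self, control_session):
        cfg, session, _ = control_session
        probs = []
        for u in session.units:
            seg = segment_bursts(u)
            out = post_event_conditional(seg, "burst", "single", window_ms=300, bin_ms=10)
            probs.append(out["probability"])
        mean_curve = np.mean(probs, axis=0)
        centers = out["bin_centers_ms"]
        early = mean_curve[centers <= 55.0].mean()
        late = mean_curve[(centers > 60.0) & (centers <= 200.0)].mean()
        assert early < 0.25 * late  # suppressed window nearly silent

    def test_window_must_exceed_bin(self, control_session):
        _, session, _ = control_session
        seg = segment_bursts(session.units[0])
        with pytest.raises(ValueError):
            post_event_conditional(seg, "burst", "single", window_ms=5, bin_ms=5)
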