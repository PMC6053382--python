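"""Event synchronization, cross-correlogram, population-burst detection."""

import numpy as np
import pytest

from meanet import (SpikeTrain, cross_correlation_peak, cross_correlogram,
                    detect_population_bursts, event_synchronization,
                    mean_cc_peak, mean_event_sync)


def brute_force_q(tx, ty, tau_max=0.05):
    """Exhaustive O(m*n) pairwise oracle for event synchronization."""
    def half_isis(t):
        out = []
        for i in range(len(t)):
            prev = t[i] - t[i - 1] if i > 0 else np.inf
            nxt = t[i + 1] - t[i] if i + 1 < len(t) else np.inf
            out.append(0.5 * min(prev, nxt))
        return out

    hx, hy = half_isis(tx), half_isis(ty)
    c = 0.0
    for i, a in enumerate(tx):
        for j, b in enumerate(ty):
            tau = min(hx[i], hy[j], tau_max)
            d = a - b
            if d == 0.0:
                c += 1.0  # half a coincidence in each direction
            elif (0 < d <= tau) or (0 < -d <= tau):
                c += 1.0
    return min(max(c / np.sqrt(len(tx) * len(ty)), 0.0), 1.0)


def brute_force_lag0(tx, ty, bin_width=0.1):
    n = sum(1 for a in tx for b in ty if -bin_width / 2 <= b - a < bin_width / 2)
    return n / np.sqrt(len(tx) * len(ty))


class TestEventSynchronization:
    def test_identical_trains_give_exactly_one(self, rng):
        t = np.sort(rng.uniform(0, 300, 20))
        x = SpikeTrain(t, duration=300.0)
        assert event_synchronization(x, SpikeTrain(t.copy(), duration=300.0)) == 1.0

    def test_asynchronous_trains_give_exactly_zero(self):
        a = SpikeTrain(np.arange(0.0, 300, 1.0), duration=300.0)
        b = SpikeTrain(np.arange(0.5, 300, 1.0), duration=300.0)
        assert event_synchronization(a, b) == 0.0

    def test_three_spike_example_matches_oracle(self):
        tx, ty = [0.0, 1.0, 2.0], [0.001, 1.001, 5.0]
        x = SpikeTrain(tx, duration=10.0)
        y = SpikeTrain(ty, duration=10.0)
        q = event_synchronization(x, y)
        assert q == brute_force_q(tx, ty)
        assert q == pytest.approx(2.0 / 3.0)  # two coincident pairs of three

    def test_equals_brute_force_on_random_pairs(self, rng):
        for _ in range(200):
            nx, ny = rng.integers(1, 50, size=2)
            tx = np.sort(rng.uniform(0, 10, nx))
            ty = np.sort(rng.uniform(0, 10, ny))
            if rng.random() < 0.3:  # inject exactly-equal spike times
                k = min(nx, ny) // 2
                ty = np.sort(np.concatenate([tx[:k], ty[k:]]))
            x = SpikeTrain(tx, duration=10.0)
            y = SpikeTrain(ty, duration=10.0)
            assert event_synchronization(x, y) == brute_force_q(tx, ty)

    def test_symmetric_no_directionality(self, rng):
        for _ in range(50):
            x = SpikeTrain(np.sort(rng.uniform(0, 10, rng.integers(1, 40))),
                           duration=10.0)
            y = SpikeTrain(np.sort(rng.uniform(0, 10, rng.integers(1, 40))),
                           duration=10.0)
            assert event_synchronization(x, y) == event_synchronization(y, x)

    def test_bounded_in_unit_interval_and_self_unity(self, rng):
        for _ in range(20):
            x = SpikeTrain(np.sort(rng.uniform(0, 5, rng.integers(1, 30))),
                           duration=5.0)
            assert event_synchronization(x, x) == 1.0

    def test_empty_train_rejected(self):
        x = SpikeTrain([1.0], duration=10.0)
        with pytest.raises(ValueError, match="active"):
            event_synchronization(x, SpikeTrain(np.empty(0), duration=10.0))

    def test_fixed_window_mode(self):
        x = SpikeTrain([1.0, 5.0], duration=10.0)
        y = SpikeTrain([1.04, 5.2], duration=10.0)
        assert event_synchronization(x, y, tau_mode="fixed", tau_max=0.05) == \
            pytest.approx(0.5)


class TestMeanEventSync:
    def test_three_identical_active_trains(self, well_factory):
        t = list(np.linspace(0.1, 299, 40))
        q, flags = mean_event_sync(well_factory([t, t, t]))
        assert q == 1.0 and flags == ()

    def test_two_trains_mean_is_pair_value(self, rng, well_factory):
        a = np.sort(rng.uniform(0, 300, 60))
        b = np.sort(rng.uniform(0, 300, 60))
        well = well_factory([a, b])
        q_pair = event_synchronization(SpikeTrain(a, duration=300.0),
                                       SpikeTrain(b, duration=300.0))
        assert mean_event_sync(well)[0] == q_pair

    def test_fewer_than_two_active_flagged(self, well_factory):
        q, flags = mean_event_sync(well_factory([list(np.linspace(0.1, 299, 40)),
                                                 [1.0]]))
        assert np.isnan(q) and "lt2_active_electrodes" in flags


class TestCrossCorrelogram:
    def test_identity_train_unit_peak_at_lag0(self):
        t = np.arange(0.0, 300, 1.0)  # ISIs > bin width
        x = SpikeTrain(t, duration=300.0)
        cc = cross_correlogram(x, SpikeTrain(t.copy(), duration=300.0))
        assert cc.lag0_value == pytest.approx(1.0)
        assert cc.lags.size == 201

    def test_shifted_train_peak_at_shift(self):
        t = np.arange(1.0, 290, 1.0)
        x = SpikeTrain(t, duration=300.0)
        y = SpikeTrain(t + 0.2, duration=300.0)
        cc = cross_correlogram(x, y)
        i_peak = int(np.argmax(cc.values))
        assert cc.lags[i_peak] == pytest.approx(0.2)
        assert cc.values[i_peak] == pytest.approx(1.0)
        assert cc.lag0_value == 0.0

    def test_mirror_symmetry(self, rng):
        x = SpikeTrain(np.sort(rng.uniform(0, 100, 80)), duration=100.0)
        y = SpikeTrain(np.sort(rng.uniform(0, 100, 50)), duration=100.0)
        cxy = cross_correlogram(x, y).values
        cyx = cross_correlogram(y, x).values
        assert np.allclose(cxy, cyx[::-1])

    def test_poisson_expectation(self, rng):
        """For independent Poisson trains the expected bin value is
        r_x r_y T bin / sqrt(r_x T r_y T)."""
        T, rx, ry = 600.0, 2.0, 3.0
        vals = []
        for _ in range(20):
            x = SpikeTrain(np.sort(rng.uniform(0, T, rng.poisson(rx * T))), duration=T)
            y = SpikeTrain(np.sort(rng.uniform(0, T, rng.poisson(ry * T))), duration=T)
            vals.append(cross_correlation_peak(x, y))
        expected = rx * ry * T * 0.1 / np.sqrt(rx * T * ry * T)
        assert np.mean(vals) == pytest.approx(expected, rel=0.1)

    def test_peak_equals_brute_force(self, rng):
        for _ in range(50):
            tx = np.sort(rng.uniform(0, 20, rng.integers(1, 40)))
            ty = np.sort(rng.uniform(0, 20, rng.integers(1, 40)))
            x = SpikeTrain(tx, duration=20.0)
            y = SpikeTrain(ty, duration=20.0)
            assert cross_correlation_peak(x, y) == pytest.approx(
                brute_force_lag0(tx, ty))
            assert cross_correlation_peak(x, y) == pytest.approx(
                cross_correlogram(x, y).lag0_value)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            cross_correlogram(SpikeTrain([1.0], duration=10.0),
                              SpikeTrain(np.empty(0), duration=10.0))

    def test_mean_cc_peak_identical_trains(self, well_factory):
        t = list(np.arange(0.5, 299, 1.0))
        v, flags = mean_cc_peak(well_factory([t, t, t]))
        assert v == pytest.approx(1.0) and flags == ()


def coactive_well(well_factory, n_coactive=6, n_single=4, duration=12.0):
    """Hand-constructed well: ``n_coactive`` electrodes fire 2 spikes in each
    of the three 100-ms bins of [6.0, 6.3); the others fire one isolated
    spike each (all electrodes active over the short recording)."""
    trains = []
    for e in range(n_coactive):
        off = e * 0.002
        trains.append([6.01 + off, 6.05 + off, 6.11 + off, 6.15 + off,
                       6.21 + off, 6.25 + off])
    for e in range(n_single):
        trains.append([1.0 + 0.9 * e])
    return well_factory(trains, duration=duration)


class TestPopulationBursts:
    def test_hand_constructed_single_burst(self, well_factory):
        well = coactive_well(well_factory)
        bursts, mbfr, mean_dur, flags = detect_population_bursts(well)
        assert len(bursts) == 1
        (b,) = bursts
        assert b.start == pytest.approx(6.0)
        assert b.stop == pytest.approx(6.3)
        assert b.n_spikes == 36
        assert mbfr == pytest.approx(1.0 / 12.0)
        assert mean_dur == pytest.approx(0.3)

    def test_silent_well(self, well_factory):
        bursts, mbfr, _, _ = detect_population_bursts(well_factory([[]], duration=10.0))
        assert bursts == [] and mbfr == 0.0

    def test_20_percent_coactive_is_no_burst(self, well_factory):
        well = coactive_well(well_factory, n_coactive=2, n_single=8)
        bursts, mbfr, _, _ = detect_population_bursts(well)
        assert bursts == [] and mbfr == 0.0

    def test_count_nonincreasing_in_thresholds(self, rng, well_factory):
        times = []
        events = np.sort(rng.uniform(1, 290, 40))
        for e in range(10):
            t = list(np.sort(rng.uniform(0, 300, 120)))
            for ev in events:
                if rng.random() < 0.7:
                    t.extend(ev + rng.uniform(0, 0.08, 4))
            times.append(np.sort(np.asarray(t)))
        well = well_factory(times)
        for arg, grid in (("frac_active", [0.1, 0.3, 0.5, 0.8]),
                          ("wmfr_min", [0.1, 0.5, 1.0, 2.0])):
            counts = [len(detect_population_bursts(well, **{arg: v})[0])
                      for v in grid]
            assert all(a >= b for a, b in zip(counts, counts[1:])), arg
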