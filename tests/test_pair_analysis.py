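import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_correlogram, poisson_train, spike_distance_grid_oracle
from surfspike.pair_analysis import (correlogram_peak_lag, cross_correlogram,
                                     pair_table, physical_distance, spike_distance)
from surfspike.types import ElectrodeGeometry, SpikeTrain


class TestCrossCorrelogram:
    def test_empty_train_gives_zero_counts(self):
        c = cross_correlogram(SpikeTrain("x", []), SpikeTrain("y", [0.1, 0.2]))
        assert c.counts.sum() == 0 and c.counts.size == 40

    def test_two_pairs_in_first_positive_bin(self):
        c = cross_correlogram(SpikeTrain("x", [0.0, 1.0]), SpikeTrain("y", [0.002, 1.002]))
        assert c.counts.sum() == 2
        assert c.counts[np.flatnonzero(c.lags == 2.5)[0]] == 2
        assert correlogram_peak_lag(c) == 2.5

    def test_antisymmetry(self, rng):
        x = poisson_train(20, 5, rng, "x")
        y = poisson_train(20, 5, rng, "y")
        cxy = cross_correlogram(x, y)
        cyx = cross_correlogram(y, x)
        # counts at lag L for (x, y) appear at -L for (y, x); with half-open
        # bins the mirrored histogram matches when no delta sits on an edge
        np.testing.assert_array_equal(cxy.counts, cyx.counts[::-1])

    def test_matches_brute_force_with_periods(self, rng):
        for _ in range(20):
            x = poisson_train(30, 3, rng, "x")
            y = poisson_train(30, 3, rng, "y")
            periods = [(0.0, 1.0), (1.5, 3.0)]
            c = cross_correlogram(x, y, periods=periods)
            keep = lambda t: ((t >= 0) & (t <= 1)) | ((t >= 1.5) & (t <= 3))
            expected = brute_force_correlogram(x.times[keep(x.times)],
                                               y.times[keep(y.times)])
            np.testing.assert_array_equal(c.counts, expected)

    def test_peak_lag_tie_break_prefers_negative(self):
        c = cross_correlogram(SpikeTrain("x", [1.0]), SpikeTrain("y", [0.999, 1.001]))
        assert correlogram_peak_lag(c) == -2.5

    def test_shifted_train_peak_recovered(self, rng):
        x = poisson_train(50, 20, rng, "x")
        y = SpikeTrain("y", x.times + 0.022)  # mid-bin shift, away from edges
        assert correlogram_peak_lag(cross_correlogram(x, y)) == 22.5  # bin [20, 25)

    def test_all_zero_correlogram_has_no_peak(self):
        with pytest.raises(ValueError):
            correlogram_peak_lag(cross_correlogram(SpikeTrain("x", []), SpikeTrain("y", [])))

    def test_invalid_bin_rejected(self):
        with pytest.raises(ValueError):
            cross_correlogram(SpikeTrain("x", [0.0]), SpikeTrain("y", [0.0]), bin=0)


class TestSpikeDistance:
    def test_identical_trains_distance_zero(self, rng):
        t = np.unique(rng.uniform(0, 4, 30))
        assert spike_distance(SpikeTrain("a", t), SpikeTrain("b", t), (0, 4)) == 0.0

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            x = poisson_train(rng.uniform(1, 20), 4, rng, "x")
            y = poisson_train(rng.uniform(1, 20), 4, rng, "y")
            d1 = spike_distance(x, y, (0, 4))
            d2 = spike_distance(y, x, (0, 4))
            assert d1 == pytest.approx(d2, abs=1e-12)
            assert 0.0 <= d1 <= 1.0

    def test_empty_train_conventions(self, rng):
        x = poisson_train(5, 4, rng, "x")
        empty = SpikeTrain("e", [])
        assert spike_distance(x, empty, (0, 4)) == 1.0
        assert spike_distance(empty, SpikeTrain("f", []), (0, 4)) == 0.0

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ValueError):
            spike_distance(SpikeTrain("x", [0.1]), SpikeTrain("y", [0.2]), (1.0, 1.0))

    def test_agrees_with_dense_grid_oracle(self, rng):
        for _ in range(10):
            x = poisson_train(rng.uniform(2, 10), 4, rng, "x")
            y = poisson_train(rng.uniform(2, 10), 4, rng, "y")
            d = spike_distance(x, y, (0, 4))
            o = spike_distance_grid_oracle(x.times, y.times, 0, 4)
            assert d == pytest.approx(o, abs=1e-3)


class TestPhysicalDistance:
    def test_euclidean_cases(self):
        g = ElectrodeGeometry(pd.DataFrame(
            [("A", "surface", 0.0, 0.0, 0.0),
             ("B", "surface", 200.0, 0.0, 0.0),
             ("C", "depth", 300.0, 0.0, 520.0)],
            columns=ElectrodeGeometry.COLUMNS))
        assert physical_distance(g, "A", "A") == 0.0
        assert physical_distance(g, "A", "B") == 200.0
        assert physical_distance(g, "A", "C") == pytest.approx(600.33, abs=0.01)

    def test_unknown_electrode_rejected(self):
        g = ElectrodeGeometry.default()
        with pytest.raises(KeyError):
            physical_distance(g, "S00", "nope")


class TestPairTable:
    @staticmethod
    def _geometry():
        return ElectrodeGeometry.default()

    def test_single_pair_correlation_undefined(self, rng):
        g = self._geometry()
        trains = {
            "d": poisson_train(5, 10, rng, "d", electrode_id="D00"),
            "s": poisson_train(5, 10, rng, "s", electrode_id="S00"),
        }
        df, r, p = pair_table(trains, g, (0, 10))
        assert len(df) == 1
        assert np.isnan(r) and np.isnan(p)

    def test_identical_trains_flagged_degenerate(self, rng):
        g = self._geometry()
        t = np.unique(rng.uniform(0, 10, 50))
        trains = {
            "d1": SpikeTrain("d1", t, electrode_id="D00"),
            "d2": SpikeTrain("d2", t, electrode_id="D05"),
            "s1": SpikeTrain("s1", t, electrode_id="S00"),
            "s2": SpikeTrain("s2", t, electrode_id="S10"),
        }
        df, r, p = pair_table(trains, g, (0, 10))
        assert len(df) == 4
        assert np.all(df.spike_distance == 0.0)
        assert np.isnan(r)  # zero variance in spike distance

    def test_mua_and_unknown_electrodes_excluded(self, rng):
        g = self._geometry()
        trains = {
            "d": poisson_train(5, 10, rng, "d", electrode_id="D00"),
            "s": poisson_train(5, 10, rng, "s", electrode_id="S00"),
            "m": poisson_train(5, 10, rng, "m", label="MUA", electrode_id="S01"),
            "x": poisson_train(5, 10, rng, "x", electrode_id="missing"),
        }
        df, _, _ = pair_table(trains, g, (0, 10))
        assert set(df.surface_unit) == {"s"} and set(df.depth_unit) == {"d"}
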