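"""QC, cleaning, connectivity and distance-conversion behaviour."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tauspread as tsp
from tauspread.exceptions import (
    DisconnectedTemplateError,
    InvalidConfigError,
    SchemaError,
)
from tauspread.fc_preproc import threshold_density


def _ts(values, tr=2.0, motion=None, nuisance=None):
    return tsp.ParcelTimeseries(
        subject_id="s", values=values, tr=tr, motion=motion, nuisance=nuisance
    )


class TestFramewiseDisplacement:
    def test_constant_motion_gives_zero(self):
        motion = np.tile([1.0, -2.0, 0.5, 0.01, 0.0, -0.02], (50, 1))
        assert np.allclose(tsp.framewise_displacement(motion), 0.0)

    def test_translation_step(self):
        motion = np.zeros((20, 6))
        motion[10:, 0] = 0.2
        fd = tsp.framewise_displacement(motion)
        assert fd[10] == pytest.approx(0.2)
        assert fd[0] == 0.0
        assert np.count_nonzero(fd) == 1

    def test_rotation_arc_length_convention(self):
        motion = np.zeros((20, 6))
        motion[5:, 4] = 0.01  # radians
        fd = tsp.framewise_displacement(motion)
        assert fd[5] == pytest.approx(0.5)  # 0.01 rad x 50 mm

    def test_wrong_column_count_rejected(self):
        with pytest.raises(SchemaError):
            tsp.framewise_displacement(np.zeros((10, 5)))

    def test_nonnegative_on_random_traces(self, rng):
        motion = rng.normal(0, 0.5, (200, 6))
        assert np.all(tsp.framewise_displacement(motion) >= 0)


class TestScrub:
    def _make(self, fd_spikes, n=100):
        # build a motion trace whose FD spikes exactly at given frames
        motion = np.zeros((n, 6))
        for f, mag in fd_spikes:
            motion[f:, 0] += mag  # one step of size mag at frame f
        values = np.random.default_rng(0).standard_normal((n, 3))
        return _ts(values, motion=motion)

    def test_quiet_run_keeps_everything(self):
        ts = self._make([])
        record, keep = tsp.scrub(ts)
        assert record.censored_fraction == 0.0
        assert not record.excluded
        assert keep.all()

    def test_single_spike_censors_three_frames(self):
        ts = self._make([(10, 1.5)])
        record, keep = tsp.scrub(ts)
        censored = np.flatnonzero(record.censored_mask)
        # the step at frame 10 also moves FD at frame 10 only; neighbours 9, 11
        assert list(censored) == [9, 10, 11]
        assert record.censored_fraction == pytest.approx(0.03)

    def test_exclusion_above_30_percent(self):
        spikes = [(i, 1.5) for i in range(2, 40, 3)]
        ts = self._make(spikes)
        record, _ = tsp.scrub(ts)
        assert record.censored_fraction > 0.30
        assert record.excluded

    @given(st.lists(st.integers(min_value=1, max_value=98), max_size=12, unique=True))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mask_matches_bruteforce(self, frames):
        """Censoring equals a brute-force mask: flagged frames +/- one."""
        fd = np.zeros(100)
        for f in frames:
            fd[f] = 2.0
        expected = np.zeros(100, dtype=bool)
        for f in frames:
            expected[max(0, f - 1): f + 2] = True
        # reconstruct motion whose FD equals fd (steps accumulate)
        motion = np.zeros((100, 6))
        x = 0.0
        for t in range(1, 100):
            x += fd[t]
            motion[t, 0] = x
        record, _ = tsp.scrub(_ts(np.zeros((100, 3)) + np.arange(100)[:, None] * 0.0 + 1.0
                                  + np.random.default_rng(1).normal(size=(100, 3)),
                                  motion=motion))
        assert np.array_equal(record.censored_mask, expected)


class TestCleanTimeseries:
    def test_constant_signal_vanishes(self):
        values = np.full((60, 4), 7.0)
        out = tsp.clean_timeseries(_ts(values), bandpass=False)
        assert np.max(np.abs(out.values)) < 1e-9

    def test_nuisance_identical_to_signal_removed(self, rng):
        sig = rng.standard_normal(80)
        values = np.column_stack([sig, rng.standard_normal(80)])
        out = tsp.clean_timeseries(
            _ts(values, nuisance=sig[:, None]), bandpass=False
        )
        assert np.max(np.abs(out.values[:, 0])) < 1e-9

    def test_bandpass_reduces_white_noise_power(self):
        reduced = 0
        for seed in range(10):
            values = np.random.default_rng(seed).standard_normal((200, 3))
            out = tsp.clean_timeseries(_ts(values))
            if out.values.var() < values.var():
                reduced += 1
        assert reduced == 10

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(InvalidConfigError):
            tsp.clean_timeseries(_ts(np.zeros((60, 2)), tr=10.0), band=(0.01, 0.08))


class TestConnectivityMatrix:
    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal((10_000, 2))
        cm = tsp.connectivity_matrix(_ts(values))
        assert abs(cm.z[0, 1]) < 0.05

    def test_identical_series_clipped_finite(self):
        sig = np.random.default_rng(4).standard_normal(100)
        cm = tsp.connectivity_matrix(_ts(np.column_stack([sig, sig])))
        expected = np.arctanh(1 - 1e-6)
        assert cm.z[0, 1] == pytest.approx(expected)
        assert cm.z[0, 1] > 7

    def test_fisher_z_is_odd(self, rng):
        r = rng.uniform(-0.99, 0.99, 50)
        assert np.allclose(tsp.fisher_z(-r), -tsp.fisher_z(r))

    def test_symmetric_zero_diagonal(self, toy_timeseries):
        cleaned = tsp.clean_timeseries(toy_timeseries)
        cm = tsp.connectivity_matrix(cleaned)
        assert np.allclose(cm.z, cm.z.T)
        assert np.allclose(np.diag(cm.z), 0)

    def test_zero_variance_region_edges_zeroed(self):
        rng = np.random.default_rng(5)
        values = rng.standard_normal((100, 3))
        values[:, 1] = 2.5
        cm = tsp.connectivity_matrix(_ts(values))
        assert np.allclose(cm.z[1, :], 0)

    def test_partial_correlation_recovers_conditional_structure(self):
        # chain A -> B -> C: partial corr(A, C | B) should be near zero while
        # the full correlation is clearly positive
        rng = np.random.default_rng(6)
        a = rng.standard_normal(5000)
        b = 0.9 * a + 0.4 * rng.standard_normal(5000)
        c = 0.9 * b + 0.4 * rng.standard_normal(5000)
        ts = _ts(np.column_stack([a, b, c]))
        full = tsp.connectivity_matrix(ts, method="full")
        part = tsp.connectivity_matrix(ts, method="partial")
        assert full.z[0, 2] > 0.5
        assert abs(part.z[0, 2]) < abs(full.z[0, 2]) / 3


class TestTemplateThresholding:
    @pytest.mark.parametrize("n,density", [(5, 0.30), (10, 0.25), (20, 0.10), (8, 0.5)])
    def test_retained_edge_count_exact(self, rng, n, density):
        z = rng.normal(0.2, 0.3, (n, n))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        out = threshold_density(z, density)
        P = n * (n - 1) // 2
        assert np.count_nonzero(out[np.triu_indices(n, 1)]) <= round(density * P)
        pos = (z[np.triu_indices(n, 1)] > 0).sum()
        assert np.count_nonzero(out[np.triu_indices(n, 1)]) == min(round(density * P), pos)

    def test_five_regions_density_030_keeps_three(self, rng):
        z = np.abs(rng.normal(0.5, 0.1, (5, 5))) + 0.1
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        out = threshold_density(z, 0.30)
        assert np.count_nonzero(out[np.triu_indices(5, 1)]) == 3

    def test_density_one_keeps_positives_only(self, rng):
        z = rng.normal(0, 0.4, (6, 6))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        out = threshold_density(z, 1.0)
        expected = np.where(z > 0, z, 0.0)
        np.fill_diagonal(expected, 0)
        assert np.allclose(out, expected)

    def test_average_of_identical_matrices_is_input(self, rng):
        z = np.abs(rng.normal(0.4, 0.1, (6, 6)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        cm = tsp.ConnectivityMatrix(regions=tuple("abcdef"), z=z)
        avg = tsp.normative_template([cm, cm], density=1.0)
        assert np.allclose(avg.z, threshold_density(z, 1.0))

    def test_bad_density_rejected(self):
        cm = tsp.ConnectivityMatrix(regions=("a", "b"), z=np.zeros((2, 2)))
        with pytest.raises(InvalidConfigError):
            tsp.normative_template([cm], density=0.0)


def _bruteforce_shortest(w):
    """Exhaustive simple-path enumeration on small graphs; inf if unreachable."""
    n = w.shape[0]
    best = np.full((n, n), np.inf)
    np.fill_diagonal(best, 0.0)

    def explore(path, length):
        i = path[-1]
        if length < best[path[0], i]:
            best[path[0], i] = length
        for j in range(n):
            if w[i, j] > 0 and j not in path:
                explore(path + [j], length + 1.0 / w[i, j])

    for s in range(n):
        explore([s], 0.0)
    return best


class TestDistanceConversion:
    def test_chain_distance(self):
        z = np.zeros((3, 3))
        z[0, 1] = z[1, 0] = 1.0
        z[1, 2] = z[2, 1] = 1.0
        d = tsp.to_distance(tsp.ConnectivityMatrix(regions=("A", "B", "C"), z=z))
        assert d.d[0, 2] == pytest.approx(2.0)

    @pytest.mark.parametrize("w", [0.5, 1.0, 2.0])
    def test_complete_graph_uniform_weight(self, w):
        n = 5
        z = np.full((n, n), w)
        np.fill_diagonal(z, 0)
        d = tsp.to_distance(tsp.ConnectivityMatrix(regions=tuple("abcde"), z=z))
        off = d.d[~np.eye(n, dtype=bool)]
        assert np.allclose(off, 1.0 / w)

    def test_zero_self_distance(self, small_cohort):
        d = tsp.to_distance(small_cohort.template)
        assert np.allclose(np.diag(d.d), 0)

    def test_disconnected_graph_reports_components(self):
        z = np.zeros((4, 4))
        z[0, 1] = z[1, 0] = 1.0
        z[2, 3] = z[3, 2] = 1.0
        with pytest.raises(DisconnectedTemplateError) as err:
            tsp.to_distance(tsp.ConnectivityMatrix(regions=tuple("abcd"), z=z))
        assert len(err.value.components) == 2

    def test_matches_bruteforce_on_random_graphs(self, rng):
        """Dijkstra distances equal exhaustive path enumeration, n <= 7."""
        for _ in range(100):
            n = int(rng.integers(3, 8))
            z = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.7)
            z = np.triu(z, 1)
            z = z + z.T
            cm = tsp.ConnectivityMatrix(regions=tuple(str(i) for i in range(n)), z=z)
            brute = _bruteforce_shortest(z)
            if np.isinf(brute).any():
                with pytest.raises(DisconnectedTemplateError):
                    tsp.to_distance(cm)
                continue
            d = tsp.to_distance(cm)
            assert np.allclose(d.d, brute, atol=1e-10)

    def test_triangle_inequality(self, small_cohort):
        d = tsp.to_distance(small_cohort.template).d
        n = d.shape[0]
        idx = np.random.default_rng(0).integers(0, n, size=(300, 3))
        for i, j, k in idx:
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_euclidean_option(self, rng):
        coords = rng.normal(0, 10, (4, 3))
        z = np.abs(rng.normal(0.5, 0.1, (4, 4)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        d = tsp.to_distance(
            tsp.ConnectivityMatrix(regions=tuple("abcd"), z=z),
            method="euclidean", coordinates=coords,
        )
        expected = np.linalg.norm(coords[0] - coords[1])
        assert d.d[0, 1] == pytest.approx(expected)
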