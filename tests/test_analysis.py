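"""Stress-intensity correlation, coupling length, time-series analytics."""

import numpy as np
import pandas as pd
import pytest

from jforce import analysis
from jforce.analysis import (
    classify_edges_min_k,
    coupling_length_scale,
    intensity_stress_correlation,
    junction_autocorrelation_length,
    resample_and_normalize,
    sample_intensity_along_interface,
    transmission_analysis,
    vector_cross_correlation,
)


class TestIntensitySampling:
    def test_constant_image(self):
        img = np.full((80, 80), 7.5)
        pts = np.array([[20.0, 20.0], [40.0, 55.0], [70.0, 10.0]])
        vals, keep = sample_intensity_along_interface(img, pts)
        assert keep.all()
        np.testing.assert_allclose(vals, 7.5)

    def test_delta_spike_divided_by_disk_area(self):
        """A unit spike smoothed with the radius-10 circular mean filter
        reads back as 1/317 (317 pixels in the disk)."""
        img = np.zeros((101, 101))
        img[50, 50] = 1.0
        vals, _ = sample_intensity_along_interface(img, np.array([[50.0, 50.0]]))
        disk_px = sum(
            1
            for x in range(-10, 11)
            for y in range(-10, 11)
            if x * x + y * y <= 100
        )
        assert disk_px == 317
        assert vals[0] == pytest.approx(1 / 317)

    def test_outside_samples_flagged(self):
        img = np.zeros((50, 50))
        pts = np.array([[25.0, 25.0], [200.0, 25.0]])
        with pytest.warns(UserWarning):
            vals, keep = sample_intensity_along_interface(img, pts)
        assert keep.tolist() == [True, False]
        assert np.isnan(vals[1])


class TestCorrelation:
    def test_linear_coupling_unit_correlation(self, rng):
        s = rng.uniform(0, 5, 200)
        r = intensity_stress_correlation(3.0 * s + 2.0, s)
        assert r.coefficient == pytest.approx(1.0)
        assert r.n_samples == 200

    def test_independent_null(self):
        rng = np.random.default_rng(99)
        r = intensity_stress_correlation(
            rng.normal(size=1000), rng.uniform(0, 1, 1000)
        )
        assert abs(r.coefficient) < 0.08

    def test_zero_variance_undefined(self):
        with pytest.warns(UserWarning):
            r = intensity_stress_correlation(np.ones(10), np.arange(10.0))
        assert np.isnan(r.coefficient)


class TestCouplingLength:
    @staticmethod
    def junctions(rng, n=30, length=40.0, spacing=1.6, ell=10.0, noise=0.2):
        from jforce.scenes import smooth_arc_noise

        out = []
        npts = int(length / spacing)
        for _ in range(n):
            arc = np.arange(npts) * spacing
            stress = 1.0 + 0.5 * smooth_arc_noise(npts, spacing, ell, rng)
            intensity = stress + noise * rng.standard_normal(npts)
            out.append({"arc_um": arc, "intensity": intensity, "stress_mag": stress})
        return out

    def test_tiny_segments_keep_correlation(self, rng):
        js = self.junctions(rng)
        curves = coupling_length_scale(js, np.array([1.6]), rng)
        assert curves.ratio.iloc[0] > 0.8

    def test_oversized_segments_skip_junctions(self, rng):
        js = self.junctions(rng, length=20.0)
        curves = coupling_length_scale(js, np.array([50.0]), rng)
        assert curves.n_junctions.iloc[0] == 0

    def test_randomization_preserves_multiset(self, rng):
        js = self.junctions(rng, n=1)
        I = np.asarray(js[0]["intensity"])
        # shuffle within segments exactly as the procedure does
        from jforce.analysis import _segment_bounds

        arc = np.asarray(js[0]["arc_um"])
        groups = _segment_bounds(arc, 8.0)
        shuffled = I.copy()
        for sel in groups:
            shuffled[sel] = shuffled[rng.permutation(sel)]
        # within each segment the multiset of values is preserved
        for sel in groups:
            assert sorted(shuffled[sel].tolist()) == sorted(I[sel].tolist())

    def test_recovers_generator_length(self):
        from jforce.evaluation import coupling_recovery

        res = coupling_recovery(seed=3, n_scenes=12)
        assert 5.0 <= res["coupling_length_um"] <= 20.0

    def test_monotone_in_generator_length(self, rng):
        """Doubling the generator correlation length does not shrink the
        recovered coupling length (median over junction sets)."""
        grid = np.array([2, 4, 6, 8, 10, 12, 16, 20], dtype=float)
        est = {}
        for ell in (5.0, 10.0):
            js = self.junctions(np.random.default_rng(5), n=40, ell=ell)
            curves = coupling_length_scale(js, grid, np.random.default_rng(6))
            est[ell] = analysis.estimate_coupling_length(curves)
        assert est[10.0] >= est[5.0]


class TestAutocorrelation:
    def test_lag_zero_is_one(self, rng):
        js = TestCouplingLength.junctions(rng, n=5)
        _, curve = junction_autocorrelation_length(js)
        assert curve.median_autocorr.iloc[0] == 1.0

    def test_white_noise_decorrelates_immediately(self, rng):
        js = []
        for _ in range(10):
            npts = 40
            arc = np.arange(npts) * 1.6
            I = rng.standard_normal(npts)
            js.append({"arc_um": arc, "intensity": I, "stress_mag": I})
        length, curve = junction_autocorrelation_length(js)
        assert length <= 1.6

    def test_recovers_generator_length(self):
        from jforce.evaluation import coupling_recovery

        res = coupling_recovery(seed=4, n_scenes=6)
        assert abs(res["autocorrelation_length_um"] - 10.0) <= 3.0


class TestMinK:
    @staticmethod
    def graph_of(edges, forces=None):
        from tests.test_mechanics import graph_with_residuals

        n = max(max(e) for e in edges) + 1
        residuals = np.zeros((n, 2))
        residuals[0] = (1.0, 0.0)
        residuals[-1] = (-1.0, 0.0)
        g = graph_with_residuals(edges, residuals)
        for k, (a, b) in enumerate(edges):
            g.graph.edges[a, b]["f_fem"] = np.array([1.0, 0.0])
            g.graph.edges[a, b]["length_um"] = 10.0
        return g

    def test_pair_min_k_one(self):
        df = classify_edges_min_k(self.graph_of([(0, 1)]))
        assert df.min_k.tolist() == [1]

    def test_star_min_k_one_everywhere(self):
        df = classify_edges_min_k(self.graph_of([(0, 1), (0, 2), (0, 3)]))
        assert df.min_k.tolist() == [1, 1, 1]

    def test_square_loop_min_k_two(self):
        df = classify_edges_min_k(self.graph_of([(0, 1), (1, 2), (2, 3), (3, 0)]))
        assert df.min_k.tolist() == [2, 2, 2, 2]

    def test_filter(self):
        df = classify_edges_min_k(
            self.graph_of([(0, 1), (1, 2), (2, 0), (2, 3)]), min_k_filter=1
        )
        assert len(df) == 1


class TestTimeSeries:
    def test_ramp_bin_means(self):
        t = np.arange(0, 960, 60.0)
        v = np.arange(len(t), dtype=float)
        rt, rv = resample_and_normalize(t, v, normalize=False)
        # four 240-s bins of four 60-s samples each
        np.testing.assert_allclose(rv[:, 0], [1.5, 5.5, 9.5, 13.5])

    def test_unit_variance_after_normalization(self, rng):
        t = np.arange(0, 4800, 60.0)
        v = rng.normal(0, 3, (len(t), 2))
        _, rv = resample_and_normalize(t, v)
        np.testing.assert_allclose(rv.std(axis=0), 1.0, atol=1e-12)

    def test_constant_series_warns(self):
        t = np.arange(0, 960, 60.0)
        with pytest.warns(UserWarning, match="constant"):
            resample_and_normalize(t, np.ones(len(t)))

    def test_slow_series_passes_through(self):
        t = np.arange(0, 3600, 600.0)
        with pytest.warns(UserWarning, match="interval"):
            rt, rv = resample_and_normalize(t, np.arange(len(t), dtype=float),
                                            normalize=False)
        np.testing.assert_allclose(rv[:, 0], np.arange(len(t)))


class TestVectorCrossCorrelation:
    def test_perfect_anticorrelation(self, rng):
        f1 = rng.normal(0, 1, (100, 2))
        df = vector_cross_correlation(f1, -f1, [0])
        assert df.c.iloc[0] == pytest.approx(-1.0)

    def test_independent_null(self):
        rng = np.random.default_rng(11)
        f1 = rng.normal(0, 1, (200, 2))
        f2 = rng.normal(0, 1, (200, 2))
        assert abs(vector_cross_correlation(f1, f2, [0]).c.iloc[0]) < 0.15

    def test_constructed_lag_detected(self, rng):
        f1 = np.zeros((120, 2))
        base = rng.normal(0, 1, (121, 2))
        from scipy.ndimage import uniform_filter1d

        base = uniform_filter1d(base, 5, axis=0)
        f1 = base[1:]
        f2 = -base[:-1]  # f2(t) = -f1(t - 1): f2 trails f1 by one frame
        lags = np.arange(-3, 4)
        df = vector_cross_correlation(f1, f2, lags)
        best = df.loc[df.c.idxmin()]
        # c(dt) = corr(f1(t + dt), f2(t)) is most negative where
        # f1(t + dt) aligns with f1(t - 1), i.e. at dt = -1
        assert best["dt"] == -1
        assert best.c == pytest.approx(-1.0, abs=1e-9)

    def test_short_overlap_is_nan(self, rng):
        f1 = rng.normal(0, 1, (8, 2))
        df = vector_cross_correlation(f1, f1, [6])
        assert np.isnan(df.c.iloc[0])

    def test_off_diagonals_near_zero_for_isotropic_series(self):
        from jforce.analysis import cross_correlation_matrix

        rng = np.random.default_rng(21)
        n = 4000
        f1 = rng.normal(0, 1, (n, 2))
        f2 = 0.5 * f1 + 0.5 * rng.normal(0, 1, (n, 2))
        M = cross_correlation_matrix(f1, f2)
        assert abs(M[0, 1]) < 2 / np.sqrt(n) * 2
        assert abs(M[1, 0]) < 2 / np.sqrt(n) * 2
        assert M[0, 0] > 0.3 and M[1, 1] > 0.3


class TestTransmission:
    def test_passive_and_anchored_signatures(self):
        from jforce.evaluation import transmission_signatures

        res = transmission_signatures(seed=0)
        assert res["passive_c_junction_junction"] == pytest.approx(-1.0, abs=0.05)
        assert abs(res["passive_c_junction_traction"]) < 0.1
        assert res["anchored_c_junction_traction"] == pytest.approx(-1.0, abs=0.05)
        assert abs(res["anchored_c_junction_junction"]) < 0.1

    def test_per_frame_force_balance_closes(self, rng):
        f1 = rng.normal(0, 1, (50, 2))
        f2 = rng.normal(0, 1, (50, 2))
        res = -(f1 + f2)
        np.testing.assert_allclose(f1 + f2 + res, 0.0, atol=1e-12)
        df = transmission_analysis({0: f1, 1: f2}, res)
        assert set(df.junction_id) == {0, 1}

    def test_single_junction_cell_rejected(self, rng):
        with pytest.raises(ValueError):
            transmission_analysis({0: rng.normal(size=(10, 2))}, rng.normal(size=(10, 2)))
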