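import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from tlstrack.analysis import (
    CylindricalMap,
    PrincipalAxis,
    cluster_timeseries,
    cylindrical_project,
    max_displacement_map,
    normalize_rz,
    percentile_summary,
    plot_map,
    plot_timeseries,
)
from tlstrack.tracking import ClusterTrackSet, DisplacementSeries, displacements

from _oracles import brute_cell_max

Z_AXIS = PrincipalAxis([0, 0, 0], [0, 0, 1])


def make_tracks(rng, K=30, T=5, spread=5.0):
    """Random track set: clusters drift by small random walks."""
    start = rng.uniform(0, spread, (K, 3))
    start[:, 2] = rng.uniform(0.5, 10.0, K)
    steps = rng.normal(0, 0.01, (K, T, 3))
    steps[:, 0, :] = 0
    centers = start[:, None, :] + np.cumsum(steps, axis=1)
    counts = np.full((K, T), 200)
    return ClusterTrackSet(centers, counts, np.arange(T) * 1200.0, np.arange(T))


class TestCylindricalProject:
    def test_on_axis_point_has_zero_radius(self):
        rpz = cylindrical_project(np.array([[0.0, 0.0, 7.0]]), Z_AXIS)
        assert rpz[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert rpz[0, 2] == pytest.approx(7.0)

    def test_vertical_axis_through_origin(self):
        rpz = cylindrical_project(np.array([[1.0, 0.0, 5.0]]), Z_AXIS)
        np.testing.assert_allclose(rpz[0], [1.0, 0.0, 5.0], atol=1e-12)

    def test_pythagoras(self, rng):
        centers = rng.uniform(-5, 5, (100, 3))
        axis = PrincipalAxis(rng.uniform(0, 1, 3), rng.normal(size=3))
        rpz = cylindrical_project(centers, axis)
        lhs = rpz[:, 0] ** 2 + rpz[:, 2] ** 2
        rhs = ((centers - axis.origin) ** 2).sum(axis=1)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            PrincipalAxis([0, 0, 0], [0, 0, 0])


class TestNormalizeRZ:
    def test_formula_anchors(self):
        r, z = normalize_rz(5.0, 10.0, 10.0)
        assert z == 100.0 and r == 50.0

    def test_scale_invariance(self, rng):
        r = rng.uniform(0, 5, 20)
        z = rng.uniform(0, 10, 20)
        z_max = float(z.max())
        s = 3.7
        a = normalize_rz(r, z, z_max)
        b = normalize_rz(r * s, z * s, z_max * s)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_nonpositive_zmax_rejected(self):
        with pytest.raises(ValueError):
            normalize_rz(1.0, 1.0, 0.0)


class TestMaxDisplacementMap:
    def test_one_cluster_per_cell(self, rng):
        tracks = make_tracks(rng, K=10, T=3)
        disp = displacements(tracks, "initial")
        cmap = max_displacement_map(tracks, disp, Z_AXIS, dai=2, cell=2.0)
        df = cmap.to_frame()
        # every populated cell's value must be one of the cluster displacements
        assert set(np.round(df["max_displacement_m"], 12)) <= set(np.round(disp.values[:, 2], 12))

    def test_two_clusters_in_one_cell_take_max(self):
        centers = np.zeros((2, 2, 3))
        centers[:, 0, :] = [[0.90, 0.0, 5.0], [0.95, 0.0, 5.0]]  # same cell
        centers[0, 1, :] = centers[0, 0, :] + [0.02, 0, 0]
        centers[1, 1, :] = centers[1, 0, :] + [0.08, 0, 0]
        tracks = ClusterTrackSet(centers, np.full((2, 2), 100), [0.0, 1200.0], [0, 1])
        disp = displacements(tracks, "initial")
        cmap = max_displacement_map(tracks, disp, Z_AXIS, dai=1, cell=2.0)
        assert np.nanmax(cmap.values) == pytest.approx(0.08)
        assert np.isfinite(cmap.values).sum() == 1

    def test_matches_brute_force_recomputation(self, rng):
        tracks = make_tracks(rng, K=60, T=4)
        disp = displacements(tracks, "initial")
        cell = 2.0
        cmap = max_displacement_map(tracks, disp, Z_AXIS, dai=3, cell=cell)
        rpz = cylindrical_project(tracks.centers[:, 0, :], Z_AXIS)
        r_n, z_n = normalize_rz(rpz[:, 0], rpz[:, 2], cmap.z_max)
        expected = brute_cell_max(r_n, z_n, disp.values[:, 3], cell, cmap.values.shape[1], cmap.values.shape[0])
        np.testing.assert_array_equal(np.isfinite(cmap.values), np.isfinite(expected))
        np.testing.assert_allclose(cmap.values[np.isfinite(expected)], expected[np.isfinite(expected)])

    def test_global_max_equals_displacement_max(self, rng):
        tracks = make_tracks(rng, K=40, T=4)
        disp = displacements(tracks, "initial")
        cmap = max_displacement_map(tracks, disp, Z_AXIS, dai=3)
        assert np.nanmax(cmap.values) == pytest.approx(np.nanmax(disp.values[:, 3]))

    def test_running_max_dominates_at_dai(self, rng):
        tracks = make_tracks(rng, K=40, T=5)
        disp = displacements(tracks, "initial")
        at = max_displacement_map(tracks, disp, Z_AXIS, dai=4)
        run = max_displacement_map(tracks, disp, Z_AXIS, dai=4, running_max=True)
        mask = np.isfinite(at.values)
        assert (run.values[mask] >= at.values[mask] - 1e-15).all()

    def test_unknown_dai_rejected(self, rng):
        tracks = make_tracks(rng, K=5, T=3)
        disp = displacements(tracks, "initial")
        with pytest.raises(ValueError):
            max_displacement_map(tracks, disp, Z_AXIS, dai=99)

    def test_previous_reference_rejected(self, rng):
        tracks = make_tracks(rng, K=5, T=3)
        disp = displacements(tracks, "previous")
        with pytest.raises(ValueError):
            max_displacement_map(tracks, disp, Z_AXIS, dai=1)


class TestPercentileSummary:
    def make_disp(self, values):
        values = np.asarray(values, dtype=float)
        return DisplacementSeries(values, "initial", np.arange(values.shape[1]) * 1200.0, np.arange(values.shape[1]))

    def test_constant_series(self):
        disp = self.make_disp(np.full((7, 4), 0.05))
        for q in (1, 50, 99):
            assert percentile_summary(disp, q) == pytest.approx(0.05)

    def test_linear_interpolation_convention(self):
        disp = self.make_disp(np.arange(1.0, 101.0)[:, None])
        assert percentile_summary(disp, 99) == pytest.approx(99.01)

    def test_q100_is_maximum(self, rng):
        disp = self.make_disp(rng.uniform(0, 1, (30, 6)))
        assert percentile_summary(disp, 100) == pytest.approx(np.max(disp.values))

    def test_per_dai_scope_shape_and_values(self, rng):
        values = rng.uniform(0, 1, (20, 5))
        disp = self.make_disp(values)
        out = percentile_summary(disp, [50, 99], scope="per-dai")
        assert out.shape == (2, 5)
        np.testing.assert_allclose(out[0], np.percentile(values, 50, axis=0))

    def test_missing_excluded_and_all_missing_rejected(self):
        values = np.full((3, 2), np.nan)
        values[0] = [0.1, 0.2]
        disp = self.make_disp(values)
        assert percentile_summary(disp, 50) == pytest.approx(0.2)  # only cluster 0 contributes
        with pytest.raises(ValueError):
            percentile_summary(self.make_disp(np.full((2, 2), np.nan)), 50)


class TestClusterTimeseries:
    def test_initial_reference_rows_start_at_zero(self, rng):
        tracks = make_tracks(rng, K=8, T=4)
        disp = displacements(tracks, "initial")
        df = cluster_timeseries(tracks, disp, [1, 2, 3])
        assert (df.loc[df["dai"] == 0, "displacement_m"] == 0).all()

    def test_row_count_and_lookup_identity(self, rng):
        tracks = make_tracks(rng, K=10, T=6)
        disp = displacements(tracks, "initial")
        ids = [1, 2, 3, 4, 5, 6, 7]
        df = cluster_timeseries(tracks, disp, ids)
        assert len(df) == len(ids) * 6
        for _, row in df.sample(10, random_state=0).iterrows():
            k, d = int(row["cluster_id"]), int(row["dai"])
            assert row["displacement_m"] == pytest.approx(disp.values[k - 1, d])

    def test_unknown_id_rejected(self, rng):
        tracks = make_tracks(rng, K=4, T=3)
        disp = displacements(tracks, "initial")
        with pytest.raises(KeyError):
            cluster_timeseries(tracks, disp, [99])

    def test_annotations_attached(self, rng):
        tracks = make_tracks(rng, K=4, T=3)
        disp = displacements(tracks, "initial")
        df = cluster_timeseries(tracks, disp, [1], {"sunset": 2280.0, "sunrise": 33120.0})
        assert df.attrs["annotations"]["sunrise"] == 33120.0


class TestPlots:
    def test_plot_functions_return_axes(self, rng):
        tracks = make_tracks(rng, K=12, T=4)
        disp = displacements(tracks, "initial")
        cmap = max_displacement_map(tracks, disp, Z_AXIS, dai=3)
        ax = plot_map(cmap)
        assert ax.figure is not None
        df = cluster_timeseries(tracks, disp, [1, 2], {"sunset": 1000.0})
        ax = plot_timeseries(df)
        assert ax.get_legend() is not None
        import matplotlib.pyplot as plt

        plt.close("all")
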