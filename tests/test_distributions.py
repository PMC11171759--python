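import numpy as np
import pytest

from vesidist import (
    CellGeometry,
    ImageStack,
    QCError,
    cell_geometry,
    distance_distribution,
    downsample,
    intensity_distribution,
    load_distribution,
    save_distribution,
    shell_phantom,
    zproject_mean,
)
from vesidist.geometry import center_of_mass, radius_of_gyration


def _geometry_from_points(coords, weights, cell_id="c", group="g"):
    coords = np.asarray(coords, dtype=float)
    weights = np.asarray(weights, dtype=float)
    c = center_of_mass(coords, weights)
    rg = radius_of_gyration(coords, weights, c)
    return CellGeometry(
        coords=coords, weights=weights, center=c, rg=rg, theta=0.0,
        cell_id=cell_id, group=group,
    )


class TestDistanceDistribution:
    def test_two_point_unscaled_binning(self):
        """Equal weights at distances 1 and 3 land in the right bins."""
        g = _geometry_from_points(
            [[0, 0, 1], [0, 0, -1], [0, 0, 3], [0, 0, -3]],
            [0.25, 0.25, 0.25, 0.25],
        )
        dist = distance_distribution(g, bins=4, scaled=False, grid_max=3.0)
        mass = dist.density * dist.bin_widths
        np.testing.assert_allclose(mass, [0.0, 0.5, 0.0, 0.5], atol=1e-12)

    def test_density_normalization(self, random_stack):
        g = cell_geometry(random_stack, 100.0)
        for scaled in (True, False):
            dist = distance_distribution(g, scaled=scaled)
            assert np.sum(dist.density * dist.bin_widths) == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_binning(self, rng):
        """Half-open bins [e, e') with a closed last bin, weighted mass."""
        coords, w = rng.normal(size=(200, 3)) * 3, rng.random(200) + 0.1
        w = w / w.sum()
        g = _geometry_from_points(coords, w)
        dist = distance_distribution(g, bins=16, scaled=True)
        edges = dist.bin_edges
        expect = np.zeros(16)
        s = g.distances / g.rg
        for si, wi in zip(s, w):
            si = min(si, edges[-1])
            for b in range(16):
                closed = b == 15
                if edges[b] <= si < edges[b + 1] or (closed and si == edges[-1]):
                    expect[b] += wi
                    break
        np.testing.assert_allclose(dist.density * dist.bin_widths, expect, atol=1e-12)

    def test_thin_shell_concentrates_at_one(self):
        dist = distance_distribution(cell_geometry(shell_phantom(radius=20), 500.0))
        mass = dist.density * dist.bin_widths
        centers = dist.bin_centers
        in_band = mass[(centers > 0.95) & (centers < 1.05)].sum()
        assert in_band >= 0.99

    def test_magnification_invariance_of_scaled_histogram(self, rng):
        """Scaling all coordinates by k changes rg by k, not the histogram."""
        coords, w = rng.normal(size=(300, 3)) * 5, rng.random(300) + 0.1
        w = w / w.sum()
        d1 = distance_distribution(_geometry_from_points(coords, w))
        d2 = distance_distribution(_geometry_from_points(coords * 3.7, w))
        assert d2.rg == pytest.approx(3.7 * d1.rg, rel=1e-12)
        np.testing.assert_allclose(d2.density, d1.density, atol=1e-9)

    def test_overflow_mass_folded_into_last_bin(self):
        g = _geometry_from_points(
            [[0, 0, 1], [0, 0, -1], [0, 0, 100], [0, 0, -100]],
            [0.4, 0.4, 0.1, 0.1],
        )
        dist = distance_distribution(g, bins=10, scaled=False, grid_max=2.5)
        assert dist.overflow_fraction == pytest.approx(0.2, abs=1e-12)
        assert (dist.density * dist.bin_widths)[-1] == pytest.approx(0.2, abs=1e-12)

    def test_scaled_with_zero_rg_rejected(self):
        g = _geometry_from_points([[1, 1, 1]], [1.0])
        with pytest.raises(QCError):
            distance_distribution(g, scaled=True)

    def test_round_trip_through_csv(self, tmp_path, random_stack):
        dist = distance_distribution(cell_geometry(random_stack, 100.0))
        save_distribution(dist, tmp_path / "d")
        back = load_distribution(tmp_path / "d")
        np.testing.assert_array_equal(back.bin_edges, dist.bin_edges)
        np.testing.assert_array_equal(back.density, dist.density)
        assert back.rg == dist.rg and back.scaled and back.cell_id == dist.cell_id


class TestDownsample:
    def test_constant_stack_quarter_area(self):
        s = downsample(ImageStack(data=np.full((3, 16, 16), 7.0)), 2)
        assert s.shape == (3, 8, 8)
        assert np.all(s.data == 7.0)

    def test_block_mean_of_single_tile(self):
        data = np.array([[[1.0, 3.0], [5.0, 7.0]]])
        tile = np.pad(data, ((0, 0), (0, 14), (0, 14)))  # meet min size
        out = downsample(ImageStack(data=tile), 2)
        assert out.data[0, 0, 0] == pytest.approx(4.0)

    def test_spacing_scaled_in_plane_only(self):
        s = ImageStack(data=np.zeros((2, 16, 16)), spacing=(0.5, 0.2, 0.2))
        assert downsample(s, 2).spacing == pytest.approx((0.5, 0.4, 0.4))

    def test_non_divisible_crops_with_warning(self):
        s = ImageStack(data=np.zeros((2, 17, 18)))
        with pytest.warns(UserWarning, match="trailing"):
            out = downsample(s, 2)
        assert out.shape == (2, 8, 9)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            downsample(ImageStack(data=np.zeros((2, 16, 16))), 0)


class TestZProject:
    def test_all_subthreshold_gives_zeros(self):
        img = zproject_mean(ImageStack(data=np.full((3, 8, 8), 5.0)), 10.0)
        assert np.all(img == 0.0)

    def test_single_layer_is_clipped_excess(self, rng):
        data = rng.integers(0, 20, size=(1, 8, 8)).astype(float)
        img = zproject_mean(ImageStack(data=data), 10.0)
        np.testing.assert_allclose(img, np.clip(data[0] - 10.0, 0, None))

    def test_matches_loop_oracle(self, random_stack):
        theta = 100.0
        img = zproject_mean(random_stack, theta)
        nz = random_stack.shape[0]
        for j in range(0, 16, 5):
            for i in range(0, 16, 5):
                expected = np.mean(
                    [max(float(random_stack.data[k, j, i]) - theta, 0.0) for k in range(nz)]
                )
                assert img[j, i] == pytest.approx(expected, rel=1e-12)


class TestIntensityDistribution:
    def test_isolated_pixels_are_individual_events(self):
        data = np.zeros((3, 8, 8))
        data[0, 1, 1], data[1, 4, 4], data[2, 6, 6] = 15.0, 18.0, 20.0
        h = intensity_distribution(ImageStack(data=data), 10.0, per_event=True)
        assert h.n_events == 3
        np.testing.assert_allclose(sorted(h.values), [5.0, 8.0, 10.0])

    def test_diagonal_neighbors_merge_under_26_connectivity(self):
        data = np.zeros((2, 8, 8))
        data[0, 1, 1] = 14.0  # excess 4
        data[1, 2, 2] = 16.0  # excess 6; 26-connected diagonal neighbour
        h = intensity_distribution(ImageStack(data=data), 10.0, per_event=True)
        assert h.n_events == 1
        assert h.values[0] == pytest.approx(10.0)

    def test_per_pixel_mode_uses_raw_intensities(self, random_stack):
        h = intensity_distribution(random_stack, 100.0, per_event=False)
        vals = random_stack.data[random_stack.data > 100]
        assert h.n_events == vals.size
        np.testing.assert_allclose(np.sort(h.values), np.sort(vals.astype(float)))

    def test_no_signal_is_qc_failure(self):
        with pytest.raises(QCError):
            intensity_distribution(ImageStack(data=np.zeros((2, 8, 8))), 10.0)
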