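"""Speckle tracking, sub-sample interpolation, masks and compounding."""

import inspect

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aortaus.geometry import SectorGrid
from aortaus.track import (
    AngularMask,
    DisplacementField,
    angular_mask,
    block_match,
    compound_displacements,
    compute_theta,
    median_filter_field,
    parabolic_subsample,
    radial_project,
)


def speckle_grid(n_dep=400, n_ang=40, seed=0, radius=49.57):
    """Synthetic RF speckle on a sector grid: band-limited noise with an
    axial carrier, mimicking beamformed analytic RF (real part used)."""
    rng = np.random.default_rng(seed)
    dz = 0.052  # mm, ~lambda/8
    grid = SectorGrid(
        beam_angles=np.arange(n_ang) * 0.294 - n_ang * 0.294 / 2,
        sample_depths=30.0 + dz * np.arange(n_dep),
        radius_of_curvature=radius,
    )
    from scipy.ndimage import gaussian_filter

    amp = gaussian_filter(rng.normal(size=(n_dep, n_ang)), (4.0, 1.0))
    phase = 2 * np.pi * np.arange(n_dep)[:, None] / 16.0  # carrier, lambda = 16 samples
    rf = amp * np.cos(phase) + gaussian_filter(rng.normal(size=(n_dep, n_ang)), (4.0, 1.0)) * np.sin(phase)
    return grid, rf


class TestParabolicSubsample:
    def test_symmetric_peak(self):
        assert parabolic_subsample(0.5, 1.0, 0.5) == 0.0

    def test_formula_by_hand(self):
        assert np.isclose(parabolic_subsample(0.4, 1.0, 0.8), 0.25)

    def test_exact_parabola_vertex(self, rng):
        for _ in range(20):
            v = rng.uniform(-0.49, 0.49)
            a = -rng.uniform(0.5, 3.0)
            f = lambda x: a * (x - v) ** 2 + 1.0
            assert abs(parabolic_subsample(f(-1), f(0), f(1)) - v) < 1e-12

    def test_requires_centered_argmax(self):
        with pytest.raises(ValueError):
            parabolic_subsample(1.2, 1.0, 0.3)

    def test_zero_curvature(self):
        assert parabolic_subsample(1.0, 1.0, 1.0) == 0.0


class TestBlockMatch:
    def test_self_match_zero_displacement(self):
        grid, rf = speckle_grid()
        f = block_match(rf, rf, grid, (0.8, 2.4), (1.6, 4.0), mode="rf")
        inner = f.valid
        assert np.allclose(f.u_ax[inner], 0.0)
        assert np.allclose(f.u_lat[inner], 0.0)
        assert np.all(f.quality[inner] > 0.999)

    def test_integer_axial_shift_recovered(self):
        grid, rf = speckle_grid(seed=1)
        mov = np.roll(rf, 3, axis=0)
        f = block_match(rf, mov, grid, (0.8, 2.4), (1.6, 4.0), mode="rf")
        ok = f.valid.copy()
        ok[:40] = ok[-40:] = False  # roll wrap-around region
        assert ok.any()
        assert np.allclose(f.u_ax[ok], 3 * grid.axial_spacing, atol=1e-6)

    def test_subsample_axial_shift(self):
        # 0.3-sample shift applied by resampling the band-limited RF
        grid, rf = speckle_grid(n_dep=600, seed=2)
        shift = 0.3
        idx = np.arange(rf.shape[0])
        mov = np.stack(
            [np.interp(idx - shift, idx, rf[:, j]) for j in range(rf.shape[1])],
            axis=1,
        )
        f = block_match(rf, mov, grid, (0.8, 2.4), (1.6, 4.0), mode="rf")
        ok = f.valid.copy()
        ok[:40] = ok[-40:] = False
        err = np.abs(f.u_ax[ok] / grid.axial_spacing - shift)
        assert np.quantile(err, 0.95) < 0.1

    def test_flat_kernel_zero_quality(self):
        grid, rf = speckle_grid(n_dep=120, n_ang=24)
        flat = np.zeros_like(rf)
        f = block_match(flat, flat, grid, (0.8, 2.4), (1.6, 4.0), mode="rf")
        assert np.all(f.quality[f.valid] == 0.0)
        assert np.all(f.u_ax[f.valid] == 0.0)

    def test_edge_nodes_invalid(self):
        grid, rf = speckle_grid(n_dep=120, n_ang=24)
        f = block_match(rf, rf, grid, (0.8, 2.4), (1.6, 4.0), mode="rf")
        assert not f.valid[0, 0]
        assert not f.valid[-1, -1]


class TestMedianFilter:
    def make_field(self, u):
        grid, _ = speckle_grid(n_dep=u.shape[0], n_ang=u.shape[1])
        return DisplacementField(
            u_ax=u.astype(float), u_lat=u.astype(float) * 0.5,
            quality=np.ones_like(u, float), valid=np.ones_like(u, bool),
            grid=grid, pairing=(1, 1),
        )

    def test_constant_field_unchanged(self):
        f = self.make_field(np.full((40, 30), 2.5))
        out = median_filter_field(f, size=(11, 11))
        assert np.allclose(out.u_ax, 2.5)

    def test_outlier_removed(self):
        u = np.full((40, 30), 1.0)
        u[20, 15] = 50.0
        out = median_filter_field(self.make_field(u), size=(11, 11))
        assert np.allclose(out.u_ax, 1.0)

    def test_matches_brute_force_sliding_median(self, rng):
        u = rng.normal(size=(20, 16))
        out = median_filter_field(self.make_field(u), size=(5, 3)).u_ax
        # edge-including reflection, matching the filter's boundary rule
        padded = np.pad(u, ((2, 2), (1, 1)), mode="symmetric")
        brute = np.empty_like(u)
        for i in range(20):
            for j in range(16):
                brute[i, j] = np.median(padded[i : i + 5, j : j + 3])
        assert np.array_equal(out, brute)


class TestThetaAndProjection:
    def test_collinear_node_theta_zero(self):
        center = np.array([0.0, 40.0])
        th = compute_theta(np.array([[0.0, 45.0]]), center, np.array([[0.0, 1.0]]))
        assert np.isclose(th[0], 0.0)

    def test_lateral_node_in_cutout(self):
        center = np.array([0.0, 40.0])
        th = compute_theta(np.array([[10.0, 40.0]]), center, np.array([[0.0, 1.0]]))
        assert np.isclose(th[0], 90.0)
        m = angular_mask(th)
        assert m.M[0] == 0.0

    def test_matches_arccos_dot_oracle(self, rng):
        center = rng.normal(size=2)
        pts = center + rng.normal(scale=10, size=(50, 2))
        b = rng.normal(size=(50, 2))
        b /= np.linalg.norm(b, axis=1, keepdims=True)
        th = compute_theta(pts, center, b)
        for i in range(50):
            rad = pts[i] - center
            c = np.dot(rad, b[i]) / np.linalg.norm(rad)
            expect = np.degrees(np.arccos(np.clip(c, -1, 1))) % 180.0
            assert abs(th[i] - expect) < 1e-9

    def test_center_node_excluded(self):
        center = np.array([1.0, 2.0])
        th = compute_theta(np.array([[1.0, 2.0]]), center, np.array([[0.0, 1.0]]))
        assert np.isnan(th[0])

    @pytest.mark.parametrize(
        "theta,expect", [(0.0, 1.0), (60.0, 2.0)]
    )
    def test_radial_projection_cosine(self, theta, expect):
        out = radial_project(np.array([1.0]), np.array([theta]))
        assert np.isclose(out[0], expect)

    def test_cutout_never_evaluated(self):
        out = radial_project(np.array([1.0, 1.0]), np.array([89.0, 110.0]))
        assert np.isnan(out).all()

    @pytest.mark.parametrize(
        "theta,expect", [(0.0, 1.0), (45.0, 0.5), (80.0, 0.0), (180.0 - 1e-9, 1.0)]
    )
    def test_angular_mask_values(self, theta, expect):
        m = angular_mask(np.array([theta]))
        assert np.isclose(m.M[0], expect, atol=1e-9)


class TestCompounding:
    PAIRS = [(1, 1), (2, 2), (1, 2), (2, 1)]

    def test_equal_fields_passthrough(self, rng):
        u = rng.normal(size=(6, 6))
        fields = {p: u for p in self.PAIRS}
        masks = {p: AngularMask(rng.uniform(0.1, 1.0, size=(6, 6))) for p in self.PAIRS}
        out, valid = compound_displacements(fields, masks)
        assert valid.all()
        assert np.allclose(out, u, atol=1e-12)

    def test_single_active_pairing(self, rng):
        u = {p: rng.normal(size=(4, 4)) for p in self.PAIRS}
        masks = {p: AngularMask(np.zeros((4, 4))) for p in self.PAIRS}
        masks[(1, 1)] = AngularMask(np.ones((4, 4)))
        out, valid = compound_displacements(u, masks)
        assert np.allclose(out, u[(1, 1)], atol=1e-12)

    def test_matches_brute_force_weighted_sum(self, rng):
        u = {p: rng.normal(size=(5, 5)) for p in self.PAIRS}
        m = {p: rng.uniform(0, 1, size=(5, 5)) for p in self.PAIRS}
        out, valid = compound_displacements(u, {p: AngularMask(m[p]) for p in self.PAIRS})
        for i in range(5):
            for j in range(5):
                w = [m[(1, 1)][i, j], m[(2, 2)][i, j],
                     0.5 * m[(1, 2)][i, j], 0.5 * m[(2, 1)][i, j]]
                vals = [u[(1, 1)][i, j], u[(2, 2)][i, j], u[(1, 2)][i, j], u[(2, 1)][i, j]]
                expect = np.dot(w, vals) / np.sum(w)
                assert abs(out[i, j] - expect) < 1e-12

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_convex_combination_bounds(self, seed):
        rng = np.random.default_rng(seed)
        u = {p: rng.normal(size=(4, 4)) for p in self.PAIRS}
        m = {p: AngularMask(rng.uniform(0, 1, size=(4, 4))) for p in self.PAIRS}
        out, valid = compound_displacements(u, m)
        stack = np.stack([u[p] for p in self.PAIRS])
        assert np.all(out[valid] <= stack.max(axis=0)[valid] + 1e-12)
        assert np.all(out[valid] >= stack.min(axis=0)[valid] - 1e-12)

    def test_all_masked_node_invalid(self):
        u = {p: np.ones((2, 2)) for p in self.PAIRS}
        m = {p: AngularMask(np.zeros((2, 2))) for p in self.PAIRS}
        out, valid = compound_displacements(u, m)
        assert not valid.any()
        assert np.isnan(out).all()

    def test_lateral_displacements_structurally_excluded(self):
        # the fusion consumes projected radial fields only: no lateral input
        params = inspect.signature(compound_displacements).parameters
        assert "u_rad_fields" in params
        assert not any("lat" in name for name in params)
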