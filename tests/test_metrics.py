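"""gCNR, ROIs, regional partition, drift error, SNRe and paired tests."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from aortaus.geometry import CartesianGrid
from aortaus.metrics import (
    exclude_lateral_sections,
    gcnr,
    make_rois,
    mean_drift_error,
    paired_compare,
    partition_regions,
    snre,
)
from aortaus.strain import build_wall_mesh, circle_contour

CENTER = np.array([0.0, 40.0])
ANCHOR = np.array([0.0, -1.0])


def circle_mesh(radius=10.0, n_circ=360):
    return build_wall_mesh(
        circle_contour(CENTER, radius, n_circ), 1.7, 5, center=CENTER,
        anterior_direction=ANCHOR,
    )


class TestGcnr:
    def test_identical_distributions_overlap(self, rng):
        a = rng.rayleigh(size=100_000)
        b = rng.rayleigh(size=100_000)
        assert gcnr(a, b) < 0.05

    def test_disjoint_supports(self, rng):
        a = rng.uniform(0, 1, 1000)
        b = rng.uniform(2, 3, 1000)
        assert gcnr(a, b) == 1.0

    def test_gaussian_gap_closed_form(self, rng):
        # two unit-variance normals, means 3 apart: overlap = 2 Phi(-1.5)
        a = rng.normal(0.0, 1.0, 100_000)
        b = rng.normal(3.0, 1.0, 100_000)
        expect = 1.0 - 2.0 * stats.norm.cdf(-1.5)
        assert abs(gcnr(a, b) - expect) < 0.02

    def test_bounded_and_bin_stability(self, rng):
        a = rng.rayleigh(1.0, 20_000)
        b = rng.rayleigh(2.0, 20_000)
        vals = [gcnr(a, b, n_bins=n) for n in (128, 256, 512)]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert max(vals) - min(vals) < 0.03

    def test_monotone_map_invariance_with_rank_binning(self, rng):
        a = rng.rayleigh(1.0, 20_000) + 0.1
        b = rng.rayleigh(2.0, 20_000) + 0.1
        before = gcnr(a, b, binning="rank")
        after = gcnr(np.log(a), np.log(b), binning="rank")
        assert abs(before - after) < 1e-12

    def test_empty_roi_rejected(self, rng):
        with pytest.raises(ValueError):
            gcnr(np.array([]), rng.normal(size=10))


class TestRois:
    def grid(self):
        return CartesianGrid.from_extent(-14, 14, 26, 54, 0.1)

    def test_eroded_lumen_radius(self):
        wall, lumen = make_rois(circle_mesh(n_circ=128), self.grid(), erosion_radius=0.6)
        pts = self.grid().points()
        r = np.linalg.norm(pts - CENTER, axis=-1)
        assert r[lumen].max() <= 9.4 + 0.15  # within ~one grid cell
        assert r[lumen].max() >= 9.4 - 0.15

    def test_wall_lumen_disjoint(self):
        wall, lumen = make_rois(circle_mesh(n_circ=128), self.grid())
        assert not np.any(wall & lumen)

    def test_erosion_matches_distance_transform_oracle(self):
        mesh = circle_mesh(n_circ=128)
        grid = CartesianGrid.from_extent(-12, 12, 28, 52, 0.2)
        _, lumen = make_rois(mesh, grid, erosion_radius=0.6)
        # brute-force oracle: a pixel survives erosion iff no background
        # pixel of the un-eroded mask lies within the structuring radius
        pts = grid.points()
        inside = np.linalg.norm(pts - CENTER, axis=-1) <= 10.0 - 1e-9
        from scipy.ndimage import distance_transform_edt

        dx, dz = grid.spacing
        dist = distance_transform_edt(inside, sampling=(dz, dx))
        r_px = int(round(0.6 / max(dx, dz)))
        oracle = dist > r_px * max(dx, dz) - 1e-9
        # agreement away from the discretized boundary
        disagree = np.mean(lumen != (oracle & inside))
        assert disagree < 0.02

    def test_erosion_emptying_lumen_rejected(self):
        mesh = circle_mesh(radius=1.0, n_circ=64)
        grid = CartesianGrid.from_extent(-3, 3, 37, 43, 0.2)
        with pytest.raises(ValueError):
            make_rois(mesh, grid, erosion_radius=2.0)


class TestRegions:
    def test_anchor_node_region_1_opposite_region_5(self):
        mesh = circle_mesh()
        part = partition_regions(mesh, ANCHOR)
        top = np.argmin(mesh.middle_layer()[:, 1])  # most anterior node
        bottom = np.argmax(mesh.middle_layer()[:, 1])
        assert part.region_index[top] == 1
        assert part.region_index[bottom] == 5

    def test_clockwise_rotation_increments_region(self):
        mesh = circle_mesh()
        part0 = partition_regions(mesh, ANCHOR)
        # rotate nodes 45 degrees clockwise on screen (x right, z down):
        # with z pointing down this is the mathematically positive rotation
        ang = np.deg2rad(45.0)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = replace(mesh, nodes=(mesh.nodes - CENTER) @ R.T + CENTER)
        part1 = partition_regions(rotated, ANCHOR)
        assert np.array_equal(part1.region_index, part0.region_index % 8 + 1)

    def test_eight_balanced_sectors(self):
        part = partition_regions(circle_mesh(), ANCHOR)
        counts = np.bincount(part.region_index)[1:]
        assert len(counts) == 8
        assert counts.max() - counts.min() <= 1


class TestDriftError:
    def test_identical_meshes_zero(self):
        m = circle_mesh()
        assert mean_drift_error(m, m) == 0.0

    def test_three_four_five(self):
        m = circle_mesh()
        shifted = replace(m, nodes=m.nodes + np.array([3.0, 4.0]))
        assert np.isclose(mean_drift_error(m, shifted), 5.0)

    def test_matches_brute_force(self, rng):
        m = circle_mesh(n_circ=32)
        m2 = replace(m, nodes=m.nodes + rng.normal(scale=0.5, size=m.nodes.shape))
        a, b = m.middle_layer(), m2.middle_layer()
        expect = np.mean([np.sqrt((a[i, 0] - b[i, 0]) ** 2 + (a[i, 1] - b[i, 1]) ** 2)
                          for i in range(a.shape[0])])
        assert abs(mean_drift_error(m, m2) - expect) < 1e-12

    def test_metric_properties(self, rng):
        m = circle_mesh(n_circ=16)
        A = replace(m, nodes=m.nodes + rng.normal(scale=1.0, size=m.nodes.shape))
        B = replace(m, nodes=m.nodes + rng.normal(scale=1.0, size=m.nodes.shape))
        assert np.isclose(mean_drift_error(m, A), mean_drift_error(A, m))
        assert mean_drift_error(m, B) <= mean_drift_error(m, A) + mean_drift_error(A, B) + 1e-12

    def test_node_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_drift_error(circle_mesh(n_circ=32), circle_mesh(n_circ=36))


class TestSnre:
    def test_unit_ratio_zero_db(self, rng):
        v = rng.normal(size=5000)
        v = (v - v.mean()) / v.std() + 1.0  # mean 1, std 1
        assert abs(snre(v)) < 1e-9

    def test_ten_to_one_is_20db(self, rng):
        v = rng.normal(size=5000)
        v = (v - v.mean()) / v.std() * 0.1 + 1.0
        assert abs(snre(v) - 20.0) < 1e-9

    def test_hand_computed_example(self):
        v = np.array([0.01, 0.012, 0.008, 0.011, 0.009])
        expect = 20.0 * np.log10(np.mean(v) / np.std(v))
        assert np.isclose(snre(v), expect, atol=1e-12)

    def test_negative_mean_uses_magnitude(self):
        v = np.array([-0.01, -0.012, -0.008, -0.011, -0.009])
        assert snre(v) == snre(-v)

    def test_zero_variance_flagged_infinite(self):
        assert snre(np.full(10, 0.01)) == np.inf


class TestPairedCompare:
    def test_identical_pairs_degenerate(self):
        a = np.arange(8.0)
        stat, p, name = paired_compare(a, a)
        assert p == 1.0 and "degenerate" in name

    def test_large_shift_significant(self, rng):
        a = rng.normal(size=20)
        b = a + 5.0 + rng.normal(scale=0.1, size=20)
        _, p, name = paired_compare(a, b)
        assert p < 0.05

    def test_t_statistic_matches_textbook_formula(self, rng):
        a = rng.normal(size=15)
        b = a + rng.normal(0.3, 0.5, size=15)
        d = a - b
        if stats.shapiro(d).pvalue >= 0.05:
            t, p, name = paired_compare(a, b)
            expect = np.mean(d) / (np.std(d, ddof=1) / np.sqrt(len(d)))
            assert name == "paired t-test"
            assert abs(t - expect) < 1e-6

    def test_nonnormal_uses_wilcoxon(self, rng):
        a = rng.normal(size=40)
        b = a - np.exp(rng.normal(size=40))  # heavily skewed differences
        _, _, name = paired_compare(a, b)
        assert name == "wilcoxon signed-rank"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_compare(np.array([1.0, 2.0]), np.array([2.0, 3.0]))


class TestLateralExclusion:
    def test_zero_width_keeps_all(self):
        keep = exclude_lateral_sections(circle_mesh(), ANCHOR, width_deg=0.0)
        assert keep.all()

    def test_full_width_excludes_all(self):
        keep = exclude_lateral_sections(circle_mesh(), ANCHOR, width_deg=360.0)
        assert not keep.any()

    def test_section_width_on_uniform_contour(self):
        # 360 uniformly spaced nodes; 40-degree sections at the two lateral
        # walls remove ~40 nodes each
        keep = exclude_lateral_sections(circle_mesh(n_circ=360), ANCHOR, width_deg=40.0)
        assert (~keep).sum() == pytest.approx(80, abs=2)
        # default width matches the analysis convention
        keep_d = exclude_lateral_sections(circle_mesh(n_circ=360), ANCHOR)
        assert (~keep_d).sum() == pytest.approx(2 * 37.5, abs=2)
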