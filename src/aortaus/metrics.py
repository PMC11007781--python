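"""Image- and strain-quality metrics: gCNR, regional analysis, drift error,
elastographic SNR and paired mode comparisons.

gCNR is one minus the overlap of the amplitude probability densities of two
regions (histogram estimate over the pooled range), bounded in [0, 1] and
invariant to monotone amplitude mappings applied to both regions.  The mean
drift error (ME) is the mean end-of-cycle position error of the tracked
middle wall layer; the elastographic SNR is ``20 log10(|mean| / std)`` of the
strain over a region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import stats
from scipy.ndimage import binary_erosion
from skimage.morphology import disk

from .geometry import CartesianGrid
from .strain import WallMesh

__all__ = [
    "RegionPartition",
    "MetricReport",
    "gcnr",
    "make_rois",
    "partition_regions",
    "mean_drift_error",
    "snre",
    "paired_compare",
    "exclude_lateral_sections",
    "clockwise_angle_deg",
]


def gcnr(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_bins: int = 256,
    binning: str = "width",
) -> float:
    """Generalized contrast-to-noise ratio between two amplitude samples.

    ``1 - sum_k min(p_a[k], p_b[k])`` over a shared ``n_bins`` histogram
    spanning the pooled range, each density normalized to sum 1.
    ``binning='width'`` uses equal-width bins over the pooled min-max range;
    ``'rank'`` places bin edges at pooled-sample quantiles, which makes the
    estimate exactly invariant to monotone amplitude mappings.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both regions must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 0.0  # identical degenerate distributions overlap fully
    if binning == "rank":
        pooled = np.concatenate([a, b])
        edges = np.unique(np.quantile(pooled, np.linspace(0.0, 1.0, n_bins + 1)))
        edges[-1] = np.nextafter(edges[-1], np.inf)
    elif binning == "width":
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        raise ValueError("binning must be 'width' or 'rank'")
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(1.0 - np.minimum(pa, pb).sum())


def _points_in_polygon(points: np.ndarray, contour: np.ndarray) -> np.ndarray:
    return MplPath(contour, closed=True).contains_points(points)


def make_rois(mesh: WallMesh, grid: CartesianGrid, erosion_radius: float = 0.6):
    """Wall and lumen binary masks on ``grid``.

    The wall mask is the mesh annulus (inside the outer contour, outside the
    inner); the lumen mask is the inner contour eroded by a disk of
    ``erosion_radius`` mm so specular wall reflections are excluded.
    """
    pts = grid.points().reshape(-1, 2)
    inside_outer = _points_in_polygon(pts, mesh.outer_contour())
    inside_inner = _points_in_polygon(pts, mesh.inner_contour())
    wall = (inside_outer & ~inside_inner).reshape(grid.shape)
    lumen = inside_inner.reshape(grid.shape)
    dx, dz = grid.spacing
    r_px = int(round(erosion_radius / max(dx, dz)))
    if r_px > 0:
        lumen = binary_erosion(lumen, structure=disk(r_px))
    if not lumen.any():
        raise ValueError("erosion emptied the lumen ROI")
    return wall, lumen


def clockwise_angle_deg(vectors: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Clockwise angle (deg, [0, 360)) from ``anchor`` to each vector, as
    displayed with x right and z down."""
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    a = np.asarray(anchor, dtype=float)
    ang = np.degrees(np.arctan2(a[0] * v[:, 1] - a[1] * v[:, 0], v @ a))
    return np.squeeze(np.mod(ang, 360.0))


@dataclass
class RegionPartition:
    """Eight 45-degree wall sectors; regions 1 and 5 centred on the anchor
    direction (the reference-probe axis through the vessel) and its opposite,
    numbered clockwise."""

    region_index: np.ndarray  # per circumferential node, in 1..8
    anchor: np.ndarray


def partition_regions(mesh: WallMesh, anchor_direction: np.ndarray) -> RegionPartition:
    """Assign every circumferential node to one of 8 clockwise 45-deg sectors."""
    rel = mesh.middle_layer() - mesh.center
    ang = np.atleast_1d(clockwise_angle_deg(rel, anchor_direction))
    idx = (np.floor(((ang + 22.5) % 360.0) / 45.0).astype(int)) % 8 + 1
    return RegionPartition(region_index=idx, anchor=np.asarray(anchor_direction, float))


def mean_drift_error(mesh_bs: WallMesh, mesh_ed: WallMesh) -> float:
    """Mean distance (mm) between corresponding middle-layer nodes of the
    begin-systole and end-diastole meshes (end-of-cycle tracking drift)."""
    a = mesh_bs.middle_layer()
    b = mesh_ed.middle_layer()
    if a.shape != b.shape:
        raise ValueError("meshes must have matching node counts")
    return float(np.mean(np.linalg.norm(a - b, axis=1)))


def snre(strain_values: np.ndarray) -> float:
    """Elastographic SNR in dB: ``20 log10(|mean| / std)``.

    The magnitude of the mean is used so contracting (negative-mean) strains
    report the same precision as expanding ones.  Zero variance returns +inf.
    """
    v = np.asarray(strain_values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 strain values")
    sd = float(np.std(v))
    mu = float(np.mean(v))
    if sd <= abs(mu) * 1e-12:  # zero variance up to rounding of the mean
        return float("inf")
    return float(20.0 * np.log10(abs(mu) / sd))


def paired_compare(values_a: np.ndarray, values_b: np.ndarray, alpha_normality: float = 0.05):
    """Paired comparison of two metric samples.

    Differences are tested for normality (Shapiro-Wilk at
    ``alpha_normality``); a paired t-test is used when normality holds, a
    Wilcoxon signed-rank test otherwise.  Returns
    ``(statistic, p_value, test_name)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length paired samples with n >= 3")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0, "degenerate (all differences zero)"
    _, p_norm = stats.shapiro(d)
    if p_norm >= alpha_normality:
        t, p = stats.ttest_rel(a, b)
        return float(t), float(p), "paired t-test"
    w, p = stats.wilcoxon(a, b)
    return float(w), float(p), "wilcoxon signed-rank"


def exclude_lateral_sections(
    mesh: WallMesh,
    anchor_direction: np.ndarray,
    width_deg: float = 37.5,
) -> np.ndarray:
    """Mask (True = keep) removing the two low-contrast lateral wall sections.

    Each excluded section spans ``width_deg`` centred on the directions
    perpendicular to the anchor (the left and right wall as seen from the
    reference probe).
    """
    rel = mesh.middle_layer() - mesh.center
    ang = np.atleast_1d(clockwise_angle_deg(rel, anchor_direction))
    half = width_deg / 2.0
    near_90 = np.minimum(np.abs(ang - 90.0), np.abs(ang - 270.0))
    return ~(near_90 < half)


@dataclass
class MetricReport:
    """Quality metrics of one dataset/mode."""

    mode: str
    gcnr_global: float = np.nan
    gcnr_regions: dict = field(default_factory=dict)
    me: float = np.nan
    me_regions: dict = field(default_factory=dict)
    snre_circ: float = np.nan
    snre_rad: float = np.nan
    peak_frame: int = -1

    def as_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "gcnr_global": self.gcnr_global,
            "me_mm": self.me,
            "snre_circ_db": self.snre_circ,
            "snre_rad_db": self.snre_rad,
            "peak_frame": self.peak_frame,
        }
        for r, v in self.gcnr_regions.items():
            d[f"gcnr_r{r}"] = v
        for r, v in self.me_regions.items():
            d[f"me_r{r}_mm"] = v
        return d
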