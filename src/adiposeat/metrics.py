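"""Adipose effect-size statistics and biomechanical-risk measures.

The central statistic is a Cohen's-d-style standardized mean difference
between two pixel regions,

    d = (mean_a - mean_b) / s_pooled,
    s_pooled = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)),

applied two ways:

* **SubQF effect size** = d(surrounding, under): positive values mean the
  adipose under the ischium is darker than the surrounding adipose;
* **IMAT effect size** = d(reference adipose, gluteus): values near zero or
  negative mean heavy fat infiltration of the gluteus maximus (a fully
  infiltrated muscle is brighter than the reference depot, so d < 0).

Both are invariant to affine intensity rescaling, which is what makes them
robust to the brightness constant the coil correction adds back.

Biomechanical risk is summarized by the mean soft-tissue depth under the IT
over a 50-mm window (thinner tissue = higher risk) and the radius of the
least-squares circle through the inferior bone contour over the same window
(smaller radius = more peaked = higher risk).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ITLandmark,
    ParameterError,
    RegionError,
    RegionIntensities,
    SegmentationSet,
    UndefinedStatisticError,
)


def pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    """(n-1)-weighted two-sample pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ParameterError("pooled SD needs at least 2 values per sample")
    return math.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
        / (na + nb - 2)
    )


def effect_size(a: RegionIntensities, b: RegionIntensities) -> float:
    """Standardized mean intensity difference (mean_a - mean_b)/s_pooled."""
    if a.n < 2 or b.n < 2:
        raise ParameterError(
            f"effect size needs n >= 2 per region (got {a.n}, {b.n})"
        )
    sp = pooled_sd(a.values, b.values)
    if sp == 0.0:
        raise UndefinedStatisticError(
            f"pooled SD of '{a.name}' and '{b.name}' is zero"
        )
    return float((a.mean - b.mean) / sp)


@dataclass
class AdiposeMetrics:
    """Per-subject adipose statistics plus the region summaries behind them."""

    subqf_effect_size: float
    imat_effect_size: float
    region_stats: dict = field(default_factory=dict)  # name -> (mean, sd, n)

    def to_row(self) -> dict:
        row = {
            "subqf_effect_size": self.subqf_effect_size,
            "imat_effect_size": self.imat_effect_size,
        }
        for name, (mean, sd, n) in self.region_stats.items():
            row[f"{name}_mean"] = mean
            row[f"{name}_sd"] = sd
            row[f"{name}_n"] = n
        return row


def compute_adipose_metrics(
    under: RegionIntensities,
    surrounding: RegionIntensities,
    ref_adipose: RegionIntensities,
    gluteus: RegionIntensities,
) -> AdiposeMetrics:
    """Both effect sizes and the mean/SD/count of every analysis region."""
    stats = {
        r.name: (r.mean, r.sd, r.n)
        for r in (surrounding, under, ref_adipose, gluteus)
    }
    return AdiposeMetrics(
        subqf_effect_size=effect_size(surrounding, under),
        imat_effect_size=effect_size(ref_adipose, gluteus),
        region_stats=stats,
    )


@dataclass
class MidpointResult:
    """Threshold-based IMAT fraction, flagged when the histogram is degenerate."""

    fraction: float
    threshold: float
    degenerate: bool = False
    note: str = ""


def midpoint_imat_fraction(
    ref_adipose: RegionIntensities,
    gluteus: RegionIntensities,
    n_bins: int = 64,
) -> MidpointResult:
    """Fraction of gluteus pixels at/above the adipose-muscle midpoint.

    The cutoff is the midpoint of the reference-adipose mean and the modal
    gluteus intensity below that mean.  For very lean or fully infiltrated
    muscles no meaningful muscle mode exists and the result is returned with
    ``degenerate=True`` rather than as a silent number.
    """
    if ref_adipose.n < 2 or gluteus.n < 2:
        raise ParameterError("midpoint method needs n >= 2 per region")
    fat_mean = ref_adipose.mean
    g = gluteus.values
    below = g[g < fat_mean]
    if below.size < max(10, 0.05 * g.size):
        return MidpointResult(
            fraction=float(np.mean(g >= fat_mean)),
            threshold=fat_mean,
            degenerate=True,
            note="almost no gluteus pixels below the adipose mean "
            "(fully infiltrated muscle)",
        )
    counts, edges = np.histogram(below, bins=n_bins)
    mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    if mode >= fat_mean:
        return MidpointResult(
            fraction=float("nan"),
            threshold=float("nan"),
            degenerate=True,
            note="gluteus mode is not darker than the adipose mean",
        )
    threshold = 0.5 * (fat_mean + mode)
    return MidpointResult(
        fraction=float(np.mean(g >= threshold)), threshold=float(threshold)
    )


def bulk_tissue_thickness(
    seg: SegmentationSet,
    landmark: ITLandmark,
    window_mm: float = 50.0,
) -> float:
    """Mean vertical soft-tissue depth under the IT over a 50-mm AP window.

    For each column within +/- window/2 of the landmark that contains bone,
    the depth is the vertical distance from the bone's inferior boundary to
    the outer skin boundary (the bottom of the SubQF mask, skin included).
    """
    if window_mm <= 0:
        raise ParameterError("window_mm must be positive")
    sp_r, sp_c = seg.spacing_mm
    half = window_mm / 2.0
    depths = []
    for c in range(seg.shape[1]):
        if abs(c * sp_c - landmark.ap_mm) > half:
            continue
        bone_col = np.nonzero(seg.ischium[:, c])[0]
        if bone_col.size == 0:
            continue
        tissue_col = np.nonzero(seg.subqf[:, c])[0]
        below = tissue_col[tissue_col > bone_col.max()]
        if below.size == 0:
            continue
        depths.append((below.max() - bone_col.max()) * sp_r)
    if not depths:
        raise RegionError(
            "thickness window", "no columns with bone over soft tissue in window"
        )
    return float(np.mean(depths))


@dataclass
class CurvatureResult:
    """Radius of the fitted circle; infinite + flagged when degenerate."""

    radius_mm: float
    center_mm: tuple[float, float]
    degenerate: bool = False


def taubin_circle_fit(points: np.ndarray) -> CurvatureResult:
    """Algebraic (Taubin) least-squares circle through 2D points.

    Deterministic, initialization-free, and exact on noiseless circles.
    Collinear points yield a degenerate (infinite-radius) result.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ParameterError("circle fit needs an (n>=3, 2) point array")
    x, y = pts[:, 0], pts[:, 1]
    xm, ym = x.mean(), y.mean()
    u, v = x - xm, y - ym
    z = u * u + v * v
    zm = z.mean()
    if zm == 0.0:
        raise ParameterError("all points coincide")
    z0 = (z - zm) / (2.0 * math.sqrt(zm))
    _, s, vt = np.linalg.svd(np.column_stack([z0, u, v]), full_matrices=False)
    a_vec = vt[2]
    a0 = a_vec[0] / (2.0 * math.sqrt(zm))
    # circle a0*(u^2+v^2) + a1*u + a2*v + a3 = 0 in centered coordinates
    a1, a2 = a_vec[1], a_vec[2]
    a3 = -zm * a0
    scale = math.sqrt(a1 * a1 + a2 * a2)
    if abs(a0) < 1e-12 * max(scale, 1e-30):
        return CurvatureResult(
            radius_mm=float("inf"), center_mm=(float("nan"), float("nan")),
            degenerate=True,
        )
    cx = -a1 / (2.0 * a0)
    cy = -a2 / (2.0 * a0)
    radius = math.sqrt(max(cx * cx + cy * cy - a3 / a0, 0.0))
    return CurvatureResult(
        radius_mm=float(radius), center_mm=(float(cx + xm), float(cy + ym))
    )


def sagittal_radius_of_curvature(
    bone_contour_mm: np.ndarray,
    landmark: ITLandmark,
    window_mm: float = 50.0,
) -> CurvatureResult:
    """Circle radius through the bone contour within 50 mm arc of the peak.

    ``bone_contour_mm`` is an ordered (n, 2) array of (ap_mm, height_mm)
    points; the points within ``window_mm/2`` of arc length from the point
    nearest the landmark are fitted with a Taubin circle.
    """
    pts = np.asarray(bone_contour_mm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ParameterError("contour must be an (n>=3, 2) array of mm points")
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    anchor = np.array([landmark.ap_mm, landmark.height_mm])
    nearest = int(np.argmin(np.linalg.norm(pts - anchor, axis=1)))
    sel = np.abs(arc - arc[nearest]) <= window_mm / 2.0
    window = pts[sel]
    if window.shape[0] < 3:
        raise ParameterError("fewer than 3 contour points within the window")
    return taubin_circle_fit(window)
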