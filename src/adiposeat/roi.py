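"""Ischium-anchored analysis regions.

All regions are anchored at the peak of the ischial tuberosity — the most
inferior bone pixel in the sagittal slice:

* the **subcutaneous band** is every SubQF pixel at or inferior to the point
  10 mm superior to the peak;
* **under the ischium** is the part of that band whose anterior-posterior
  position falls within the ischium's AP footprint (its extent within the
  band's height range) widened by 5 mm on each side; **surrounding** is the
  rest of the band — the two sets partition the band exactly;
* the **IMAT reference adipose** is every SubQF pixel strictly posterior to
  the peak and inferior to the gluteus maximus' inferior boundary at its AP
  position (columns the gluteus does not reach are excluded).

A pixel belongs to a mm-defined region when its center does; the widened
footprint interval is closed on both ends.
"""

from __future__ import annotations

import numpy as np

from .core import (
    ITLandmark,
    ParameterError,
    RegionIntensities,
    RegionError,
    SagittalSlice,
    SegmentationSet,
)


def find_it_peak(
    ischium_mask: np.ndarray, spacing_mm: tuple[float, float]
) -> ITLandmark:
    """Most inferior ischium pixel; AP centroid of ties, rounded anteriorly."""
    mask = np.asarray(ischium_mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise RegionError("ischium", "ischium mask is empty")
    peak_row = int(rows.max())
    tied = cols[rows == peak_row]
    peak_col = int(np.floor(tied.mean()))
    n_rows = mask.shape[0]
    return ITLandmark(
        row=peak_row,
        col=peak_col,
        height_mm=(n_rows - 1 - peak_row) * spacing_mm[0],
        ap_mm=peak_col * spacing_mm[1],
    )


def _gather(
    name: str, image: SagittalSlice, rows: np.ndarray, cols: np.ndarray
) -> RegionIntensities:
    if rows.size == 0:
        raise RegionError(name)
    coords = np.column_stack([rows, cols])
    return RegionIntensities(name, image.data[rows, cols], coords)


def extract_subqf_regions(
    image: SagittalSlice,
    seg: SegmentationSet,
    landmark: ITLandmark,
    margin_mm: float = 5.0,
    band_mm: float = 10.0,
) -> tuple[RegionIntensities, RegionIntensities]:
    """Split the subcutaneous band into under- and surrounding-ischium parts.

    Returns ``(under, surrounding)`` with intensities taken from ``image``
    (pass the corrected slice).  Raises :class:`RegionError` naming whichever
    region comes out empty.
    """
    if margin_mm <= 0 or band_mm <= 0:
        raise ParameterError("margin_mm and band_mm must be positive")
    if image.shape != seg.shape:
        raise ParameterError("image and segmentation shapes differ")
    sp_r, sp_c = seg.spacing_mm

    s_rows, s_cols = np.nonzero(seg.subqf)
    if s_rows.size == 0:
        raise RegionError("subqf", "SubQF mask is empty")
    # at or inferior to the point band_mm superior to the peak
    in_band = (landmark.row - s_rows) * sp_r <= band_mm
    b_rows, b_cols = s_rows[in_band], s_cols[in_band]
    if b_rows.size == 0:
        raise RegionError("subqf band")

    i_rows, i_cols = np.nonzero(seg.ischium)
    in_range = (landmark.row - i_rows) * sp_r <= band_mm
    if not np.any(in_range):
        raise RegionError(
            "ischium footprint", "no ischium pixels within the band height range"
        )
    foot_min = i_cols[in_range].min() * sp_c - margin_mm
    foot_max = i_cols[in_range].max() * sp_c + margin_mm

    ap = b_cols * sp_c
    is_under = (ap >= foot_min) & (ap <= foot_max)
    under = _gather("adipose_under", image, b_rows[is_under], b_cols[is_under])
    surrounding = _gather(
        "adipose_surrounding", image, b_rows[~is_under], b_cols[~is_under]
    )
    return under, surrounding


def extract_imat_regions(
    image: SagittalSlice,
    seg: SegmentationSet,
    landmark: ITLandmark,
) -> tuple[RegionIntensities, RegionIntensities]:
    """Reference adipose (posterior/inferior to the gluteus) and gluteus.

    Returns ``(ref_adipose, gluteus)``.  The reference depot is every SubQF
    pixel strictly posterior to the landmark and below the gluteus' inferior
    boundary at its column.
    """
    if image.shape != seg.shape:
        raise ParameterError("image and segmentation shapes differ")
    sp_r, sp_c = seg.spacing_mm
    g_rows, g_cols = np.nonzero(seg.gluteus)
    if g_rows.size == 0:
        raise RegionError("gluteus", "gluteus mask is empty")
    gluteus = _gather("gluteus", image, g_rows, g_cols)

    # inferior boundary of the gluteus per column
    n_cols = seg.shape[1]
    bottom = np.full(n_cols, -1, dtype=int)
    np.maximum.at(bottom, g_cols, g_rows)

    s_rows, s_cols = np.nonzero(seg.subqf)
    ap = s_cols * sp_c
    sel = (ap > landmark.ap_mm) & (bottom[s_cols] >= 0) & (s_rows > bottom[s_cols])
    ref = _gather("ref_adipose_posterior", image, s_rows[sel], s_cols[sel])
    return ref, gluteus


def inferior_bone_contour(seg: SegmentationSet) -> np.ndarray:
    """Inferior ischium boundary as (ap_mm, height_mm) points ordered by AP.

    One point per column that contains bone: the most inferior bone pixel.
    This is the contour whose curvature at the IT peak is the sagittal
    radius-of-curvature risk measure.
    """
    sp_r, sp_c = seg.spacing_mm
    rows, cols = np.nonzero(seg.ischium)
    if rows.size == 0:
        raise RegionError("ischium", "ischium mask is empty")
    n_rows = seg.shape[0]
    pts = []
    for c in np.unique(cols):
        r = rows[cols == c].max()
        pts.append((c * sp_c, (n_rows - 1 - r) * sp_r))
    return np.asarray(pts, dtype=float)
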