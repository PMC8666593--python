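"""Shared containers and coordinate conventions.

All images are single sagittal slices stored as 2D float arrays indexed
``data[row, col]``:

* row 0 is the most **superior** row; rows increase inferiorly.
* col 0 is the most **anterior** column; columns increase posteriorly.
* ``spacing_mm = (row_mm, col_mm)`` gives the physical pixel size.

Physical coordinates derived from indices:

* ``height_mm`` is measured upward from the inferior image edge — the side
  of the planar receiver coil under the cushion — so the coil-gradient
  model is a function of height:  ``height = (n_rows - 1 - row) * row_mm``.
* ``ap_mm`` is the anterior–posterior position: ``ap = col * col_mm``.

Pixel-containment convention for mm-defined regions: a pixel belongs to a
region if its *center* coordinate satisfies the region predicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class AdiposeatError(Exception):
    """Base class for all package errors."""


class ParameterError(AdiposeatError, ValueError):
    """Invalid generation or configuration parameters."""


class GenerationError(AdiposeatError):
    """Synthetic geometry left a required compartment empty."""


class RegionError(AdiposeatError):
    """A named analysis region is empty or otherwise unusable."""

    def __init__(self, region: str, message: str | None = None):
        self.region = region
        super().__init__(message or f"region '{region}' is empty or invalid")


class FitError(AdiposeatError):
    """Curve fitting failed; carries the residuals that were available."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        self.residuals = residuals
        super().__init__(message)


class UndefinedStatisticError(AdiposeatError):
    """A statistic is undefined for the given input (e.g. zero pooled SD)."""


@dataclass
class SagittalSlice:
    """One 2D sagittal intensity image with physical pixel spacing."""

    data: np.ndarray
    spacing_mm: tuple[float, float]  # (row, col) pixel size in mm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("slice data must be 2D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ParameterError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row_heights_mm(self) -> np.ndarray:
        """Height above the inferior (coil-side) edge for every row."""
        n = self.data.shape[0]
        return (n - 1 - np.arange(n)) * self.spacing_mm[0]

    def height_of_row(self, row: float) -> float:
        return (self.data.shape[0] - 1 - row) * self.spacing_mm[0]

    def ap_of_col(self, col: float) -> float:
        return col * self.spacing_mm[1]


@dataclass(frozen=True)
class ITLandmark:
    """Peak (most inferior point) of the ischial tuberosity."""

    row: int
    col: int
    height_mm: float
    ap_mm: float


@dataclass
class SegmentationSet:
    """Label masks co-registered to one slice, plus the IT-peak landmark.

    Masks are boolean arrays of the slice shape: ``ischium`` (pelvis/ischium
    bone), ``gluteus`` (gluteus maximus) and ``subqf`` (subcutaneous fat,
    including skin, which scan resolution does not separate).
    """

    ischium: np.ndarray
    gluteus: np.ndarray
    subqf: np.ndarray
    spacing_mm: tuple[float, float]
    landmark: ITLandmark | None = None

    def __post_init__(self) -> None:
        self.ischium = np.asarray(self.ischium, dtype=bool)
        self.gluteus = np.asarray(self.gluteus, dtype=bool)
        self.subqf = np.asarray(self.subqf, dtype=bool)
        if not (self.ischium.shape == self.gluteus.shape == self.subqf.shape):
            raise ParameterError("masks must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ischium.shape

    def label_volume(self) -> np.ndarray:
        """Integer label image: 1 = bone, 2 = gluteus, 3 = SubQF+skin."""
        lab = np.zeros(self.shape, dtype=np.int16)
        lab[self.ischium] = 1
        lab[self.gluteus] = 2
        lab[self.subqf] = 3
        return lab


@dataclass
class RegionIntensities:
    """Pixel intensities of one named analysis region.

    ``pixel_coords`` is an (n, 2) integer array of (row, col) indices in the
    source slice, aligned one-to-one with ``values``.
    """

    name: str
    values: np.ndarray
    pixel_coords: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pixel_coords = np.asarray(self.pixel_coords, dtype=int)
        if self.values.ndim != 1:
            raise ParameterError("region values must be a 1D vector")
        if self.pixel_coords.shape != (self.values.size, 2):
            raise ParameterError("pixel_coords must be (n, 2) matching values")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.n >= 2 else float("nan")


def region_from_mask(
    name: str, image: SagittalSlice, mask: np.ndarray
) -> RegionIntensities:
    """Collect the intensities of every pixel of a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ParameterError("mask shape does not match image")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise RegionError(name)
    coords = np.column_stack([rows, cols])
    return RegionIntensities(name, image.data[rows, cols], coords)
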