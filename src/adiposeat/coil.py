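"""Coil intensity-gradient correction from a homogeneous phantom.

A planar receiver coil under the cushion causes signal falloff with height
(the superior-inferior axis).  A scan of a homogeneous fluid phantom exposes
that falloff in isolation; its per-height mean in-mask intensity is fitted
with a two-term power law

    f(h) = a * (h + y0)^b + c

where ``h`` is the height above the inferior image edge (mm) and ``y0``
absorbs the offset of the coil plane below that edge.  Buttock slices are
corrected by subtracting ``f`` at each pixel's height; the image-height mean
of ``f`` is added back so the overall brightness scale is preserved (the
standardized effect sizes downstream are invariant to that global constant).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import FitError, ParameterError, SagittalSlice


@dataclass
class NormalizationCurve:
    """Fitted intensity-vs-height model of the coil falloff."""

    amplitude: float
    exponent: float
    offset: float  # constant term c
    axis_origin_mm: float  # y0, height of the coil plane below the image edge
    fit_residual_rms: float
    row_spacing_mm: float | None = None  # spacing the curve was fitted at

    def __call__(self, heights_mm: np.ndarray) -> np.ndarray:
        h = np.asarray(heights_mm, dtype=float)
        return (
            self.amplitude * np.power(h + self.axis_origin_mm, self.exponent)
            + self.offset
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationCurve":
        return cls(**d)


def _model(h, a, b, y0, c):
    return a * np.power(h + y0, b) + c


def _height_profile(
    phantom: SagittalSlice, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean in-mask intensity for every image row that intersects the mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != phantom.shape:
        raise ParameterError("mask shape does not match phantom")
    rows_present = np.nonzero(mask.any(axis=1))[0]
    heights = phantom.row_heights_mm()[rows_present]
    means = np.array(
        [phantom.data[r, mask[r]].mean() for r in rows_present]
    )
    return heights, means


def fit_normalization_curve(
    phantom: SagittalSlice, mask: np.ndarray
) -> NormalizationCurve:
    """Least-squares fit of the per-height phantom profile to a power law.

    The profile is the mean in-mask intensity of each image row.  Several
    starting points for the coil-plane offset and exponent are tried and the
    fit with the lowest residual sum of squares is kept.
    """
    heights, profile = _height_profile(phantom, mask)
    if heights.size < 10:
        raise ParameterError(
            f"mask spans only {heights.size} distinct heights; need >= 10"
        )

    span = float(profile.max() - profile.min())
    scale = max(abs(float(profile.mean())), 1.0)
    if span <= 1e-9 * scale:
        # flat field: no gradient to model
        return NormalizationCurve(
            amplitude=0.0,
            exponent=-0.5,
            offset=float(profile.mean()),
            axis_origin_mm=50.0,
            fit_residual_rms=float(np.sqrt(np.mean((profile - profile.mean()) ** 2))),
            row_spacing_mm=phantom.spacing_mm[0],
        )

    best = None
    bounds = ([-np.inf, -4.0, 1e-2, -np.inf], [np.inf, 4.0, 1e3, np.inf])
    h_min = float(heights.min())
    sign = 1.0 if profile[np.argmin(heights)] >= profile[np.argmax(heights)] else -1.0
    for y0_guess in (10.0, 50.0, 150.0):
        for b_guess in (-0.5, -1.0):
            a_guess = sign * span * (h_min + y0_guess) ** (-b_guess)
            c_guess = float(profile.min() if sign > 0 else profile.max())
            try:
                popt, _ = curve_fit(
                    _model,
                    heights,
                    profile,
                    p0=(a_guess, b_guess, y0_guess, c_guess),
                    bounds=bounds,
                    maxfev=5000,
                    xtol=1e-12,
                    ftol=1e-12,
                )
            except (RuntimeError, ValueError):
                continue
            resid = profile - _model(heights, *popt)
            sse = float(resid @ resid)
            if best is None or sse < best[0]:
                best = (sse, popt, resid)
    if best is None:
        raise FitError(
            "power-law fit did not converge from any starting point",
            residuals=profile - profile.mean(),
        )
    sse, popt, resid = best
    return NormalizationCurve(
        amplitude=float(popt[0]),
        exponent=float(popt[1]),
        axis_origin_mm=float(popt[2]),
        offset=float(popt[3]),
        fit_residual_rms=float(np.sqrt(np.mean(resid**2))),
        row_spacing_mm=phantom.spacing_mm[0],
    )


def correct_slice(
    image: SagittalSlice, curve: NormalizationCurve
) -> SagittalSlice:
    """Subtract the coil falloff, preserving the overall brightness scale.

    Every pixel gets ``- f(height) + mean_h f(height)`` added, where the mean
    runs over all image rows; the result is deterministic and commutes with
    adding a global constant to the input.
    """
    if (
        curve.row_spacing_mm is not None
        and abs(curve.row_spacing_mm - image.spacing_mm[0]) > 1e-9
    ):
        raise ParameterError(
            "curve was fitted at a different row spacing than this slice"
        )
    heights = image.row_heights_mm()
    f = curve(heights)
    if not np.all(np.isfinite(f)):
        raise ParameterError("normalization curve is not finite over the image")
    adjust = -f + f.mean()
    return SagittalSlice(image.data + adjust[:, None], image.spacing_mm)
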