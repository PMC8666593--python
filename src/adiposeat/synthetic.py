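"""Synthetic seated-buttock MRI data with exact ground truth.

The generator emulates what the analysis pipeline consumes:

* a **phantom calibration scan** — a homogeneous fluid-filled ball imaged on
  a planar receiver coil, so its only in-mask intensity structure is the
  vertical coil-gradient falloff plus noise;
* a **single-subject sagittal buttock slice** — an ischium with an
  inferior-most peak whose bone contour is an arc of known radius, a gluteus
  maximus posterior/superior to it with a configurable fraction of
  fat-infiltrated voxels, and a subcutaneous-fat layer (skin included in the
  mask) whose under-ischium band is darkened by a configurable standardized
  contrast; the coil gradient and scanner noise are applied last;
* a **cohort** of such subjects whose parameters are drawn from group-level
  distributions (pressure-injury history vs. none) calibrated to the scale
  of a clinical wheelchair-user population.

Every random draw flows from a single integer seed, so regeneration is
bit-identical.  Ground truth stores the exact compartment pixel sets, the
applied gradient field, and the pre-gradient image, so that downstream
stages can be verified to machine precision on noiseless data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    GenerationError,
    ITLandmark,
    ParameterError,
    SagittalSlice,
    SegmentationSet,
)

# Height of the (virtual) coil plane below the inferior image edge.  The
# additive gradient model is a*(height + GRADIENT_ORIGIN_OFFSET_MM)^b, which
# keeps the power law finite everywhere in the image.
GRADIENT_ORIGIN_OFFSET_MM = 50.0

# Geometry anchors, all in mm so that generation is pixel-spacing invariant.
_PEAK_HEIGHT_MM = 54.0  # IT peak height above the inferior image edge
_PEAK_AP_MM = 70.0  # IT peak anterior-posterior position
_BONE_MAX_HALFWIDTH_MM = 30.0
_BONE_HEIGHT_MM = 45.0  # superior clipping of the bone wedge above the peak
_GLUTEUS_CENTER_UP_MM = 30.0
_GLUTEUS_CENTER_POST_MM = 55.0
_GLUTEUS_SEMI_VERT_MM = 18.0
_GLUTEUS_SEMI_AP_MM = 30.0
_SUBQF_ANT_EXTENT_MM = 50.0  # fat apron extent anterior of the peak
_SUBQF_POST_EXTENT_MM = 80.0
_APRON_TOP_ABOVE_PEAK_MM = 18.0  # soft-tissue top where no bone/gluteus exists
_THICKNESS_WINDOW_MM = 50.0


@dataclass
class Covariates:
    """Per-subject characteristics joined to the imaging metrics."""

    pri_history: int = 0
    ischial_pri: int = 0
    years_wheelchair: float = 15.3
    spasms: int | None = 1
    bmi: float = 23.9
    hip_breadth_in: float | None = 1.4


@dataclass
class SubjectParams:
    """Generative parameters for one synthetic subject.

    ``subqf_contrast`` is the target standardized darkening of adipose under
    the ischium relative to surrounding adipose (the noiseless image measures
    exactly this value).  ``imat_fraction`` is the fraction of gluteus voxels
    replaced by adipose-like intensities.  ``base_intensities`` are mean
    intensities per compartment in arbitrary scanner units; ``posterior_fat``
    is the reference adipose depot posterior/inferior to the gluteus, which
    in T1 scans of this region is darker than the surrounding subcutaneous
    layer.
    """

    subqf_contrast: float = 0.40
    imat_fraction: float = 0.15
    tissue_thickness_mm: float = 14.8
    it_radius_mm: float = 83.7
    base_intensities: dict = field(
        default_factory=lambda: {
            "fat": 2022.0,
            "posterior_fat": 1517.0,
            "muscle": 1324.0,
            "bone": 400.0,
            "background": 80.0,
        }
    )
    texture_sd: float = 150.0  # within-tissue intensity spread (not noise)
    noise_sd: float = 50.0
    gradient: tuple[float, float] = (3000.0, -0.5)
    covariates: Covariates = field(default_factory=Covariates)
    seed: int = 0
    shape: tuple[int, int] = (160, 170)
    spacing_mm: tuple[float, float] = (1.0, 1.0)

    def validate(self) -> None:
        if not 0.0 <= self.imat_fraction <= 1.0:
            raise ParameterError("imat_fraction must lie in [0, 1]")
        if self.tissue_thickness_mm <= 0:
            raise ParameterError("tissue_thickness_mm must be positive")
        if self.it_radius_mm <= 0:
            raise ParameterError("it_radius_mm must be positive")
        if self.noise_sd < 0 or self.texture_sd < 0:
            raise ParameterError("noise/texture SDs must be non-negative")
        b = self.base_intensities
        if not (b["fat"] > b["muscle"] > b["bone"]):
            raise ParameterError(
                "compartment intensities must be ordered fat > muscle > bone"
            )


@dataclass
class GroundTruth:
    """Exact record of how one subject was generated."""

    params: SubjectParams
    landmark: ITLandmark
    masks: dict  # name -> boolean array (bone, gluteus, subqf)
    regions: dict  # name -> (n, 2) int coord arrays for analysis regions
    gradient_field: np.ndarray
    pre_gradient_image: np.ndarray
    achieved: dict  # measured-on-truth values: subqf_effect, thickness, radius


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

def gradient_field(
    shape: tuple[int, int],
    spacing_mm: tuple[float, float],
    gradient: tuple[float, float],
    origin_offset_mm: float = GRADIENT_ORIGIN_OFFSET_MM,
) -> np.ndarray:
    """Additive coil-falloff field a*(height + y0)^b evaluated per pixel."""
    a, b = gradient
    n_rows = shape[0]
    heights = (n_rows - 1 - np.arange(n_rows)) * spacing_mm[0]
    profile = a * (heights + origin_offset_mm) ** b
    return np.repeat(profile[:, None], shape[1], axis=1)


def generate_phantom_scan(
    gradient: tuple[float, float] = (3000.0, -0.5),
    base_intensity: float = 1800.0,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (280, 280),
    spacing_mm: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
) -> tuple[SagittalSlice, np.ndarray]:
    """Scan of a homogeneous fluid-filled ball on the receiver coil.

    Returns the slice and the circular boolean mask of the homogeneous
    region.  In-mask intensity is ``base_intensity`` plus the vertical
    power-law falloff plus optional Gaussian noise; outside the ball the
    image is dark background.
    """
    if base_intensity <= 0:
        raise ParameterError("base_intensity must be positive")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows, cols = np.indices(shape)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    ry = (rows - cy) * spacing_mm[0]
    rx = (cols - cx) * spacing_mm[1]
    radius_mm = 0.42 * min(shape[0] * spacing_mm[0], shape[1] * spacing_mm[1])
    mask = ry**2 + rx**2 <= radius_mm**2
    field2d = gradient_field(shape, spacing_mm, gradient)
    data = np.zeros(shape, dtype=float)
    data[mask] = base_intensity + field2d[mask]
    if np.any(data[mask] <= 0):
        raise ParameterError(
            "gradient amplitude drives in-mask intensity non-positive"
        )
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=shape)
    return SagittalSlice(data, spacing_mm), mask


# ---------------------------------------------------------------------------
# Single subject
# ---------------------------------------------------------------------------

def _bone_mask(params: SubjectParams) -> np.ndarray:
    """Bone wedge: disk of the IT-contour radius, clipped in AP and height."""
    n_rows, n_cols = params.shape
    sp_r, sp_c = params.spacing_mm
    peak_row = n_rows - 1 - int(round(_PEAK_HEIGHT_MM / sp_r))
    peak_col = int(round(_PEAK_AP_MM / sp_c))
    r = params.it_radius_mm
    halfwidth = min(_BONE_MAX_HALFWIDTH_MM, 0.8 * r)
    rows, cols = np.indices(params.shape)
    dy = (rows - (peak_row - r / sp_r)) * sp_r
    dx = (cols - peak_col) * sp_c
    mask = (dy**2 + dx**2 <= r**2) & (np.abs(dx) <= halfwidth)
    mask &= (peak_row - rows) * sp_r <= _BONE_HEIGHT_MM
    mask &= rows <= peak_row
    return mask


def _gluteus_mask(params: SubjectParams, bone: np.ndarray) -> np.ndarray:
    n_rows, n_cols = params.shape
    sp_r, sp_c = params.spacing_mm
    peak_row = n_rows - 1 - int(round(_PEAK_HEIGHT_MM / sp_r))
    peak_col = int(round(_PEAK_AP_MM / sp_c))
    rows, cols = np.indices(params.shape)
    dy = (rows - (peak_row - _GLUTEUS_CENTER_UP_MM / sp_r)) * sp_r
    dx = (cols - (peak_col + _GLUTEUS_CENTER_POST_MM / sp_c)) * sp_c
    mask = (dy / _GLUTEUS_SEMI_VERT_MM) ** 2 + (dx / _GLUTEUS_SEMI_AP_MM) ** 2 <= 1.0
    return mask & ~bone


def _peak_from_mask(mask: np.ndarray) -> tuple[int, int]:
    """Most inferior bone pixel; AP centroid of ties, rounded anteriorly."""
    rows, cols = np.nonzero(mask)
    peak_row = rows.max()
    tied = np.sort(cols[rows == peak_row])
    return int(peak_row), int(math.floor(tied.mean()))


def _soft_tissue_top(
    params: SubjectParams, bone: np.ndarray, gluteus: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column top boundary of the subcutaneous layer, and its AP extent."""
    n_rows, n_cols = params.shape
    sp_r, sp_c = params.spacing_mm
    peak_row = n_rows - 1 - int(round(_PEAK_HEIGHT_MM / sp_r))
    peak_col = int(round(_PEAK_AP_MM / sp_c))
    apron_top = peak_row - int(round(_APRON_TOP_ABOVE_PEAK_MM / sp_r))
    top = np.full(n_cols, apron_top, dtype=float)
    for c in range(n_cols):
        candidates = [apron_top]
        if bone[:, c].any():
            candidates.append(np.nonzero(bone[:, c])[0].max())
        if gluteus[:, c].any():
            candidates.append(np.nonzero(gluteus[:, c])[0].max())
        top[c] = max(candidates)
    ap = np.arange(n_cols) * sp_c
    in_extent = (ap >= _PEAK_AP_MM - _SUBQF_ANT_EXTENT_MM) & (
        ap <= _PEAK_AP_MM + _SUBQF_POST_EXTENT_MM
    )
    return top.astype(int), in_extent


def _truth_regions(
    subqf: np.ndarray,
    bone: np.ndarray,
    gluteus: np.ndarray,
    peak: tuple[int, int],
    spacing_mm: tuple[float, float],
    margin_mm: float = 5.0,
    band_mm: float = 10.0,
) -> dict:
    """Plain per-pixel enumeration of the analysis regions (ground truth)."""
    sp_r, sp_c = spacing_mm
    peak_row, peak_col = peak
    band_top = peak_row - band_mm / sp_r  # rows >= band_top are in the band
    foot_cols = [
        c
        for r, c in zip(*np.nonzero(bone))
        if r >= band_top
    ]
    if not foot_cols:
        raise GenerationError("ischium footprint empty within the band")
    foot_min = min(foot_cols) * sp_c - margin_mm
    foot_max = max(foot_cols) * sp_c + margin_mm

    glut_bottom: dict[int, int] = {}
    for r, c in zip(*np.nonzero(gluteus)):
        glut_bottom[c] = max(glut_bottom.get(c, -1), r)

    under, surrounding, ref = [], [], []
    for r, c in zip(*np.nonzero(subqf)):
        if r >= band_top:
            if foot_min <= c * sp_c <= foot_max:
                under.append((r, c))
            else:
                surrounding.append((r, c))
        if c * sp_c > peak_col * sp_c and c in glut_bottom and r > glut_bottom[c]:
            ref.append((r, c))
    out = {
        "under": np.array(under, dtype=int).reshape(-1, 2),
        "surrounding": np.array(surrounding, dtype=int).reshape(-1, 2),
        "ref_adipose": np.array(ref, dtype=int).reshape(-1, 2),
        "gluteus": np.column_stack(np.nonzero(gluteus)),
    }
    for name, arr in out.items():
        if arr.shape[0] == 0:
            raise GenerationError(f"generated geometry left region '{name}' empty")
    return out


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    return math.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
        / (na + nb - 2)
    )


def generate_subject_slice(
    params: SubjectParams,
) -> tuple[SagittalSlice, SegmentationSet, GroundTruth]:
    """Render one synthetic subject with exact ground truth.

    Compartment intensities are assigned first (with within-tissue texture),
    the under-ischium adipose band is then shifted so the noiseless
    standardized contrast equals ``params.subqf_contrast`` exactly, and the
    coil gradient and scanner noise are applied last.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_rows, n_cols = params.shape
    sp_r, sp_c = params.spacing_mm

    bone = _bone_mask(params)
    if not bone.any():
        raise GenerationError("bone mask empty for the given geometry")
    gluteus = _gluteus_mask(params, bone)
    if not gluteus.any():
        raise GenerationError("gluteus mask empty for the given geometry")
    peak = _peak_from_mask(bone)
    peak_row, peak_col = peak

    top, in_extent = _soft_tissue_top(params, bone, gluteus)

    # Flat skin line placed so the mean vertical depth from the bone contour
    # to the skin over the 50-mm measurement window equals the target.
    half_w = _THICKNESS_WINDOW_MM / 2.0
    window_cols = [
        c
        for c in range(n_cols)
        if abs((c - peak_col) * sp_c) <= half_w and bone[:, c].any()
    ]
    if not window_cols:
        raise GenerationError("no bone columns in the thickness window")
    bone_bottom = {c: np.nonzero(bone[:, c])[0].max() for c in window_cols}
    mean_bottom = float(np.mean([bone_bottom[c] for c in window_cols]))
    skin_row = int(round(mean_bottom + params.tissue_thickness_mm / sp_r))
    if skin_row >= n_rows - 1:
        raise GenerationError("tissue thickness exceeds the image extent")

    subqf = np.zeros(params.shape, dtype=bool)
    for c in range(n_cols):
        if not in_extent[c]:
            continue
        lo = top[c] + 1
        if lo <= skin_row:
            subqf[lo : skin_row + 1, c] = True
    subqf &= ~bone & ~gluteus
    if not subqf.any():
        raise GenerationError("subcutaneous layer empty for the given geometry")

    regions = _truth_regions(subqf, bone, gluteus, peak, params.spacing_mm)

    # --- compartment intensities with texture ------------------------------
    base = params.base_intensities
    data = np.full(params.shape, base["background"], dtype=float)
    data += rng.normal(0.0, 0.1 * params.texture_sd, size=params.shape)
    data[bone] = base["bone"] + rng.normal(
        0.0, 0.5 * params.texture_sd, size=int(bone.sum())
    )
    data[subqf] = base["fat"] + rng.normal(
        0.0, params.texture_sd, size=int(subqf.sum())
    )
    # the posterior/inferior reference adipose depot is darker
    ref_idx = regions["ref_adipose"]
    data[ref_idx[:, 0], ref_idx[:, 1]] = base["posterior_fat"] + rng.normal(
        0.0, params.texture_sd, size=ref_idx.shape[0]
    )
    # gluteus: muscle texture, with imat_fraction of voxels adipose-like
    g_idx = regions["gluteus"]
    n_g = g_idx.shape[0]
    g_vals = base["muscle"] + rng.normal(0.0, params.texture_sd, size=n_g)
    n_fat = int(round(params.imat_fraction * n_g))
    if n_fat > 0:
        which = rng.choice(n_g, size=n_fat, replace=False)
        g_vals[which] = base["fat"] + rng.normal(0.0, params.texture_sd, size=n_fat)
    data[g_idx[:, 0], g_idx[:, 1]] = g_vals

    # --- exact under-ischium darkening -------------------------------------
    u_idx, s_idx = regions["under"], regions["surrounding"]
    u_vals = data[u_idx[:, 0], u_idx[:, 1]]
    s_vals = data[s_idx[:, 0], s_idx[:, 1]]
    sd_pool = _pooled_sd(s_vals, u_vals)
    shift = (u_vals.mean() - s_vals.mean()) + params.subqf_contrast * sd_pool
    data[u_idx[:, 0], u_idx[:, 1]] -= shift

    pre_gradient = data.copy()
    grad = gradient_field(params.shape, params.spacing_mm, params.gradient)
    data = data + grad
    if params.noise_sd > 0:
        data = data + rng.normal(0.0, params.noise_sd, size=params.shape)

    image = SagittalSlice(data, params.spacing_mm)
    landmark = ITLandmark(
        row=peak_row,
        col=peak_col,
        height_mm=image.height_of_row(peak_row),
        ap_mm=image.ap_of_col(peak_col),
    )
    seg = SegmentationSet(
        ischium=bone,
        gluteus=gluteus,
        subqf=subqf,
        spacing_mm=params.spacing_mm,
        landmark=landmark,
    )
    achieved_thickness = float(
        np.mean([(skin_row - bone_bottom[c]) * sp_r for c in window_cols])
    )
    truth = GroundTruth(
        params=params,
        landmark=landmark,
        masks={"bone": bone, "gluteus": gluteus, "subqf": subqf},
        regions=regions,
        gradient_field=grad,
        pre_gradient_image=pre_gradient,
        achieved={
            "subqf_effect_size": params.subqf_contrast,
            "bulk_thickness_mm": achieved_thickness,
            "it_radius_mm": params.it_radius_mm,
        },
    )
    return image, seg, truth


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class GroupDistributions:
    """Per-group parameter distributions behind the cohort generator.

    Defaults for the two groups (no pressure-injury history vs. history) are
    provided as :data:`NO_PRI_GROUP` and :data:`PRI_GROUP`, calibrated to
    group means and SDs on the scale of a clinical wheelchair-user cohort.
    """

    subqf_mean: float
    subqf_sd: float
    p_full_infiltration: float
    imat_fraction_mean: float
    imat_fraction_sd: float
    thickness_mean_mm: float
    thickness_sd_mm: float
    radius_mean_mm: float
    radius_sd_mm: float
    years_mean: float
    years_sd: float
    bmi_mean: float
    bmi_sd: float
    hip_mean_in: float
    hip_sd_in: float
    p_spasms: float
    p_ischial_pri: float
    # correlation structure: fraction increases with years of wheelchair use
    # and decreases when spasms are present (leaner muscle with spasms)
    years_imat_slope: float = 0.003
    spasm_imat_shift: float = -0.04
    p_missing_spasms: float = 5 / 43
    p_missing_hip: float = 4 / 43

    def validate(self) -> None:
        for name in ("subqf_sd", "imat_fraction_sd", "thickness_sd_mm",
                     "radius_sd_mm", "years_sd", "bmi_sd", "hip_sd_in"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        for name in ("p_full_infiltration", "p_spasms", "p_ischial_pri",
                     "p_missing_spasms", "p_missing_hip"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")


NO_PRI_GROUP = GroupDistributions(
    subqf_mean=0.21, subqf_sd=0.56,
    p_full_infiltration=4 / 21,
    imat_fraction_mean=0.06, imat_fraction_sd=0.05,
    thickness_mean_mm=17.1, thickness_sd_mm=7.1,
    radius_mean_mm=93.9, radius_sd_mm=44.7,
    years_mean=10.7, years_sd=9.3,
    bmi_mean=24.5, bmi_sd=5.0,
    hip_mean_in=1.7, hip_sd_in=0.8,
    p_spasms=0.56, p_ischial_pri=0.0,
)

PRI_GROUP = GroupDistributions(
    subqf_mean=0.58, subqf_sd=0.45,
    p_full_infiltration=3 / 22,
    imat_fraction_mean=0.11, imat_fraction_sd=0.06,
    thickness_mean_mm=12.5, thickness_sd_mm=3.9,
    radius_mean_mm=73.6, radius_sd_mm=27.5,
    years_mean=19.6, years_sd=13.3,
    bmi_mean=23.3, bmi_sd=4.6,
    hip_mean_in=1.1, hip_sd_in=0.8,
    p_spasms=0.70, p_ischial_pri=12 / 22,
)


def draw_subject_params(
    dist: GroupDistributions,
    pri_history: int,
    rng: np.random.Generator,
    base: SubjectParams | None = None,
) -> SubjectParams:
    """Draw one subject's generative parameters from a group distribution."""
    dist.validate()
    base = base or SubjectParams()
    years = max(2.0, rng.normal(dist.years_mean, dist.years_sd))
    spasms: int | None = int(rng.random() < dist.p_spasms)
    if rng.random() < dist.p_missing_spasms:
        spasms = None
    hip: float | None = max(0.3, rng.normal(dist.hip_mean_in, dist.hip_sd_in))
    if rng.random() < dist.p_missing_hip:
        hip = None
    if rng.random() < dist.p_full_infiltration:
        imat = 1.0
    else:
        imat = rng.normal(dist.imat_fraction_mean, dist.imat_fraction_sd)
        imat += dist.years_imat_slope * (years - dist.years_mean)
        if spasms:
            imat += dist.spasm_imat_shift
        imat = float(np.clip(imat, 0.0, 0.45))
    cov = Covariates(
        pri_history=int(pri_history),
        ischial_pri=int(pri_history and rng.random() < dist.p_ischial_pri),
        years_wheelchair=float(years),
        spasms=spasms,
        bmi=float(max(14.0, rng.normal(dist.bmi_mean, dist.bmi_sd))),
        hip_breadth_in=hip,
    )
    return replace(
        base,
        subqf_contrast=float(rng.normal(dist.subqf_mean, dist.subqf_sd)),
        imat_fraction=imat,
        tissue_thickness_mm=float(
            max(6.0, rng.normal(dist.thickness_mean_mm, dist.thickness_sd_mm))
        ),
        it_radius_mm=float(
            np.clip(rng.normal(dist.radius_mean_mm, dist.radius_sd_mm), 36.0, 140.0)
        ),
        covariates=cov,
        seed=int(rng.integers(2**31)),
    )


def draw_cohort_params(
    n_no_pri: int = 21,
    n_pri: int = 22,
    group_params: tuple[GroupDistributions, GroupDistributions] | None = None,
    seed: int = 0,
) -> list[SubjectParams]:
    """Draw a whole cohort's parameters (no image rendering)."""
    if n_no_pri < 2 or n_pri < 2:
        raise ParameterError("each group needs at least 2 subjects")
    no_dist, pri_dist = group_params or (NO_PRI_GROUP, PRI_GROUP)
    rng = np.random.default_rng(seed)
    params = [
        draw_subject_params(no_dist, 0, rng) for _ in range(n_no_pri)
    ] + [
        draw_subject_params(pri_dist, 1, rng) for _ in range(n_pri)
    ]
    return params


def cohort_truth_table(params: list[SubjectParams]) -> pd.DataFrame:
    """True per-subject parameter/covariate table for a drawn cohort."""
    rows = []
    for i, p in enumerate(params):
        c = p.covariates
        rows.append(
            {
                "subject_id": f"S{i:03d}",
                "pri_history": c.pri_history,
                "ischial_pri": c.ischial_pri,
                "spasms": c.spasms,
                "years_wheelchair": c.years_wheelchair,
                "bmi": c.bmi,
                "hip_breadth_in": c.hip_breadth_in,
                "true_subqf_contrast": p.subqf_contrast,
                "true_imat_fraction": p.imat_fraction,
                "true_thickness_mm": p.tissue_thickness_mm,
                "true_it_radius_mm": p.it_radius_mm,
                "seed": p.seed,
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(
    n_no_pri: int = 21,
    n_pri: int = 22,
    group_params: tuple[GroupDistributions, GroupDistributions] | None = None,
    seed: int = 0,
) -> tuple[list[tuple[SagittalSlice, SegmentationSet, GroundTruth]], pd.DataFrame]:
    """Generate a full cohort of rendered subjects plus its truth table."""
    params = draw_cohort_params(n_no_pri, n_pri, group_params, seed)
    subjects = [generate_subject_slice(p) for p in params]
    return subjects, cohort_truth_table(params)
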