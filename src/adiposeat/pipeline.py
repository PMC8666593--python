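"""End-to-end orchestration: phantom fit -> correction -> ROIs -> metrics -> stats.

A :class:`PipelineConfig` describes either a synthetic cohort (group sizes
and a seed) or real inputs (paths to scans, label volumes, landmarks, the
phantom and a covariates table).  ``run_subject`` turns one slice into one
metrics row; ``run_cohort`` runs every subject and then the full statistics
battery.  Outputs are plain CSV; intermediate artifacts (normalization
curve, per-region pixel lists) can be persisted for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as adio
from .coil import NormalizationCurve, correct_slice, fit_normalization_curve
from .core import AdiposeatError, ParameterError, SagittalSlice, SegmentationSet
from .metrics import (
    bulk_tissue_thickness,
    compute_adipose_metrics,
    midpoint_imat_fraction,
    sagittal_radius_of_curvature,
)
from .roi import (
    extract_imat_regions,
    extract_subqf_regions,
    find_it_peak,
    inferior_bone_contour,
)
from . import synthetic

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "subqf_effect_size", "imat_effect_size",
    "bulk_thickness_mm", "sagittal_radius_mm",
]


class StageError(AdiposeatError):
    """An error in a named pipeline stage for a named subject."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause
        super().__init__(f"[{stage}] subject {subject_id}: {cause}")


@dataclass
class PipelineConfig:
    """Everything needed for one run; exactly one input mode must be set."""

    # synthetic mode
    n_no_pri: int | None = None
    n_pri: int | None = None
    group_params: tuple | None = None
    # real-input mode: list of dicts with scan/labels/(landmark) paths
    subjects: list | None = None
    phantom_path: str | None = None
    phantom_mask_path: str | None = None
    covariates_path: str | None = None
    # shared
    correction: bool = True
    margin_mm: float = 5.0
    band_mm: float = 10.0
    window_mm: float = 50.0
    mirror_ap: bool = False  # left-side scans can be AP-mirrored to match
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        synth = self.n_no_pri is not None and self.n_pri is not None
        real = self.subjects is not None
        if synth == real:
            raise ParameterError(
                "exactly one of synthetic group sizes or real subject inputs "
                "must be specified"
            )
        if min(self.margin_mm, self.band_mm, self.window_mm) <= 0:
            raise ParameterError("all margins must be strictly positive")
        self.synthetic_mode = synth


def _mirror(image: SagittalSlice, seg: SegmentationSet):
    data = image.data[:, ::-1].copy()
    return (
        SagittalSlice(data, image.spacing_mm),
        SegmentationSet(
            ischium=seg.ischium[:, ::-1].copy(),
            gluteus=seg.gluteus[:, ::-1].copy(),
            subqf=seg.subqf[:, ::-1].copy(),
            spacing_mm=seg.spacing_mm,
        ),
    )


def run_subject(
    image: SagittalSlice,
    seg: SegmentationSet,
    curve: NormalizationCurve | None = None,
    margin_mm: float = 5.0,
    band_mm: float = 10.0,
    window_mm: float = 50.0,
    subject_id: str = "S000",
) -> dict:
    """One subject through correction, ROI extraction and all metrics.

    Returns a flat dict (one CSV row).  Any stage failure is re-raised as a
    :class:`StageError` carrying the stage name and subject id.
    """

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - tagged and re-raised
            raise StageError(name, subject_id, exc) from exc

    if curve is not None:
        corrected = _stage("correction", lambda: correct_slice(image, curve))
    else:
        corrected = image
    landmark = seg.landmark or _stage(
        "landmark", lambda: find_it_peak(seg.ischium, seg.spacing_mm)
    )
    under, surrounding = _stage(
        "subqf_rois",
        lambda: extract_subqf_regions(
            corrected, seg, landmark, margin_mm=margin_mm, band_mm=band_mm
        ),
    )
    ref, gluteus = _stage(
        "imat_rois", lambda: extract_imat_regions(corrected, seg, landmark)
    )
    adip = _stage(
        "adipose_metrics",
        lambda: compute_adipose_metrics(under, surrounding, ref, gluteus),
    )
    midpoint = _stage(
        "midpoint_comparator", lambda: midpoint_imat_fraction(ref, gluteus)
    )
    thickness = _stage(
        "thickness",
        lambda: bulk_tissue_thickness(seg, landmark, window_mm=window_mm),
    )
    curvature = _stage(
        "curvature",
        lambda: sagittal_radius_of_curvature(
            inferior_bone_contour(seg), landmark, window_mm=window_mm
        ),
    )
    row = {"subject_id": subject_id}
    row.update(adip.to_row())
    row.update(
        {
            "midpoint_imat_fraction": midpoint.fraction,
            "midpoint_degenerate": midpoint.degenerate,
            "bulk_thickness_mm": thickness,
            "sagittal_radius_mm": curvature.radius_mm,
            "curvature_degenerate": curvature.degenerate,
            "landmark_row": landmark.row,
            "landmark_col": landmark.col,
        }
    )
    return row


def run_cohort(
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[dict]]:
    """Whole-cohort run: metrics table, statistics, summary, failure manifest."""
    from . import stats as cohort_stats

    if config.synthetic_mode:
        subjects, truth = synthetic.generate_cohort(
            config.n_no_pri, config.n_pri, config.group_params, config.seed
        )
        curve = None
        if config.correction:
            gradient = subjects[0][2].params.gradient
            phantom, mask = synthetic.generate_phantom_scan(
                gradient=gradient, seed=config.seed
            )
            curve = fit_normalization_curve(phantom, mask)
        inputs = [
            (str(truth.loc[i, "subject_id"]), img, seg)
            for i, (img, seg, _) in enumerate(subjects)
        ]
        covariates = truth
    else:
        curve = None
        if config.correction:
            if not (config.phantom_path and config.phantom_mask_path):
                raise ParameterError(
                    "correction requested but no phantom scan/mask given"
                )
            phantom = adio.read_slice(config.phantom_path)
            mask = adio.read_slice(config.phantom_mask_path).data > 0
            curve = fit_normalization_curve(phantom, mask)
        inputs = []
        for entry in config.subjects:
            img = adio.read_slice(entry["scan"])
            landmark = (
                adio.read_landmark(entry["landmark"])
                if "landmark" in entry
                else None
            )
            seg = adio.read_labels(entry["labels"], landmark=landmark)
            if config.mirror_ap:
                img, seg = _mirror(img, seg)
            inputs.append((entry["subject_id"], img, seg))
        covariates = (
            pd.read_csv(config.covariates_path)
            if config.covariates_path
            else pd.DataFrame({"subject_id": [sid for sid, _, _ in inputs]})
        )

    rows, failures = [], []
    for sid, img, seg in inputs:
        try:
            rows.append(
                run_subject(
                    img,
                    seg,
                    curve=curve,
                    margin_mm=config.margin_mm,
                    band_mm=config.band_mm,
                    window_mm=config.window_mm,
                    subject_id=sid,
                )
            )
        except StageError as exc:
            logger.warning("skipping subject: %s", exc)
            failures.append(
                {"subject_id": exc.subject_id, "stage": exc.stage,
                 "error": str(exc.cause)}
            )
    if not rows:
        raise ParameterError("no subject produced metrics (empty cohort?)")

    metrics_df = pd.DataFrame(rows).merge(covariates, on="subject_id", how="left")
    stats_df = cohort_stats.standard_battery(metrics_df)
    summary_df = cohort_stats.cohort_summary(metrics_df)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics_df.to_csv(out / "metrics.csv", index=False)
        stats_df.to_csv(out / "stats.csv", index=False)
        summary_df.to_csv(out / "summary.csv", index=False)
        if curve is not None:
            adio.write_curve(out / "normalization_curve.json", curve)
        if failures:
            pd.DataFrame(failures).to_csv(out / "failures.csv", index=False)
    return metrics_df, stats_df, summary_df, failures
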