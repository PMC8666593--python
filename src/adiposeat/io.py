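"""Reading and writing the pipeline's on-disk formats.

Images travel as NIfTI (intensity slice, and one integer label volume with
codes 1 = bone, 2 = gluteus, 3 = SubQF+skin); DICOM is accepted on input.
Landmarks and normalization curves are JSON, tables CSV, configs YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .coil import NormalizationCurve
from .core import ITLandmark, ParameterError, SagittalSlice, SegmentationSet

LABEL_CODES = {"ischium": 1, "gluteus": 2, "subqf": 3}


def write_slice(path: str | Path, image: SagittalSlice) -> None:
    affine = np.diag([image.spacing_mm[0], image.spacing_mm[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(image.data[:, :, None], affine), str(path))


def read_slice(path: str | Path) -> SagittalSlice:
    """Load a sagittal slice from NIfTI or DICOM."""
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        import pydicom

        ds = pydicom.dcmread(str(path))
        data = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
        return SagittalSlice(
            data * slope + intercept, (float(spacing[0]), float(spacing[1]))
        )
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ParameterError("expected a single-slice volume")
        data = data[:, :, 0]
    zooms = img.header.get_zooms()
    return SagittalSlice(data, (float(zooms[0]), float(zooms[1])))


def write_labels(path: str | Path, seg: SegmentationSet) -> None:
    affine = np.diag([seg.spacing_mm[0], seg.spacing_mm[1], 1.0, 1.0])
    nib.save(
        nib.Nifti1Image(
            seg.label_volume()[:, :, None].astype(np.int16), affine
        ),
        str(path),
    )


def read_labels(
    path: str | Path, landmark: ITLandmark | None = None
) -> SegmentationSet:
    img = nib.load(str(path))
    lab = np.asarray(img.dataobj)
    if lab.ndim == 3:
        lab = lab[:, :, 0]
    zooms = img.header.get_zooms()
    return SegmentationSet(
        ischium=lab == LABEL_CODES["ischium"],
        gluteus=lab == LABEL_CODES["gluteus"],
        subqf=lab == LABEL_CODES["subqf"],
        spacing_mm=(float(zooms[0]), float(zooms[1])),
        landmark=landmark,
    )


def write_landmark(path: str | Path, landmark: ITLandmark) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "row": landmark.row,
                "col": landmark.col,
                "height_mm": landmark.height_mm,
                "ap_mm": landmark.ap_mm,
            },
            indent=2,
        )
    )


def read_landmark(path: str | Path) -> ITLandmark:
    d = json.loads(Path(path).read_text())
    return ITLandmark(**d)


def write_curve(path: str | Path, curve: NormalizationCurve) -> None:
    Path(path).write_text(json.dumps(curve.to_dict(), indent=2))


def read_curve(path: str | Path) -> NormalizationCurve:
    return NormalizationCurve.from_dict(json.loads(Path(path).read_text()))


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParameterError("config must be a YAML mapping")
    return cfg
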