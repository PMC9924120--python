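"""DICOM series export of reconstructed dose volumes.

Slices are written as a secondary-capture-style grayscale series (16-bit
unsigned, explicit VR little endian) — the simplest widely readable
encoding for derived image data.  Physical dose is carried by the standard
rescale tags:

    dose_mGy = stored_value * RescaleSlope + RescaleIntercept

with ``RescaleIntercept = -RescaleSlope`` so that stored value 0 is
reserved as the "no measurement" sentinel for points outside the phantom
disk (NaN in the working volume).  A dose ``d`` is stored as
``round(d / slope) + 1``; the default slope of 0.01 mGy quantises dose to
0.01 mGy and represents up to ~655 mGy.  A sidecar JSON documents the
convention next to the series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .reconstruct3d import DoseVolume

__all__ = ["ExportSettings", "write_dicom_series", "read_dicom_series"]

_SENTINEL = 0  # stored value reserved for "outside the phantom"


@dataclass
class ExportSettings:
    """How to quantise and label the exported series.

    ``rescale_slope_mGy`` is both the rescale slope and the dose
    quantisation step (default 0.01 mGy).
    """

    rescale_slope_mGy: float = 0.01
    series_description: str = "filmdose3d reconstructed dose"
    patient_id: str = "PHANTOM"

    def __post_init__(self) -> None:
        if self.rescale_slope_mGy <= 0:
            raise ValueError("rescale slope must be positive")


def _deterministic_uid(*parts) -> str:
    return generate_uid(entropy_srcs=[str(p) for p in parts])


def write_dicom_series(
    volume: DoseVolume,
    settings: ExportSettings,
    out_dir: str | Path,
) -> list[Path]:
    """Write one DICOM file per axial slice; returns the file paths.

    Slice positions along the phantom axis are encoded in
    ``ImagePositionPatient``/``SliceLocation`` from the volume's origin and
    inter-slice spacing; instance numbers follow slice order.  UIDs are
    derived deterministically from the volume content and settings so that
    identical inputs produce identical series.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slope = settings.rescale_slope_mGy

    finite = volume.slices[np.isfinite(volume.slices)]
    if finite.size and finite.min() < 0:
        raise ValueError("dose volume contains negative values")
    max_dose = float(finite.max()) if finite.size else 0.0
    if round(max_dose / slope) + 1 > 65535:
        raise ValueError(
            f"maximum dose {max_dose:.1f} mGy does not fit 16 bits at slope "
            f"{slope} mGy; increase rescale_slope_mGy to at least "
            f"{max_dose / 65534:.4g}"
        )

    content_key = (
        volume.n_slices,
        volume.in_plane_spacing_mm,
        volume.inter_slice_spacing_mm,
        float(np.nansum(volume.slices)),
        settings.series_description,
    )
    series_uid = _deterministic_uid("series", *content_key)
    study_uid = _deterministic_uid("study", *content_key)
    positions = volume.slice_positions_mm

    paths: list[Path] = []
    for i in range(volume.n_slices):
        plane = volume.slices[i]
        stored = np.where(
            np.isfinite(plane),
            np.clip(np.rint(np.nan_to_num(plane) / slope), 0, 65534) + 1,
            _SENTINEL,
        ).astype(np.uint16)

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = _deterministic_uid(series_uid, i)
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "OT"
        ds.ConversionType = "WSD"
        ds.SeriesDescription = settings.series_description
        ds.PatientName = settings.patient_id
        ds.PatientID = settings.patient_id
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(positions[i])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceLocation = float(positions[i])
        ds.PixelSpacing = [volume.in_plane_spacing_mm, volume.in_plane_spacing_mm]
        ds.SliceThickness = volume.inter_slice_spacing_mm
        ds.SpacingBetweenSlices = volume.inter_slice_spacing_mm
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = stored.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = f"{slope:.10g}"
        ds.RescaleIntercept = f"{-slope:.10g}"
        ds.RescaleType = "mGy"
        ds.PixelData = stored.tobytes()

        path = out_dir / f"slice_{i + 1:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)

    sidecar = {
        "series_instance_uid": str(series_uid),
        "rescale_slope_mGy": slope,
        "rescale_intercept_mGy": -slope,
        "stored_value_0": "outside phantom (no measurement), read back as NaN",
        "units": "mGy",
    }
    (out_dir / "series.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return paths


def read_dicom_series(series_dir: str | Path) -> DoseVolume:
    """Read back a dose series written by :func:`write_dicom_series`.

    Slices are ordered by instance number regardless of filename order; the
    directory must contain exactly one series with uniform slice spacing.
    Stored value 0 is restored as NaN (outside the phantom).
    """
    series_dir = Path(series_dir)
    files = sorted(series_dir.glob("*.dcm"))
    if not files:
        raise ValueError(f"no DICOM files found in {series_dir}")
    datasets = [pydicom.dcmread(f) for f in files]

    series_uids = sorted({str(ds.SeriesInstanceUID) for ds in datasets})
    if len(series_uids) > 1:
        raise ValueError(
            "directory contains more than one series: " + ", ".join(series_uids)
        )
    datasets.sort(key=lambda ds: int(ds.InstanceNumber))

    positions = np.array([float(ds.SliceLocation) for ds in datasets])
    if len(positions) > 1:
        steps = np.diff(positions)
        if np.any(np.abs(steps - steps[0]) > 1e-6):
            raise ValueError(f"non-uniform slice spacing: steps {steps}")
        spacing = float(steps[0])
    else:
        spacing = float(datasets[0].SpacingBetweenSlices)

    planes = []
    for ds in datasets:
        slope = float(ds.RescaleSlope)
        intercept = float(ds.RescaleIntercept)
        stored = ds.pixel_array.astype(float)
        dose = stored * slope + intercept
        dose[stored == _SENTINEL] = np.nan
        planes.append(dose)

    ps = datasets[0].PixelSpacing
    return DoseVolume(
        slices=np.stack(planes),
        in_plane_spacing_mm=float(ps[0]),
        inter_slice_spacing_mm=spacing,
        long_axis_origin_mm=positions[0],
    )
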