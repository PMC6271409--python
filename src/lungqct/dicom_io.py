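"""DICOM series and cohort-table IO.

Reading converts stored pixel values to calibrated Hounsfield units via the
per-slice rescale slope and intercept, sorts slices by spatial position
along the slice normal (file names and instance numbers are unreliable
across vendors), and clamps anything below -1024 HU to -1024: values below
air are scanner padding and would otherwise leak into the analysis band.

The resulting :class:`CTVolume` stores ``voxels[z, y, x]`` with slice 0 at
the most negative position along the normal, and ``spacing = (dz, dy, dx)``
in millimetres.

Only axial single-frame CT image storage is supported; enhanced
multi-frame objects are rejected with a clear message.  Writing exists so
synthetic phantoms can exercise the full reader path and round-trip within
the +/-0.5 HU integer-storage quantization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian

from .records import REQUIRED_COLUMNS, PatientRecord, frame_to_records, records_to_frame

HU_FLOOR = -1024.0
HU_CEIL = 3200.0
#: tolerance on slice-gap uniformity, as a fraction of the median gap
SLICE_GAP_TOLERANCE = 0.10

# deterministic-UID root (test/fixture use only, never uploaded anywhere)
_UID_ROOT = "1.2.826.0.1.3680043.10.1457."


@dataclass
class CTVolume:
    """A calibrated CT attenuation volume.

    Attributes
    ----------
    voxels : float array, shape (nz, ny, nx)
        Attenuation in HU; slice index 0 is the most negative position
        along the slice normal.
    spacing : (dz, dy, dx)
        Voxel spacing in mm, all strictly positive.
    patient_id : str
        Opaque identifier.
    acquisition_date : str or None
        ISO date when present in the source.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str = "anonymous"
    acquisition_date: Optional[str] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.voxels.size and (self.voxels.min() < HU_FLOOR - 1e-9
                                 or self.voxels.max() > HU_CEIL + 1e-9):
            raise ValueError(
                f"attenuation outside plausible CT range [{HU_FLOOR}, {HU_CEIL}]: "
                f"[{self.voxels.min():.1f}, {self.voxels.max():.1f}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx / 1000.0


def _slice_position(ds: Dataset) -> float:
    """Signed position of a slice along its normal (mm)."""
    orient = getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])
    row = np.array(orient[:3], dtype=float)
    col = np.array(orient[3:], dtype=float)
    normal = np.cross(row, col)
    pos = np.array(getattr(ds, "ImagePositionPatient", [0, 0, 0]), dtype=float)
    return float(np.dot(normal, pos))


def load_dicom_series(directory) -> CTVolume:
    """Read a single-frame CT series from a directory into HU.

    Raises
    ------
    ValueError
        If the directory holds no DICOM slices, mixes series identifiers,
        lacks rescale attributes, contains multi-frame objects, or the
        slice gaps deviate from uniform by more than 10%.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ValueError(f"not a directory: {directory}")
    slices = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue  # non-DICOM bystander files are ignored
        slices.append((path, ds))
    if not slices:
        raise ValueError(f"no readable DICOM slices in {directory}")

    series_uids = {str(getattr(ds, "SeriesInstanceUID", "<missing>")) for _, ds in slices}
    if len(series_uids) > 1:
        raise ValueError(
            f"directory mixes series identifiers: {sorted(series_uids)}"
        )
    for path, ds in slices:
        if int(getattr(ds, "NumberOfFrames", 1)) > 1:
            raise ValueError(
                f"{path.name}: enhanced multi-frame DICOM is not supported; "
                "export the series as single-frame CT image storage"
            )
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(f"{path.name}: missing RescaleSlope/RescaleIntercept")

    slices.sort(key=lambda item: _slice_position(item[1]))
    positions = [_slice_position(ds) for _, ds in slices]

    if len(slices) > 1:
        gaps = np.diff(positions)
        if np.any(gaps <= 0):
            dupes = [f"{positions[i]:.3f}" for i in np.nonzero(gaps <= 0)[0]]
            raise ValueError(f"duplicate or non-increasing slice positions near {dupes}")
        median_gap = float(np.median(gaps))
        bad = np.nonzero(np.abs(gaps - median_gap) > SLICE_GAP_TOLERANCE * median_gap)[0]
        if bad.size:
            where = [f"{positions[i]:.2f}->{positions[i + 1]:.2f} mm" for i in bad]
            raise ValueError(
                f"non-uniform slice spacing (median {median_gap:.3f} mm), gaps at: {where}"
            )
        dz = median_gap
    else:
        dz = float(getattr(slices[0][1], "SliceThickness", 1.0))

    planes = []
    for _, ds in slices:
        slope = float(ds.RescaleSlope)
        intercept = float(ds.RescaleIntercept)
        hu = ds.pixel_array.astype(np.float64) * slope + intercept
        planes.append(hu)
    voxels = np.stack(planes, axis=0)
    voxels = np.clip(voxels, HU_FLOOR, HU_CEIL)

    first = slices[0][1]
    dy, dx = (float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0]))
    date = getattr(first, "AcquisitionDate", "") or getattr(first, "StudyDate", "")
    iso_date = None
    if date and len(str(date)) == 8:
        d = str(date)
        iso_date = f"{d[:4]}-{d[4:6]}-{d[6:]}"
    return CTVolume(
        voxels=voxels,
        spacing=(dz, dy, dx),
        patient_id=str(getattr(first, "PatientID", "anonymous")),
        acquisition_date=iso_date,
    )


def _deterministic_uid(seed: int, counter: int) -> str:
    return f"{_UID_ROOT}{seed % (2**31)}.{counter}"


def write_dicom_series(
    volume: CTVolume,
    directory,
    *,
    seed: Optional[int] = None,
    overwrite: bool = False,
) -> Path:
    """Write a CTVolume as one single-frame CT file per slice.

    Stored pixels are uint16 with RescaleSlope 1 and RescaleIntercept
    -1024, so ``load_dicom_series`` inverts the write up to +/-0.5 HU
    rounding.  With a ``seed``, UIDs and therefore the full byte payload
    are deterministic.

    Raises
    ------
    ValueError
        Zero-slice volume, or a non-empty target directory without
        ``overwrite=True``.
    """
    if volume.voxels.shape[0] == 0 or volume.voxels.size == 0:
        raise ValueError("refusing to write an empty volume")
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise ValueError(f"directory {directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)

    if seed is None:
        from pydicom.uid import generate_uid

        def make_uid(_counter: int) -> str:
            return generate_uid()
    else:
        def make_uid(counter: int) -> str:
            return _deterministic_uid(seed, counter)

    intercept = -1024.0
    stored = np.round(volume.voxels - intercept)
    stored = np.clip(stored, 0, 65535).astype(np.uint16)

    nz = stored.shape[0]
    dz, dy, dx = volume.spacing
    study_uid = make_uid(0)
    series_uid = make_uid(1)
    frame_uid = make_uid(2)
    date = (volume.acquisition_date or "2000-01-01").replace("-", "")
    for i in range(nz):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = make_uid(10 + i)
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.PatientID = volume.patient_id
        ds.PatientName = volume.patient_id
        ds.StudyDate = date
        ds.AcquisitionDate = date
        ds.InstanceNumber = i + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * dz]
        ds.SliceThickness = dz
        ds.PixelSpacing = [dy, dx]
        ds.Rows, ds.Columns = stored.shape[1], stored.shape[2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.RescaleType = "HU"
        ds.PixelData = stored[i].tobytes()
        ds.save_as(directory / f"slice_{i:04d}.dcm", enforce_file_format=True)
    return directory


# ---------------------------------------------------------------------------
# cohort tables (RFC-4180 CSV)
# ---------------------------------------------------------------------------

def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV into PatientRecords.

    The header must include ``patient_id``, ``followup_days`` and
    ``deceased``; index and clinical columns are optional but must use the
    documented names.  Missing cells stay missing.
    """
    import pandas as pd

    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad_time = frame["followup_days"] < 0
    if bad_time.any():
        rows = frame.loc[bad_time, "patient_id"].tolist()
        raise ValueError(f"{path}: negative followup_days for patient(s) {rows}")
    if not frame["deceased"].isin([0, 1]).all():
        bad = sorted(frame.loc[~frame["deceased"].isin([0, 1]), "deceased"].unique())
        raise ValueError(f"{path}: deceased must be 0 or 1, found {bad}")
    return frame_to_records(frame)


def write_cohort_csv(records: Sequence[PatientRecord], path) -> Path:
    """Write records as CSV; round-trips through :func:`read_cohort_csv`."""
    path = Path(path)
    frame = records_to_frame(records)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
    return path
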