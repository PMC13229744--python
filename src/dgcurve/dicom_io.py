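"""Reading and classification of DICOM-RT objects.

Converts RT Dose, RT Structure Set and RT Plan files into the in-memory
representations (:class:`DoseGrid`, :class:`ROI`, :class:`PlanInfo`) that the
rest of the package operates on.  File classification is driven purely by the
SOP Class UID, so a mixed directory of exports can be sorted without relying
on file names.

All geometry is kept in patient coordinates, in millimetres; dose is stored
internally in Gy.  The dose voxel with index ``(k, j, i)`` (slice, row,
column) has its centre at ``origin + (i*dx, j*dy, k*dz)``, matching the
DICOM RT Dose grid definition.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pydicom
from pydicom.uid import RTDoseStorage, RTPlanStorage, RTStructureSetStorage

logger = logging.getLogger(__name__)

#: Maximum spread of consecutive frame-offset differences still treated as a
#: uniformly spaced grid (mm).  Far below any clinical dose grid pitch.
SLICE_UNIFORMITY_TOL_MM = 0.01

#: Default prescription estimate as a fraction of the maximum dose
#: (corresponds to prescribing at roughly the 83% isodose level, a common
#: SRS/SABR convention).
DEFAULT_RX_FRACTION = 5.0 / 6.0


class RTFileKind(Enum):
    """Classification of an uploaded DICOM object."""

    DOSE = "DOSE"
    STRUCT = "STRUCT"
    PLAN = "PLAN"
    UNSUPPORTED = "UNSUPPORTED"


@dataclass
class DoseGrid:
    """A 3D physical dose array with its spatial calibration.

    Attributes
    ----------
    values:
        Dose in Gy, shape ``(n_slices, n_rows, n_cols)`` -> (z, y, x).
    spacing:
        ``(dx, dy, dz)`` voxel pitch in mm.
    origin:
        ``(x0, y0, z0)`` centre of voxel ``(0, 0, 0)`` in patient
        coordinates, mm.
    slice_offsets:
        Per-slice offsets along z relative to the first slice, mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    slice_offsets: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("dose array must be 3-dimensional (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing}")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        if self.slice_offsets is None:
            dz = self.spacing[2]
            self.slice_offsets = np.arange(self.values.shape[0]) * dz
        self.slice_offsets = np.asarray(self.slice_offsets, dtype=float)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def max_gy(self) -> float:
        return float(self.values.max())

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates ``(x, y, z)`` along each axis, mm."""
        nz, ny, nx = self.values.shape
        dx, dy, dz = self.spacing
        x0, y0, z0 = self.origin
        return (
            x0 + np.arange(nx) * dx,
            y0 + np.arange(ny) * dy,
            z0 + np.arange(nz) * dz,
        )


@dataclass
class Contour:
    """A single closed planar polygon in patient coordinates."""

    vertices: np.ndarray  # (n, 2) x/y in mm
    z_mm: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 3:
            raise ValueError("a contour polygon needs at least 3 vertices")


@dataclass
class ROI:
    """A named structure: a stack of planar contour polygons."""

    name: str
    contours: list[Contour] = field(default_factory=list)
    number: int | None = None
    #: set when every contour lies outside the companion dose grid
    out_of_grid: bool = False

    @property
    def planes(self) -> np.ndarray:
        """Sorted unique contour plane z coordinates, mm."""
        return np.unique([c.z_mm for c in self.contours])


class PrescriptionSource(Enum):
    PLAN_FILE = "plan_file"
    ESTIMATED = "estimated"
    USER = "user"


@dataclass(frozen=True)
class PlanInfo:
    """Prescription dose and its provenance."""

    rx_gy: float
    n_fractions: int | None = None
    source: PrescriptionSource = PrescriptionSource.ESTIMATED

    def __post_init__(self) -> None:
        if not (self.rx_gy > 0):
            raise ValueError(f"prescription dose must be positive, got {self.rx_gy}")


def _read_dataset(src) -> pydicom.Dataset:
    """Read a dataset from a path, bytes, or an already-parsed Dataset."""
    if isinstance(src, pydicom.Dataset):
        return src
    try:
        if isinstance(src, (bytes, bytearray)):
            return pydicom.dcmread(io.BytesIO(src))
        return pydicom.dcmread(src)
    except Exception as exc:  # pydicom raises InvalidDicomError and friends
        name = src if isinstance(src, (str, os.PathLike)) else "<bytes>"
        raise ValueError(f"not a readable DICOM object: {name}") from exc


def classify_rt_file(src) -> RTFileKind:
    """Classify a DICOM object by its SOP Class UID.

    Anything other than RT Dose / RT Structure Set / RT Plan storage is
    reported as :attr:`RTFileKind.UNSUPPORTED` (a batch never aborts on an
    unexpected modality; the caller logs and skips it).
    """
    ds = _read_dataset(src)
    uid = str(getattr(ds, "SOPClassUID", ""))
    if uid == RTDoseStorage:
        return RTFileKind.DOSE
    if uid == RTStructureSetStorage:
        return RTFileKind.STRUCT
    if uid == RTPlanStorage:
        return RTFileKind.PLAN
    return RTFileKind.UNSUPPORTED


def load_dose(src) -> DoseGrid:
    """Load an RT Dose object into a :class:`DoseGrid`.

    The stored integer pixel data is converted to Gy with DoseGridScaling;
    spacing comes from PixelSpacing and the GridFrameOffsetVector, whose
    consecutive differences must be uniform within
    :data:`SLICE_UNIFORMITY_TOL_MM`.
    """
    ds = _read_dataset(src)
    if classify_rt_file(ds) is not RTFileKind.DOSE:
        raise ValueError("object is not an RT Dose file")
    scaling = getattr(ds, "DoseGridScaling", None)
    if scaling is None:
        raise ValueError("RT Dose object lacks DoseGridScaling; cannot convert to Gy")

    raw = ds.pixel_array  # (frames, rows, cols)
    if raw.ndim == 2:
        raw = raw[np.newaxis]
    values = raw.astype(float) * float(scaling)

    # PixelSpacing is (row spacing, column spacing) = (dy, dx)
    dy, dx = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector], dtype=float)
    if len(offsets) != values.shape[0]:
        raise ValueError("GridFrameOffsetVector length does not match frame count")
    diffs = np.diff(offsets)
    if len(diffs) == 0:
        raise ValueError("single-frame dose grids are not supported")
    if np.any(diffs <= 0):
        raise ValueError("frame offsets must be strictly increasing")
    if diffs.max() - diffs.min() > SLICE_UNIFORMITY_TOL_MM:
        raise ValueError(
            f"non-uniform frame offsets (spread {diffs.max() - diffs.min():.4f} mm "
            f"exceeds {SLICE_UNIFORMITY_TOL_MM} mm tolerance)"
        )
    dz = float(diffs.mean())

    x0, y0, z0 = (float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(
        values=values,
        spacing=(dx, dy, dz),
        origin=(x0, y0, z0 + float(offsets[0])),
        slice_offsets=offsets,
    )


def load_structures(src, dose_grid: DoseGrid | None = None) -> list[ROI]:
    """Load all ROIs from an RT Structure Set.

    Polygons with fewer than 3 vertices are rejected with a warning.  When a
    ``dose_grid`` is supplied, ROIs whose contours all fall outside the grid
    are flagged (``out_of_grid=True``) but kept, so the caller can decide
    what to do with them.
    """
    ds = _read_dataset(src)
    if classify_rt_file(ds) is not RTFileKind.STRUCT:
        raise ValueError("object is not an RT Structure Set file")

    names: dict[int, str] = {}
    for item in getattr(ds, "StructureSetROISequence", []):
        names[int(item.ROINumber)] = str(item.ROIName)

    rois: list[ROI] = []
    for item in getattr(ds, "ROIContourSequence", []):
        number = int(item.ReferencedROINumber)
        roi = ROI(name=names.get(number, f"ROI-{number}"), number=number)
        for contour in getattr(item, "ContourSequence", []):
            data = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            if len(data) < 3:
                logger.warning(
                    "ROI %r: rejecting contour with %d vertex/vertices", roi.name, len(data)
                )
                continue
            roi.contours.append(Contour(vertices=data[:, :2], z_mm=float(data[0, 2])))
        if not roi.contours:
            logger.warning("ROI %r has no valid contours", roi.name)
        if dose_grid is not None and roi.contours:
            roi.out_of_grid = not _roi_overlaps_grid(roi, dose_grid)
            if roi.out_of_grid:
                logger.warning("ROI %r lies entirely outside the dose grid", roi.name)
        rois.append(roi)
    return rois


def _roi_overlaps_grid(roi: ROI, grid: DoseGrid) -> bool:
    xs, ys, zs = grid.axis_coordinates()
    dx, dy, dz = grid.spacing
    lo = (xs[0] - dx / 2, ys[0] - dy / 2, zs[0] - dz / 2)
    hi = (xs[-1] + dx / 2, ys[-1] + dy / 2, zs[-1] + dz / 2)
    for c in roi.contours:
        if not (lo[2] <= c.z_mm <= hi[2]):
            continue
        v = c.vertices
        if (v[:, 0].max() >= lo[0] and v[:, 0].min() <= hi[0]
                and v[:, 1].max() >= lo[1] and v[:, 1].min() <= hi[1]):
            return True
    return False


def resolve_prescription(
    plan_src=None,
    dose_grid: DoseGrid | None = None,
    user_rx_gy: float | None = None,
) -> PlanInfo:
    """Resolve the reference (prescription) dose with precedence
    user > plan file > estimated.

    Without a plan file or user override the prescription defaults to
    ``5/6 * Dmax`` of the dose grid — i.e. the dose grid maximum is taken to
    sit at roughly the 83% isodose level.
    """
    if user_rx_gy is not None:
        return PlanInfo(rx_gy=float(user_rx_gy), source=PrescriptionSource.USER)

    if plan_src is not None:
        ds = _read_dataset(plan_src)
        if classify_rt_file(ds) is not RTFileKind.PLAN:
            raise ValueError("object is not an RT Plan file")
        rx = _plan_target_dose(ds)
        if rx is not None:
            return PlanInfo(
                rx_gy=rx,
                n_fractions=_plan_fractions(ds),
                source=PrescriptionSource.PLAN_FILE,
            )
        logger.warning(
            "RT Plan lacks a target prescription entry; falling back to 5/6*Dmax estimate"
        )

    if dose_grid is None:
        raise ValueError("a dose grid is required to estimate the prescription dose")
    return PlanInfo(
        rx_gy=DEFAULT_RX_FRACTION * dose_grid.max_gy,
        source=PrescriptionSource.ESTIMATED,
    )


def _plan_target_dose(ds: pydicom.Dataset) -> float | None:
    for ref in getattr(ds, "DoseReferenceSequence", []):
        dose = getattr(ref, "TargetPrescriptionDose", None)
        if dose is not None and float(dose) > 0:
            return float(dose)
    return None


def _plan_fractions(ds: pydicom.Dataset) -> int | None:
    for fg in getattr(ds, "FractionGroupSequence", []):
        n = getattr(fg, "NumberOfFractionsPlanned", None)
        if n is not None:
            return int(n)
    return None


def patient_demographics(src) -> dict[str, str]:
    """Extract identifying header fields (echoed in reports, never computed on)."""
    ds = _read_dataset(src)
    return {
        "PatientName": str(getattr(ds, "PatientName", "")),
        "PatientID": str(getattr(ds, "PatientID", "")),
        "PatientSex": str(getattr(ds, "PatientSex", "")),
        "PatientAge": str(getattr(ds, "PatientAge", "")),
    }
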