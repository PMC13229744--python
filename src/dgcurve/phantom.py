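"""Synthetic spherical dose phantoms with closed-form isodose geometry.

The phantom is a uniform dose plateau ``d0`` inside a sphere of radius
``r0`` with a linear radial fall-off of slope ``g`` (Gy/mm) outside:

    D(r) = d0                          for r <= r0
    D(r) = max(0, d0 - g*(r - r0))     for r >  r0

Every quantity the analysis pipeline measures is then closed-form: the
isodose surface at level ``d < d0`` is a sphere of radius
``r(d) = r0 + (d0 - d)/g``, so V(d) = 4/3*pi*r(d)^3, S(d) = 4*pi*r(d)^2,
each shell's differential gradient index is the inter-sphere distance
``Dd/g``, the cumulative index at level d is ``(d0 - d)/g``, and the
gradient index obeys the cube law GI = (1 + d_f/r0)^3 with
``d_f = 0.5*d0/g`` the prescription-to-half-prescription fall-off distance.
A linear profile was chosen over inverse-square or Gaussian fall-off
precisely because it keeps all of these quantities exact.

An optional second slope below a breakpoint dose produces a piecewise-linear
profile whose gradient steepens (or relaxes) away from the target,
separating the minimum dDGI from the dDGI at the prescription.

Phantoms can be written as standards-conformant DICOM RT Dose / RT
Structure Set / RT Plan triplets; writing is fully deterministic (UIDs are
derived from the spec and seed), so identical inputs give bit-identical
files.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import (
    ExplicitVRLittleEndian,
    RTDoseStorage,
    RTPlanStorage,
    RTStructureSetStorage,
)

from .dicom_io import Contour, DoseGrid, PlanInfo, PrescriptionSource, ROI

#: private-style UID root for deterministic synthetic objects
_UID_ROOT = "1.2.826.0.1.3680043.10.1472"


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one spherical phantom.

    Attributes
    ----------
    r0_mm:
        Target (plateau) radius, mm.
    d0_gy:
        Plateau dose == prescription dose, Gy.
    g_gy_per_mm:
        Radial fall-off slope outside the target, Gy/mm.
    spacing_mm:
        Isotropic voxel pitch, mm (clinical SRS grids are ~1 mm isotropic).
    extent_mm:
        Half-width of the cubic grid; must contain the lowest analysed
        isodose sphere.
    center_mm:
        Sphere centre in patient coordinates.
    low_frac:
        Lowest analysed isodose as a fraction of d0; used to validate that
        the grid is big enough.
    g2_gy_per_mm / break_frac:
        Optional second slope taking over below ``break_frac * d0``,
        yielding a piecewise-linear radial profile.
    seed:
        Folded into the generated DICOM UIDs so distinct phantom instances
        get distinct SOP instances; the dose field itself is deterministic.
    """

    r0_mm: float = 10.0
    d0_gy: float = 13.0
    g_gy_per_mm: float = 2.0
    spacing_mm: float = 1.0
    extent_mm: float | None = None
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    low_frac: float = 0.3
    g2_gy_per_mm: float | None = None
    break_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r0_mm <= 0 or self.d0_gy <= 0 or self.g_gy_per_mm <= 0:
            raise ValueError("r0, d0 and g must all be positive")
        if not (0 < self.low_frac < 1):
            raise ValueError("low_frac must lie in (0, 1)")
        if self.extent_mm is None:
            # default: lowest analysed sphere plus a 3-voxel margin
            object.__setattr__(
                self,
                "extent_mm",
                self.isodose_radius(self.low_frac * self.d0_gy) + 3 * self.spacing_mm,
            )
        if self.isodose_radius(self.low_frac * self.d0_gy) > self.extent_mm:
            raise ValueError(
                "grid extent too small: the lowest analysed isodose sphere "
                f"(r={self.isodose_radius(self.low_frac * self.d0_gy):.1f} mm) "
                f"exceeds extent {self.extent_mm:.1f} mm"
            )

    # ---- closed forms -------------------------------------------------

    def isodose_radius(self, d_gy: float) -> float:
        """r(d): radius of the isodose sphere at level d (r0 at the plateau)."""
        if d_gy >= self.d0_gy:
            return self.r0_mm
        d_break = self.break_frac * self.d0_gy
        if self.g2_gy_per_mm is None or d_gy >= d_break:
            return self.r0_mm + (self.d0_gy - d_gy) / self.g_gy_per_mm
        r_break = self.r0_mm + (self.d0_gy - d_break) / self.g_gy_per_mm
        return r_break + (d_break - d_gy) / self.g2_gy_per_mm

    def dose_at_radius(self, r_mm: np.ndarray) -> np.ndarray:
        r = np.asarray(r_mm, dtype=float)
        dose = self.d0_gy - self.g_gy_per_mm * np.maximum(0.0, r - self.r0_mm)
        if self.g2_gy_per_mm is not None:
            d_break = self.break_frac * self.d0_gy
            r_break = self.isodose_radius(d_break)
            outer = d_break - self.g2_gy_per_mm * (r - r_break)
            dose = np.where(r > r_break, outer, dose)
        return np.maximum(dose, 0.0)

    @property
    def falloff_50_mm(self) -> float:
        """d_f: radial distance from the Rx isodose to the 50% Rx isodose."""
        return self.isodose_radius(0.5 * self.d0_gy) - self.r0_mm

    @property
    def analytic_gi(self) -> float:
        """Cube-law gradient index (1 + d_f/r0)^3."""
        return (1.0 + self.falloff_50_mm / self.r0_mm) ** 3


@dataclass
class PhantomBundle:
    """In-memory analogue of one RT Dose / Struct / Plan triplet."""

    dose: DoseGrid
    rois: list[ROI]
    plan: PlanInfo
    spec: PhantomSpec | None = None
    specs: list[PhantomSpec] = field(default_factory=list)

    @property
    def target(self) -> ROI:
        return self.rois[0]


def _radial_field(spec: PhantomSpec, grid_axes) -> np.ndarray:
    xs, ys, zs = grid_axes
    cx, cy, cz = spec.center_mm
    r = np.sqrt(
        (zs[:, None, None] - cz) ** 2
        + (ys[None, :, None] - cy) ** 2
        + (xs[None, None, :] - cx) ** 2
    )
    return spec.dose_at_radius(r)


def _sphere_roi(spec: PhantomSpec, zs: np.ndarray, n_vertices: int = 64, name: str = "Target") -> ROI:
    cx, cy, cz = spec.center_mm
    theta = 2 * np.pi * np.arange(n_vertices) / n_vertices
    roi = ROI(name=name)
    for z in zs:
        h = z - cz
        if abs(h) >= spec.r0_mm:
            continue
        radius = math.sqrt(spec.r0_mm**2 - h**2)
        verts = np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])
        roi.contours.append(Contour(vertices=verts, z_mm=float(z)))
    return roi


def _grid_offset_vox(seed: int) -> np.ndarray:
    """Seeded sub-voxel offset of the grid relative to the sphere centre.

    Clinical dose grids are never lattice-aligned with the target; an exact
    alignment is also a degenerate case for voxel counting (whole shells of
    voxel centres sit exactly on an isodose sphere).  A generic sub-voxel
    shift reproduces the realistic, well-behaved geometry.
    """
    return np.random.default_rng(seed).uniform(0.05, 0.95, 3)


def make_sphere_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build the dose grid, target ROI and plan for one spherical phantom."""
    h = spec.spacing_mm
    n = int(np.floor(spec.extent_mm / h))
    off = _grid_offset_vox(spec.seed)
    axes = [(np.arange(-n, n + 1) + off[i]) * h for i in range(3)]
    xs, ys, zs = (axes[i] + spec.center_mm[i] for i in range(3))
    dose = DoseGrid(
        values=_radial_field(spec, (xs, ys, zs)),
        spacing=(h, h, h),
        origin=(float(xs[0]), float(ys[0]), float(zs[0])),
    )
    roi = _sphere_roi(spec, zs)
    plan = PlanInfo(rx_gy=spec.d0_gy, n_fractions=1, source=PrescriptionSource.PLAN_FILE)
    return PhantomBundle(dose=dose, rois=[roi], plan=plan, spec=spec, specs=[spec])


def make_multisphere_phantom(specs: list[PhantomSpec]) -> PhantomBundle:
    """Voxelwise-maximum union of several spherical phantoms.

    Mimics multi-target geometries (several small, spatially separated
    high-dose volumes).  The closed forms stay valid only while the
    component isodose surfaces are disjoint at the lowest analysed level,
    so overlap there is an error, not a warning.
    """
    if len(specs) < 2:
        raise ValueError("a multi-sphere phantom needs at least two components")
    h = specs[0].spacing_mm
    d0 = specs[0].d0_gy
    if any(s.spacing_mm != h for s in specs):
        raise ValueError("all component spheres must share one voxel spacing")
    if any(s.d0_gy != d0 for s in specs):
        raise ValueError("all component spheres must share one prescription dose")

    for i, a in enumerate(specs):
        for b in specs[i + 1:]:
            r_a = a.isodose_radius(a.low_frac * a.d0_gy)
            r_b = b.isodose_radius(b.low_frac * b.d0_gy)
            dist = math.dist(a.center_mm, b.center_mm)
            if dist <= r_a + r_b:
                raise ValueError(
                    f"spheres at {a.center_mm} and {b.center_mm} overlap at the "
                    f"lowest analysed isodose (separation {dist:.1f} mm <= "
                    f"{r_a + r_b:.1f} mm); analytic truth would be invalid"
                )

    centers = np.array([s.center_mm for s in specs])
    margins = np.array([s.extent_mm for s in specs])
    lo = (centers - margins[:, None]).min(axis=0)
    hi = (centers + margins[:, None]).max(axis=0)
    off = _grid_offset_vox(specs[0].seed)
    axes = tuple(np.arange(lo[i] + off[i] * h, hi[i] + h / 2, h) for i in range(3))
    field_ = np.zeros((len(axes[2]), len(axes[1]), len(axes[0])))
    for s in specs:
        np.maximum(field_, _radial_field(s, axes), out=field_)
    dose = DoseGrid(
        values=field_,
        spacing=(h, h, h),
        origin=(float(axes[0][0]), float(axes[1][0]), float(axes[2][0])),
    )
    rois = [_sphere_roi(s, axes[2], name=f"Target{i+1}") for i, s in enumerate(specs)]
    plan = PlanInfo(rx_gy=d0, n_fractions=1, source=PrescriptionSource.PLAN_FILE)
    return PhantomBundle(dose=dose, rois=rois, plan=plan, specs=list(specs))


def analytic_truth(spec: PhantomSpec, levels_gy=None, delta_d_gy: float | None = None) -> dict:
    """Closed-form V(d), S(d), dDGI, cDGI, GI and CI for one sphere phantom.

    ``dDGI[d]`` is the exact inter-sphere distance for the shell
    ``[d, d + Dd]`` evaluated from the closed-form volumes and surfaces
    (which, for a linear profile, is Dd/g up to curvature terms of order
    ``(Dd/g/r)^2``).
    """
    if levels_gy is None:
        levels_gy = np.linspace(spec.low_frac * spec.d0_gy, spec.d0_gy, 8)
    levels_gy = np.asarray(sorted(levels_gy), dtype=float)
    if delta_d_gy is None and len(levels_gy) > 1:
        delta_d_gy = float(np.diff(levels_gy).mean())

    radii = np.array([spec.isodose_radius(d) for d in levels_gy])
    volume = 4.0 / 3.0 * np.pi * radii**3
    surface = 4.0 * np.pi * radii**2

    ddgi = np.full(len(levels_gy), np.nan)
    for i in range(len(levels_gy) - 1):
        ddgi[i] = (volume[i] - volume[i + 1]) / (0.5 * (surface[i] + surface[i + 1]))
    cdgi = np.array([spec.isodose_radius(d) - spec.r0_mm for d in levels_gy])

    return {
        "levels_gy": levels_gy,
        "radius_mm": radii,
        "volume_mm3": volume,
        "surface_mm2": surface,
        "ddgi_mm": ddgi,
        "cdgi_mm": cdgi,
        "gi": spec.analytic_gi,
        "ci": 1.0,  # target ROI coincides with the prescription isodose sphere
        "falloff_50_mm": spec.falloff_50_mm,
        "delta_d_gy": delta_d_gy,
    }


# ---- DICOM writing ----------------------------------------------------


def _uid(spec_key: str, kind: str) -> str:
    digest = int(hashlib.sha256(f"{spec_key}/{kind}".encode()).hexdigest(), 16)
    return f"{_UID_ROOT}.{digest % 10**30}"


def _spec_key(bundle: PhantomBundle) -> str:
    return "|".join(repr(s) for s in bundle.specs) or repr(bundle.spec)


def _base_dataset(sop_class, sop_instance, modality: str) -> pydicom.FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_instance
    ds.Modality = modality
    ds.PatientName = "Phantom^Sphere"
    ds.PatientID = "PHANTOM"
    ds.PatientSex = "O"
    ds.StudyDate = "20200101"
    ds.StudyTime = "000000"
    ds.StudyInstanceUID = _uid(sop_instance, "study")
    ds.SeriesInstanceUID = _uid(sop_instance, "series")
    ds.FrameOfReferenceUID = _uid("frame", "frame")
    return ds


def write_dicom_bundle(bundle: PhantomBundle, directory) -> dict[str, Path]:
    """Write a bundle as rtdose.dcm / rtstruct.dcm / rtplan.dcm.

    DoseGridScaling is chosen so that the quantisation step is below 0.01%
    of the prescription dose (32-bit stored values), far inside every
    tolerance used by the analysis.  All UIDs are derived by hashing the
    phantom spec, so the output is bit-identical across runs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    key = _spec_key(bundle)
    paths = {
        "dose": directory / "rtdose.dcm",
        "struct": directory / "rtstruct.dcm",
        "plan": directory / "rtplan.dcm",
    }
    _write_dose(bundle, paths["dose"], key)
    _write_struct(bundle, paths["struct"], key)
    _write_plan(bundle, paths["plan"], key)
    return paths


def _write_dose(bundle: PhantomBundle, path: Path, key: str) -> None:
    grid = bundle.dose
    ds = _base_dataset(RTDoseStorage, _uid(key, "dose"), "RTDOSE")
    nz, ny, nx = grid.values.shape
    dx, dy, dz = grid.spacing

    scaling = 1e-4  # Gy per stored unit
    stored = np.round(grid.values / scaling).astype(np.uint32)

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [f"{dy:.6f}", f"{dx:.6f}"]
    ds.ImagePositionPatient = [f"{v:.6f}" for v in grid.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [f"{k * dz:.6f}" for k in range(nz)]
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)


def _write_struct(bundle: PhantomBundle, path: Path, key: str) -> None:
    ds = _base_dataset(RTStructureSetStorage, _uid(key, "struct"), "RTSTRUCT")
    ds.StructureSetLabel = "Phantom"
    ds.StructureSetDate = "20200101"
    ds.StructureSetTime = "000000"

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for i, roi in enumerate(bundle.rois, start=1):
        ssr = Dataset()
        ssr.ROINumber = i
        ssr.ROIName = roi.name
        ssr.ReferencedFrameOfReferenceUID = ds.FrameOfReferenceUID
        ssr.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(ssr)

        rc = Dataset()
        rc.ReferencedROINumber = i
        rc.ContourSequence = []
        for c in roi.contours:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = len(c.vertices)
            data = np.column_stack(
                [c.vertices, np.full(len(c.vertices), c.z_mm)]
            ).ravel()
            item.ContourData = [f"{v:.6f}" for v in data]
            rc.ContourSequence.append(item)
        ds.ROIContourSequence.append(rc)
    ds.save_as(path, enforce_file_format=True)


def _write_plan(bundle: PhantomBundle, path: Path, key: str) -> None:
    ds = _base_dataset(RTPlanStorage, _uid(key, "plan"), "RTPLAN")
    ds.RTPlanLabel = "Phantom"
    ds.RTPlanDate = "20200101"
    ds.RTPlanTime = "000000"
    ds.RTPlanGeometry = "TREATMENT_DEVICE"

    ref = Dataset()
    ref.DoseReferenceNumber = 1
    ref.DoseReferenceStructureType = "SITE"
    ref.DoseReferenceType = "TARGET"
    ref.TargetPrescriptionDose = f"{bundle.plan.rx_gy:.6f}"
    ds.DoseReferenceSequence = [ref]

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = bundle.plan.n_fractions or 1
    ds.FractionGroupSequence = [fg]
    ds.save_as(path, enforce_file_format=True)


def jittered_spec(spec: PhantomSpec, rel_sigma: float, seed: int) -> PhantomSpec:
    """A copy of ``spec`` with r0 and g perturbed multiplicatively.

    Emulates paired re-delineation (e.g. two MR sequences of one patient)
    for reproducibility studies.
    """
    rng = np.random.default_rng(seed)
    factors = 1.0 + rel_sigma * rng.standard_normal(2)
    return replace(
        spec,
        r0_mm=spec.r0_mm * float(factors[0]),
        g_gy_per_mm=spec.g_gy_per_mm * float(factors[1]),
        extent_mm=None,
        seed=seed,
    )
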