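"""Voxel-based cumulative DVHs, DVH-derived metrics and conventional indices.

Structure masks are built by even-odd point-in-polygon testing of voxel
centres against each contour plane; the differential dose histogram over the
masked voxels is binned at 1 cGy and converted to cumulative (volume
receiving at least each dose).  On top of the curve sit the clinical
metrics: Dx by linear interpolation, Vx by interpolation on the dose axis,
mean dose by trapezoidal integration of the cumulative curve, and the
max/min surrogates D2/D98.

The conventional plan-quality indices live here too:

* Paddick conformity index  CI = (TV n PIV)^2 / (TV * PIV)
* gradient index            GI = V(50% Rx) / V(Rx)
* R50%                      = V(50% Rx) / TV
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath

from .dicom_io import ROI, DoseGrid
from .isodose import enclosed_volume, isodose_mask

logger = logging.getLogger(__name__)

DVH_BIN_CGY = 1.0  # differential histogram pitch


@dataclass
class DVHCurve:
    """Cumulative DVH of one structure.

    ``bin_edges_cgy[i]`` is a dose threshold; ``cumulative_mm3[i]`` the
    absolute volume receiving at least that dose.  The curve starts at dose
    0 with the full structure volume and is non-increasing.
    """

    structure: str
    bin_edges_cgy: np.ndarray
    cumulative_mm3: np.ndarray

    @property
    def volume_mm3(self) -> float:
        return float(self.cumulative_mm3[0])

    @property
    def cumulative_pct(self) -> np.ndarray:
        return 100.0 * self.cumulative_mm3 / self.volume_mm3


@dataclass(frozen=True)
class IndexSet:
    """Conformity / gradient indices of one plan-target pair."""

    paddick_ci: float
    gi: float
    r50: float
    tv_mm3: float
    piv_mm3: float
    v50_mm3: float


def structure_mask(dose_grid: DoseGrid, roi: ROI) -> np.ndarray:
    """Boolean voxel mask of an ROI on the dose grid.

    Voxel centres are tested against each contour plane's polygons with
    even-odd parity (XOR across polygons), so a contour nested inside
    another carves a hole.  A contour plane is matched to the nearest dose
    slice when within half the slice spacing; otherwise it is skipped.
    """
    xs, ys, zs = dose_grid.axis_coordinates()
    dz = dose_grid.spacing[2]
    nz, ny, nx = dose_grid.values.shape
    mask = np.zeros((nz, ny, nx), dtype=bool)
    if not roi.contours:
        logger.warning("ROI %r has no contours; empty mask", roi.name)
        return mask

    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)
    points = np.column_stack([gx.ravel(), gy.ravel()])

    matched_any = False
    for c in roi.contours:
        k = int(np.argmin(np.abs(zs - c.z_mm)))
        if abs(zs[k] - c.z_mm) > dz / 2 + 1e-9:
            continue
        matched_any = True
        inside = MplPath(c.vertices).contains_points(points).reshape(ny, nx)
        mask[k] ^= inside
    if not matched_any:
        logger.warning("ROI %r: no contour plane matches a dose slice", roi.name)
    return mask


def compute_dvh(dose_grid: DoseGrid, roi: ROI | np.ndarray, name: str | None = None) -> DVHCurve:
    """Cumulative DVH at 1 cGy pitch over the voxels inside a structure."""
    if isinstance(roi, ROI):
        mask = structure_mask(dose_grid, roi)
        name = name or roi.name
    else:
        mask = np.asarray(roi, dtype=bool)
        name = name or "structure"
    if not mask.any():
        raise ValueError(f"structure {name!r} covers no dose voxels; cannot build a DVH")

    doses_cgy = dose_grid.values[mask] * 100.0
    n_bins = int(np.ceil(doses_cgy.max() / DVH_BIN_CGY)) + 1
    edges = np.arange(n_bins + 1) * DVH_BIN_CGY
    diff, _ = np.histogram(doses_cgy, bins=edges)
    # cumulative_mm3[i] = volume with dose >= edges[i]
    cum_counts = np.concatenate([[mask.sum()], mask.sum() - np.cumsum(diff)])
    cumulative = cum_counts.astype(float) * dose_grid.voxel_volume_mm3
    return DVHCurve(structure=name, bin_edges_cgy=edges, cumulative_mm3=cumulative)


def dose_at_volume(dvh: DVHCurve, x_percent: float) -> float:
    """Dx: the dose (Gy) received by at least x% of the structure.

    Linear interpolation on the cumulative curve; an x outside the curve's
    support clamps to the corresponding end with a warning rather than
    extrapolating.
    """
    if not (0 < x_percent <= 100):
        raise ValueError("x_percent must lie in (0, 100]")
    pct = dvh.cumulative_pct
    edges = dvh.bin_edges_cgy
    if x_percent > pct[0]:
        logger.warning("D%g requested but curve starts at %.3f%%; clamping", x_percent, pct[0])
        return float(edges[0]) / 100.0
    # Dx is the largest dose whose coverage is still >= x: on flat stretches
    # of the cumulative curve take the upper end, otherwise interpolate
    # linearly inside the bracketing bin.
    idx = int(np.nonzero(pct >= x_percent)[0][-1])
    if idx == len(edges) - 1 or pct[idx] == x_percent:
        return float(edges[idx]) / 100.0
    d = edges[idx] + (pct[idx] - x_percent) / (pct[idx] - pct[idx + 1]) * (
        edges[idx + 1] - edges[idx]
    )
    return float(d) / 100.0


def volume_at_dose(dvh: DVHCurve, x_gy: float) -> tuple[float, float]:
    """Vx: (percent, mm^3) of the structure receiving at least ``x_gy``."""
    if x_gy < 0:
        raise ValueError("dose must be non-negative")
    x_cgy = x_gy * 100.0
    vol = float(np.interp(x_cgy, dvh.bin_edges_cgy, dvh.cumulative_mm3))
    return 100.0 * vol / dvh.volume_mm3, vol


def vx_set(dvh: DVHCurve, doses_gy=range(5, 55, 5)) -> dict[float, float]:
    """Convenience V5..V50 (%) at 5 Gy intervals."""
    return {float(d): volume_at_dose(dvh, float(d))[0] for d in doses_gy}


def summary_stats(dvh: DVHCurve) -> dict[str, float]:
    """Mean (trapezoidal over the cumulative curve), max (D2), min (D98)."""
    frac = dvh.cumulative_mm3 / dvh.volume_mm3
    mean_cgy = float(np.trapezoid(frac, dvh.bin_edges_cgy))
    return {
        "mean_gy": mean_cgy / 100.0,
        "max_gy": dose_at_volume(dvh, 2.0),
        "min_gy": dose_at_volume(dvh, 98.0),
    }


def paddick_ci(
    tv_mask: np.ndarray, piv_mask: np.ndarray, spacing: tuple[float, float, float]
) -> float:
    """Paddick conformity index (TV n PIV)^2 / (TV * PIV), in [0, 1]."""
    tv = np.asarray(tv_mask, dtype=bool)
    piv = np.asarray(piv_mask, dtype=bool)
    if tv.shape != piv.shape:
        raise ValueError("target and prescription-isodose masks must share one grid")
    v_tv = enclosed_volume(tv, spacing)
    v_piv = enclosed_volume(piv, spacing)
    if v_tv == 0 or v_piv == 0:
        raise ValueError("Paddick CI needs non-empty target and prescription isodose")
    v_ov = enclosed_volume(tv & piv, spacing)
    return v_ov**2 / (v_tv * v_piv)


def gradient_index(dose_grid: DoseGrid, rx_gy: float) -> float:
    """GI = V(50% Rx) / V(Rx); the prescription isodose is the >= Rx mask."""
    if rx_gy > dose_grid.max_gy:
        raise ValueError("prescription dose exceeds the grid maximum; empty isodose")
    v_rx = enclosed_volume(isodose_mask(dose_grid, rx_gy), dose_grid.spacing)
    if v_rx == 0:
        raise ValueError("empty prescription isodose volume")
    v_half = enclosed_volume(isodose_mask(dose_grid, 0.5 * rx_gy), dose_grid.spacing)
    return v_half / v_rx


def r50(dose_grid: DoseGrid, rx_gy: float, tv_volume_mm3: float) -> float:
    """R50% = V(50% Rx) / target volume."""
    if tv_volume_mm3 <= 0:
        raise ValueError("target volume must be positive")
    v_half = enclosed_volume(isodose_mask(dose_grid, 0.5 * rx_gy), dose_grid.spacing)
    return v_half / tv_volume_mm3


def index_set(dose_grid: DoseGrid, tv_mask: np.ndarray, rx_gy: float) -> IndexSet:
    """All conventional indices of one plan in a single pass."""
    spacing = dose_grid.spacing
    piv = isodose_mask(dose_grid, rx_gy).mask
    half = isodose_mask(dose_grid, 0.5 * rx_gy).mask
    tv_mm3 = enclosed_volume(tv_mask, spacing)
    piv_mm3 = enclosed_volume(piv, spacing)
    v50_mm3 = enclosed_volume(half, spacing)
    return IndexSet(
        paddick_ci=paddick_ci(tv_mask, piv, spacing),
        gi=v50_mm3 / piv_mm3,
        r50=v50_mm3 / tv_mm3,
        tv_mm3=tv_mm3,
        piv_mm3=piv_mm3,
        v50_mm3=v50_mm3,
    )
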