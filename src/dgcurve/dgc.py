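"""Dose-gradient-curve computation and clinical quality grading.

The differential dose gradient index for the shell between adjacent isodose
levels ``d`` and ``d + Dd`` is

    dDGI_d = [V(d) - V(d + Dd)] / (1/2 * [S(d) + S(d + Dd)])

i.e. shell volume over mean shell surface area — the average physical
distance (mm) between the two isodose surfaces.  Because raw dDGI scales
with the step, a step-normalised form dDGI_N = dDGI / Dd (mm/Gy) is carried
alongside.  The cumulative index

    cDGI_i = sum_{j=i}^{D0-Dd} dDGI_j ,   cDGI_{D0} = 0

accumulates shell distances from the reference (prescription) isodose
surface down to each level: the total physical fall-off distance.

The dDGI at the prescription dose is graded into four tiers:
Ideal (<3 mm, small-volume SRS territory), Good (3-5 mm, typical SBRT),
Acceptable (5-7 mm, larger targets / lung), Poor (>=7 mm, re-optimisation
worth considering).  The 3 mm anchor is the classical SRS benchmark of a
prescription-to-half-prescription fall-off within 3 mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .dicom_io import DoseGrid
from .isodose import (
    enclosed_volume,
    isodose_mask,
    surface_area_marching_cubes,
    surface_area_voxel,
)

logger = logging.getLogger(__name__)

#: Lower-inclusive grade boundaries in mm: [0,3) Ideal, [3,5) Good,
#: [5,7) Acceptable, [7,inf) Poor.
GRADE_BOUNDS_MM = (3.0, 5.0, 7.0)

GRADE_INTERPRETATION = {
    "Ideal": (
        "Steep dose fall-off typical of well-optimised small-volume SRS plans; "
        "the prescription-to-adjacent-isodose distance is under 3 mm."
    ),
    "Good": (
        "Dose fall-off in the range commonly observed for standard SBRT plans."
    ),
    "Acceptable": (
        "Shallower gradient consistent with larger targets or low-density "
        "tissue such as lung; review against site-specific expectations."
    ),
    "Poor": (
        "Shallow dose gradient; plan re-optimisation may be warranted to "
        "improve normal-tissue sparing."
    ),
}


class StepUnit(Enum):
    GY = "gy"
    PERCENT = "pct"


@dataclass(frozen=True)
class GradingResult:
    grade: str
    ddgi_at_rx_mm: float
    interpretation_text: str


@dataclass
class DGCResult:
    """Per-level table plus the scalar summary of one DGC analysis.

    ``table`` columns: dose_gy, rel_pct, volume_mm3, surface_mm2, ddgi_mm,
    ddgi_norm_mm_per_gy, cdgi_mm, flag.  The dDGI on a row is the shell
    anchored at that row's dose (between it and the next level up); the top
    row therefore has no dDGI.
    """

    table: pd.DataFrame
    rx_gy: float
    delta_d_gy: float
    grid_spacing_mm: tuple[float, float, float]
    surface_method: str
    ddgi_at_rx_mm: float = float("nan")
    ddgi_at_rx_fallback: bool = False
    min_ddgi_mm: float = float("nan")
    cdgi_50_mm: float = float("nan")
    grading: GradingResult | None = None
    flags: list[str] = field(default_factory=list)


def generate_dose_levels(
    rx_gy: float,
    step: float,
    step_unit: StepUnit | str = StepUnit.GY,
    low_frac: float = 0.3,
    dmax_gy: float | None = None,
) -> np.ndarray:
    """Isodose levels ``rx + k*Dd`` symmetric around the prescription.

    The levels are clipped to ``[low_frac*rx, dmax]``; the prescription dose
    is always one of them exactly.  Percentage steps convert as
    ``Dd = (step/100) * rx``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not (0 < low_frac < 1):
        raise ValueError("low_frac must lie in (0, 1)")
    unit = StepUnit(step_unit) if not isinstance(step_unit, StepUnit) else step_unit
    delta = step if unit is StepUnit.GY else (step / 100.0) * rx_gy
    lo = low_frac * rx_gy
    hi = dmax_gy if dmax_gy is not None else rx_gy
    k_min = int(np.ceil((lo - rx_gy) / delta - 1e-9))
    k_max = int(np.floor((hi - rx_gy) / delta + 1e-9))
    levels = rx_gy + np.arange(k_min, k_max + 1) * delta
    if len(levels) < 2:
        raise ValueError(
            f"step {delta:g} Gy leaves fewer than 2 levels in [{lo:g}, {hi:g}] Gy"
        )
    return levels


def ddgi(v_d: float, v_next: float, s_d: float, s_next: float) -> float:
    """Differential index for one shell: (V(d) - V(d+Dd)) / mean surface."""
    mean_s = 0.5 * (s_d + s_next)
    if mean_s <= 0:
        logger.warning("shell with zero mean surface area; dDGI undefined")
        return float("nan")
    return (v_d - v_next) / mean_s


def normalize_ddgi(ddgi_mm: float, delta_d_gy: float) -> float:
    """Step-normalised index dDGI_N = dDGI / Dd, mm/Gy."""
    if delta_d_gy <= 0:
        raise ValueError("delta_d must be positive")
    return ddgi_mm / delta_d_gy


def cdgi(ddgi_by_level: pd.Series, d0_gy: float, atol: float = 1e-9) -> pd.Series:
    """Cumulative index per level: summed shell dDGI from each level up to D0.

    ``ddgi_by_level`` maps each level's dose to the dDGI of the shell
    anchored there.  The result is exactly 0 at ``d0_gy`` and NaN above it
    (the cumulative curve is defined downward from the reference surface).
    Levels must form a contiguous ladder up to D0.
    """
    doses = np.asarray(ddgi_by_level.index, dtype=float)
    if not np.any(np.isclose(doses, d0_gy, atol=atol)):
        raise ValueError(f"level table does not contain the reference dose {d0_gy} Gy")
    order = np.argsort(doses)
    doses_sorted = doses[order]
    vals_sorted = np.asarray(ddgi_by_level.values, dtype=float)[order]
    below = doses_sorted < d0_gy - atol
    if below.any():
        steps = np.diff(doses_sorted[doses_sorted <= d0_gy + atol])
        if steps.size and (steps.max() - steps.min()) > 1e-6 * max(steps.max(), 1.0):
            raise ValueError("levels below the reference dose are not contiguous")
        if np.any(~np.isfinite(vals_sorted[below])):
            raise ValueError("dDGI missing for a shell below the reference dose")

    out = np.full_like(doses_sorted, np.nan)
    running = 0.0
    for i in range(len(doses_sorted) - 1, -1, -1):
        d = doses_sorted[i]
        if d > d0_gy + atol:
            continue
        if np.isclose(d, d0_gy, atol=atol):
            out[i] = 0.0
            running = 0.0
        else:
            running += vals_sorted[i]
            out[i] = running
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    return pd.Series(out[inverse], index=ddgi_by_level.index)


def grade(ddgi_at_rx_mm: float) -> GradingResult:
    """Four-tier quality grade of the dDGI at the prescription dose."""
    if not np.isfinite(ddgi_at_rx_mm) or ddgi_at_rx_mm < 0:
        raise ValueError(f"dDGI at Rx must be finite and non-negative, got {ddgi_at_rx_mm}")
    b1, b2, b3 = GRADE_BOUNDS_MM
    if ddgi_at_rx_mm < b1:
        name = "Ideal"
    elif ddgi_at_rx_mm < b2:
        name = "Good"
    elif ddgi_at_rx_mm < b3:
        name = "Acceptable"
    else:
        name = "Poor"
    return GradingResult(
        grade=name,
        ddgi_at_rx_mm=ddgi_at_rx_mm,
        interpretation_text=GRADE_INTERPRETATION[name],
    )


_SURFACE_FUNCS = {
    "marching_cubes": surface_area_marching_cubes,
    "voxel": surface_area_voxel,
}


def compute_dgc(
    dose_grid: DoseGrid,
    rx_gy: float,
    step: float = 1.0,
    step_unit: StepUnit | str = StepUnit.PERCENT,
    low_frac: float = 0.3,
    surface_method: str = "marching_cubes",
    voxel_correction_factor: float = 1.0,
) -> DGCResult:
    """Full dose-gradient-curve analysis of one dose grid.

    Builds the symmetric level ladder, measures V(d) and S(d) at every
    level, forms the per-shell dDGI, the step-normalised dDGI and the
    cumulative cDGI, and grades the dDGI at the prescription dose.

    Defaults: 1% step, 30% lower bound, marching-cubes surfaces — chosen so
    the prescription and 50% levels are exact grid points and the surface
    estimate is quantitatively reliable.
    """
    if surface_method not in _SURFACE_FUNCS:
        raise ValueError(f"unknown surface method {surface_method!r}")
    surf = _SURFACE_FUNCS[surface_method]
    surf_kwargs = (
        {"correction_factor": voxel_correction_factor} if surface_method == "voxel" else {}
    )

    levels = generate_dose_levels(rx_gy, step, step_unit, low_frac, dose_grid.max_gy)
    delta_d = float(np.diff(levels).mean())
    spacing = dose_grid.spacing

    flags: list[str] = []
    volumes, surfaces = [], []
    kept_levels = []
    for d in levels:
        m = isodose_mask(dose_grid, float(d))
        v = enclosed_volume(m, spacing)
        if v == 0 and d > rx_gy:
            # empty masks above the prescription terminate the ladder upward
            flags.append(f"level {d:.4g} Gy empty; table truncated")
            break
        kept_levels.append(float(d))
        volumes.append(v)
        surfaces.append(surf(m, spacing, **surf_kwargs) if v > 0 else 0.0)

    levels = np.asarray(kept_levels)
    volumes = np.asarray(volumes)
    surfaces = np.asarray(surfaces)

    ddgi_vals = np.full(len(levels), np.nan)
    for i in range(len(levels) - 1):
        ddgi_vals[i] = ddgi(volumes[i], volumes[i + 1], surfaces[i], surfaces[i + 1])

    table = pd.DataFrame(
        {
            "dose_gy": levels,
            "rel_pct": 100.0 * levels / rx_gy,
            "volume_mm3": volumes,
            "surface_mm2": surfaces,
            "ddgi_mm": ddgi_vals,
            "ddgi_norm_mm_per_gy": ddgi_vals / delta_d,
        }
    )
    table["cdgi_mm"] = cdgi(pd.Series(ddgi_vals, index=levels), rx_gy).values
    table["flag"] = ""

    rx_idx = int(np.argmin(np.abs(levels - rx_gy)))
    if not np.isclose(levels[rx_idx], rx_gy, atol=1e-9):
        raise RuntimeError("prescription level missing from generated ladder")

    # dDGI at Rx: the shell anchored at d = Rx ([Rx, Rx+Dd]); when the level
    # above Rx is unavailable (Rx at or above Dmax) fall back to the shell
    # below, [Rx-Dd, Rx], and say so.
    fallback = False
    at_rx = ddgi_vals[rx_idx] if rx_idx < len(levels) - 1 else float("nan")
    if not np.isfinite(at_rx):
        fallback = True
        at_rx = ddgi_vals[rx_idx - 1] if rx_idx >= 1 else float("nan")
        table.loc[table.index[rx_idx], "flag"] = "ddgi_at_rx from shell below Rx"
        flags.append("dDGI at Rx taken from the shell below the prescription level")

    shell_vals = ddgi_vals[:-1] if len(ddgi_vals) > 1 else ddgi_vals
    finite = shell_vals[np.isfinite(shell_vals)]
    min_ddgi = float(finite.min()) if finite.size else float("nan")

    half_rx = 0.5 * rx_gy
    cdgi_50 = float("nan")
    if levels.min() <= half_rx + 1e-9:
        idx50 = int(np.argmin(np.abs(levels - half_rx)))
        if np.isclose(levels[idx50], half_rx, rtol=0, atol=1e-6 * rx_gy):
            cdgi_50 = float(table["cdgi_mm"].iloc[idx50])
        else:
            cdgi_50 = float(
                np.interp(half_rx, levels, table["cdgi_mm"].fillna(np.nan).values)
            )

    grading = grade(float(at_rx)) if np.isfinite(at_rx) else None

    return DGCResult(
        table=table,
        rx_gy=rx_gy,
        delta_d_gy=delta_d,
        grid_spacing_mm=spacing,
        surface_method=surface_method,
        ddgi_at_rx_mm=float(at_rx),
        ddgi_at_rx_fallback=fallback,
        min_ddgi_mm=min_ddgi,
        cdgi_50_mm=cdgi_50,
        grading=grading,
        flags=flags,
    )


def ddgi_at_rx(result: DGCResult) -> float:
    return result.ddgi_at_rx_mm


def min_ddgi(result: DGCResult) -> float:
    return result.min_ddgi_mm
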