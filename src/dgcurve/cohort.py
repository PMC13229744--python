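"""Batch analysis over many cases and the accompanying statistics.

Each analysed case collapses into one :class:`CaseRecord`; over a cohort of
records the module provides Pearson/Spearman correlations with two-sided
p-values, the paired mean absolute percentage difference used for
reproducibility studies, and target-volume subgroup summaries
(mean +/- SD per band).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CaseRecord:
    """Per-case scalar metrics, one row of the cohort table."""

    case_id: str
    tv_mm3: float
    rx_gy: float
    ddgi_at_rx_mm: float
    min_ddgi_mm: float
    cdgi_50_mm: float
    paddick_ci: float
    gi: float
    r50: float
    grid_spacing_mm: float
    delta_d_gy: float
    oar_max_gy: float | None = None
    oar_mean_gy: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def records_frame(records: list[CaseRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


def correlate(x, y) -> dict[str, float]:
    """Pearson r and Spearman rho with two-sided p-values.

    Pearson p-values come from the t-distribution transform of r; Spearman
    p-values likewise use the t approximation on the rank correlation.
    Constant input is flagged (NaN correlation) rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must be paired")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs to correlate")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant series; correlation undefined")
        nan = float("nan")
        return {"pearson_r": nan, "pearson_p": nan, "spearman_rho": nan, "spearman_p": nan}
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
    }


def mapd(series_a, series_b) -> float:
    """Mean absolute percentage difference of paired measurements.

    mean_i |a_i - b_i| / ((a_i + b_i)/2) * 100 — symmetric in its arguments
    and invariant to rescaling both series by a common factor.  Pairs with
    zero mean are excluded with a warning.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must be paired")
    means = (a + b) / 2.0
    ok = means != 0
    if not ok.all():
        logger.warning("excluding %d pair(s) with zero mean", int((~ok).sum()))
    if not ok.any():
        raise ValueError("no pairs with non-zero mean")
    return float(np.mean(np.abs(a[ok] - b[ok]) / np.abs(means[ok])) * 100.0)


def subgroup_summary(
    records: pd.DataFrame | list[CaseRecord],
    volume_breaks_mm3: tuple[float, ...] = (1000.0, 3000.0),
    metrics: tuple[str, ...] = ("ddgi_at_rx_mm", "gi", "paddick_ci", "cdgi_50_mm"),
) -> pd.DataFrame:
    """Mean +/- SD of each metric within target-volume bands.

    Bands are lower-inclusive: breaks (1 cc, 3 cc) give [0, 1), [1, 3) and
    [3, inf) cc, so a 1.0 cc target lands in the middle band.  Empty bands
    are reported with n = 0 and no summary.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    breaks = list(volume_breaks_mm3)
    if sorted(breaks) != breaks or len(set(breaks)) != len(breaks):
        raise ValueError("volume breaks must be strictly increasing")
    edges = [-np.inf, *breaks, np.inf]
    labels = _band_labels(breaks)
    bands = pd.cut(df["tv_mm3"], bins=edges, right=False, labels=labels)

    rows = []
    for label in labels:
        sub = df[bands == label]
        row: dict = {"tv_band": label, "n": len(sub)}
        for m in metrics:
            if len(sub):
                row[f"{m}_mean"] = float(sub[m].mean())
                row[f"{m}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0
            else:
                row[f"{m}_mean"] = float("nan")
                row[f"{m}_sd"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _band_labels(breaks_mm3: list[float]) -> list[str]:
    cc = [b / 1000.0 for b in breaks_mm3]
    labels = [f"<{cc[0]:g} cc"]
    labels += [f"{cc[i]:g}-{cc[i+1]:g} cc" for i in range(len(cc) - 1)]
    labels.append(f">={cc[-1]:g} cc")
    return labels
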