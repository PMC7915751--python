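"""Per-subject bimodal decomposition of per-cell MitoTracker intensity.

Intensities are analysed on a log10 scale with a Gaussian kernel density
estimate; the density minimum (valley) between the two heaviest modes
splits cells into low and high subpopulations, and the fraction below the
valley is the subject's MitoTracker-low proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

__all__ = [
    "KdeCurve",
    "SubjectResult",
    "kde",
    "find_valley",
    "proportion_low",
    "subpop_pipeline",
    "MIN_CELLS",
]

MIN_CELLS = 50
GRID_POINTS = 512
MODE_HEIGHT_FRACTION = 0.05


class TooFewCellsError(ValueError):
    """Raised when a subject has fewer cells than the configured floor."""


@dataclass
class KdeCurve:
    grid: np.ndarray  # log10 intensity
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class SubjectResult:
    subject_id: int
    n_cells: int
    threshold: float | None
    prop_low: float | None
    bimodal: bool
    fallback: bool
    mode_locations: list


def kde(intensities, bandwidth: str | float = "silverman",
        min_cells: int = MIN_CELLS, grid_points: int = GRID_POINTS) -> KdeCurve:
    """Gaussian KDE of log10 intensity on a grid spanning data +- 3 bandwidths."""
    x = np.asarray(intensities, dtype=float)
    if x.size < min_cells:
        raise TooFewCellsError(
            f"{x.size} cells < floor of {min_cells}; subject flagged")
    if np.any(x <= 0):
        raise ValueError("intensities must be positive before log transform")
    logx = np.log10(x)
    est = gaussian_kde(logx, bw_method=bandwidth)
    h = float(np.sqrt(est.covariance[0, 0]))
    grid = np.linspace(logx.min() - 3 * h, logx.max() + 3 * h, grid_points)
    return KdeCurve(grid=grid, density=est(grid), bandwidth=h)


def _mode_masses(curve: KdeCurve, peaks: np.ndarray) -> np.ndarray:
    """Integrated density over each mode's basin (split at inter-peak minima)."""
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(a + 1 + int(np.argmin(curve.density[a + 1:b])))
    bounds.append(len(curve.grid) - 1)
    masses = []
    for i in range(len(peaks)):
        sl = slice(bounds[i], bounds[i + 1] + 1)
        masses.append(float(np.trapezoid(curve.density[sl], curve.grid[sl])))
    return np.asarray(masses)


def find_valley(curve: KdeCurve) -> tuple[float | None, list, bool]:
    """Locate the density minimum between the two heaviest modes.

    Modes are local maxima exceeding 5% of the global maximum.  Returns
    (threshold, mode_locations, bimodal); unimodal curves yield
    (None, modes, False).
    """
    height = MODE_HEIGHT_FRACTION * float(curve.density.max())
    peaks, _ = find_peaks(curve.density, height=height)
    modes = [float(curve.grid[p]) for p in peaks]
    if len(peaks) < 2:
        return None, modes, False
    masses = _mode_masses(curve, peaks)
    top2 = np.sort(peaks[np.argsort(masses)[-2:]])
    i1, i2 = int(top2[0]), int(top2[1])
    valley = i1 + 1 + int(np.argmin(curve.density[i1 + 1:i2]))
    return float(curve.grid[valley]), modes, True


def proportion_low(intensities, threshold: float) -> float:
    """Fraction of cells with log10 intensity strictly below the threshold."""
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("no cells")
    return float(np.mean(np.log10(x) < threshold))


def subpop_pipeline(cells: pd.DataFrame, intensity: str = "mean",
                    bandwidth: str | float = "silverman",
                    min_cells: int = MIN_CELLS) -> pd.DataFrame:
    """Per-subject kde -> find_valley -> proportion_low over a cells table.

    Subjects whose own curve is unimodal (or who are below the cell floor)
    receive the valley of the pooled-cohort KDE as a fallback threshold and
    are flagged ``fallback=True``.  One subject's failure never aborts the
    cohort.
    """
    col = {"mean": "mt_mean", "total": "mt_total"}[intensity]
    out_cols = ["patient_id", "n_cells", "threshold_log10", "prop_low",
                "bimodal", "fallback"]
    if len(cells) == 0:
        return pd.DataFrame(columns=out_cols)
    cells = cells[cells[col] > 0]

    pooled_threshold = None
    if len(cells) >= min_cells:
        pooled = kde(cells[col].to_numpy(), bandwidth, min_cells=min_cells)
        pooled_threshold, _, pooled_bimodal = find_valley(pooled)
        if not pooled_bimodal:
            pooled_threshold = None

    rows = []
    for pid, sub in cells.groupby("patient_id", sort=True):
        x = sub[col].to_numpy()
        threshold, bimodal, fallback = None, False, False
        try:
            curve = kde(x, bandwidth, min_cells=min_cells)
            threshold, _, bimodal = find_valley(curve)
        except TooFewCellsError:
            pass
        if threshold is None:
            threshold, fallback = pooled_threshold, True
        prop = proportion_low(x, threshold) if threshold is not None else None
        rows.append({"patient_id": pid, "n_cells": int(len(x)),
                     "threshold_log10": threshold, "prop_low": prop,
                     "bimodal": bimodal, "fallback": fallback})
    return pd.DataFrame(rows, columns=out_cols)
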