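"""Magnitude-based artifact characterization of time windows.

Per window: the 90th percentile of the per-bin magnitude standard
deviations, and the mean per-bin skewness / excess kurtosis.  Windows are
then grouped by whether the selection produced any bins, mirroring the
no-selection vs. any-selection comparison tables.

Kurtosis is the *excess* convention (normal -> 0), so the |kurtosis| > 3
threshold flags genuinely heavy tails; with the Pearson convention the
normal distribution itself would sit at the threshold.  Percentiles use
linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .epoching import WindowGrid, make_windows
from .processing import RangeTimeMatrix, all_magnitudes
from .selection import SelectionMask


def window_std_p90(magnitudes: np.ndarray) -> float:
    """90th percentile across bins of the per-bin std over the window.

    ``magnitudes`` is [bins x samples] for one window.
    """
    mags = np.atleast_2d(np.asarray(magnitudes, dtype=float))
    stds = np.std(mags, axis=1)
    return float(np.percentile(stds, 90))


def window_shape_stats(magnitudes: np.ndarray,
                       *, excess: bool = True) -> tuple[float, float]:
    """Mean per-bin sample skewness and (excess) kurtosis over the window.

    Zero-variance bins are excluded; returns (nan, nan) if all bins are
    flat.
    """
    mags = np.atleast_2d(np.asarray(magnitudes, dtype=float))
    if mags.shape[1] < 4:
        raise ValueError("need at least 4 samples per bin")
    keep = np.std(mags, axis=1) > 0
    if not np.any(keep):
        return np.nan, np.nan
    skew = stats.skew(mags[keep], axis=1)
    kurt = stats.kurtosis(mags[keep], axis=1, fisher=excess)
    return float(np.mean(skew)), float(np.mean(kurt))


def artifact_report(matrix: RangeTimeMatrix, grid: WindowGrid | None = None,
                    *, excess: bool = True) -> pd.DataFrame:
    """Per-window artifact metrics for a frame-level, bin-restricted matrix."""
    grid = grid or WindowGrid()
    if matrix.level != "frame":
        raise ValueError("artifact_report expects a frame-level matrix")
    mags = all_magnitudes(matrix)
    rows = []
    for w, win in enumerate(make_windows(matrix.n_cols / matrix.fs, grid)):
        seg = mags[:, win.sample_slice(matrix.fs)]
        skew, kurt = window_shape_stats(seg, excess=excess)
        rows.append({"window": w, "window_start_s": win.start_s,
                     "std_p90": window_std_p90(seg),
                     "mean_skewness": skew, "mean_kurtosis": kurt})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupStats:
    n_windows: int
    std_quartiles: tuple[float, float, float]
    pct_skew_gt1: float
    pct_kurt_gt3: float

    def to_dict(self) -> dict:
        return {
            "n_windows": self.n_windows,
            "std_q25": self.std_quartiles[0],
            "std_q50": self.std_quartiles[1],
            "std_q75": self.std_quartiles[2],
            "pct_abs_skewness_gt_1": self.pct_skew_gt1,
            "pct_abs_kurtosis_gt_3": self.pct_kurt_gt3,
        }


def _group(report: pd.DataFrame) -> GroupStats:
    if len(report) == 0:
        return GroupStats(0, (np.nan, np.nan, np.nan), np.nan, np.nan)
    q = np.percentile(report["std_p90"], [25, 50, 75])
    return GroupStats(
        n_windows=len(report),
        std_quartiles=(float(q[0]), float(q[1]), float(q[2])),
        pct_skew_gt1=float(100.0 * np.mean(np.abs(report["mean_skewness"]) > 1)),
        pct_kurt_gt3=float(100.0 * np.mean(np.abs(report["mean_kurtosis"]) > 3)),
    )


def group_exceedance(report: pd.DataFrame, mask: SelectionMask) -> dict:
    """No-selection vs. any-selection group statistics.

    ``report`` rows and mask columns must share the same window grid.
    Returns the machine twin of the exploration tables: per group, the
    std_p90 quartiles and the |skewness| > 1 / |kurtosis| > 3 ratios.
    """
    if len(report) != mask.selected.shape[1]:
        raise ValueError("report and mask cover different window counts")
    any_sel = mask.selected.any(axis=0)
    selected = _group(report[any_sel])
    unselected = _group(report[~any_sel])
    return {"any_selection": selected.to_dict(),
            "no_selection": unselected.to_dict()}
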