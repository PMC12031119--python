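"""Scoring selection masks and rates against synthetic ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .epoching import WindowGrid, make_rate_windows
from .rates import ErrorSummary, error_summary
from .selection import SelectionMask
from .simulate import GroundTruth


def window_labels(truth: GroundTruth, mask: SelectionMask,
                  vital: str, *, exclude_artifacts: bool = True):
    """(labels, valid) boolean [bin x window] arrays on the mask's grid.

    A window is valid for scoring when it does not overlap an artifact
    event (selection behaviour during gross motion is deliberately
    unspecified).  Bins are matched by the mask's original device indices.
    """
    bins = truth.breathing_bins if vital == "breathing" else truth.heartbeat_bins
    labels = np.repeat(bins[mask.bin_indices][:, None],
                       len(mask.window_starts_s), axis=1)
    valid = np.ones_like(labels, dtype=bool)
    if exclude_artifacts:
        fs = truth.frame_rate
        for w, start in enumerate(mask.window_starts_s):
            lo = int(round(start * fs))
            hi = int(round((start + mask.window_length_s) * fs))
            if np.any(truth.artifact_active[lo:hi]):
                valid[:, w] = False
    return labels, valid


def sensitivity_specificity(mask: SelectionMask, truth: GroundTruth,
                            vital: str, *, exclude_artifacts: bool = True):
    """(sensitivity, specificity) of a 15 s selection mask vs. the labels.

    For heartbeat, bins that also contain breathing are excluded from the
    sensitivity (the breathing motion legitimately masks the pulse there).
    """
    labels, valid = window_labels(truth, mask, vital,
                                  exclude_artifacts=exclude_artifacts)
    sel = mask.selected
    if vital == "heartbeat":
        masked = truth.breathing_bins[mask.bin_indices]
        valid = valid & ~(labels & masked[:, None])
    pos = labels & valid
    neg = ~labels & valid
    sens = float(np.sum(sel & pos) / np.sum(pos)) if np.any(pos) else np.nan
    spec = float(np.sum(~sel & neg) / np.sum(neg)) if np.any(neg) else np.nan
    return sens, spec


def true_rate_series(truth: GroundTruth, vital: str,
                     n_short_windows: int,
                     grid: WindowGrid | None = None) -> pd.DataFrame:
    """Ground-truth rates averaged over each 60 s rate window."""
    grid = grid or WindowGrid()
    rates = (truth.breathing_rate_bpm if vital == "breathing"
             else truth.heart_rate_bpm)
    fs = truth.frame_rate
    rows = []
    for win in make_rate_windows(n_short_windows, grid):
        seg = rates[win.sample_slice(fs)]
        rows.append({"window_start_s": win.start_s,
                     "rate_bpm": float(np.mean(seg)) if len(seg) else np.nan})
    return pd.DataFrame(rows)


def rates_vs_truth(radar: pd.DataFrame, truth_rates: pd.DataFrame) -> ErrorSummary:
    """Error summary of a radar rate series against the true trajectory."""
    merged = radar.merge(truth_rates, on="window_start_s",
                         suffixes=("_radar", "_true"))
    return error_summary(merged["rate_bpm_true"].to_numpy(),
                         merged["rate_bpm_radar"].to_numpy())
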