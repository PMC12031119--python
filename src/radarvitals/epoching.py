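"""Sliding-window segmentation and the continuity merge.

Selection runs on 15 s windows stepped by 5 s; runs of 10 consecutive short
windows in which a bin was selected at least 7 times are merged into 60 s
rate-computation windows, which advance on the same 5 s grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class WindowGrid:
    window_length_s: float = 15.0
    step_s: float = 5.0
    merge_span: int = 10
    merge_quorum: int = 7

    def __post_init__(self) -> None:
        if self.window_length_s <= 0 or self.step_s <= 0:
            raise ValueError("window length and step must be positive")
        if not 1 <= self.merge_quorum <= self.merge_span:
            raise ValueError("need 1 <= merge_quorum <= merge_span")

    @property
    def rate_window_length_s(self) -> float:
        """Length of a merged window: (span-1) * step + window_length."""
        return (self.merge_span - 1) * self.step_s + self.window_length_s


@dataclass(frozen=True)
class Window:
    start_s: float
    length_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.length_s

    def sample_slice(self, fs: float) -> slice:
        return slice(int(round(self.start_s * fs)),
                     int(round(self.end_s * fs)))


def make_windows(duration_s: float, grid: WindowGrid) -> list[Window]:
    """Short windows at 0, step, 2*step, ... fully inside the recording."""
    if duration_s < grid.window_length_s:
        raise ValueError(
            f"recording of {duration_s} s shorter than one "
            f"{grid.window_length_s} s window"
        )
    n = int(np.floor((duration_s - grid.window_length_s) / grid.step_s)) + 1
    return [Window(i * grid.step_s, grid.window_length_s) for i in range(n)]


def make_rate_windows(n_short_windows: int, grid: WindowGrid) -> list[Window]:
    """Merged 60 s windows; runs needing short windows beyond the recording
    end are skipped (no padding)."""
    n = n_short_windows - grid.merge_span + 1
    return [Window(i * grid.step_s, grid.rate_window_length_s)
            for i in range(max(n, 0))]


def merge_selections(mask: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """Quorum merge of a [bins x short-windows] boolean mask.

    Output column ``w`` covers short windows ``w .. w + merge_span - 1``;
    a bin is selected iff it was selected in at least ``merge_quorum`` of
    them.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be [bins x windows]")
    n_out = mask.shape[1] - grid.merge_span + 1
    if n_out <= 0:
        return np.zeros((mask.shape[0], 0), dtype=bool)
    counts = np.cumsum(np.concatenate(
        [np.zeros((mask.shape[0], 1), dtype=int), mask.astype(int)], axis=1), axis=1)
    run = counts[:, grid.merge_span:] - counts[:, :-grid.merge_span]
    return run[:, :n_out] >= grid.merge_quorum
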