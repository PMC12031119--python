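"""End-to-end composition: recording -> masks -> rates -> report."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import io
from .artifacts import artifact_report, group_exceedance
from .config import PipelineConfig
from .epoching import merge_selections
from .processing import RangeTimeMatrix, chirp_median, first_chirp, restrict_bins
from .rates import error_summary, rate_series
from .selection import select_bins

log = logging.getLogger("radarvitals")


def to_frame_level(matrix: RangeTimeMatrix, config: PipelineConfig) -> RangeTimeMatrix:
    if matrix.level == "frame":
        return matrix
    if config.chirp_mode == "median":
        return chirp_median(matrix)
    return first_chirp(matrix)


def prepare(matrix: RangeTimeMatrix, config: PipelineConfig) -> RangeTimeMatrix:
    """Chirp combination + range-bin restriction."""
    frame = to_frame_level(matrix, config)
    return restrict_bins(frame, config.restrict_min_m, config.restrict_max_m)


def run_selection(matrix: RangeTimeMatrix, config: PipelineConfig,
                  *, collect_evidence: bool = False):
    """Returns (breathing_mask, heartbeat_mask, merged dict, evidence)."""
    prepared = prepare(matrix, config)
    breath, heart, evidence = select_bins(
        prepared, config.grid, config.criteria,
        collect_evidence=collect_evidence)
    merged = {
        "breathing": merge_selections(breath.selected, config.grid),
        "heartbeat": merge_selections(heart.selected, config.grid),
    }
    return breath, heart, merged, evidence


def run_rates(matrix: RangeTimeMatrix, masks: dict, config: PipelineConfig,
              *, single_best_bin: bool = False) -> pd.DataFrame:
    """Radar rate series for both vitals, long format with a 'vital' column."""
    prepared = prepare(matrix, config)
    frames = []
    for vital, mask in masks.items():
        df = rate_series(prepared, mask, config.grid, config.criteria,
                         config.rates, single_best_bin=single_best_bin)
        df.insert(0, "vital", vital)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_report(radar_rates: pd.DataFrame,
               references: dict[str, pd.DataFrame]) -> dict:
    """Error summaries per vital against reference rate series."""
    out = {}
    for vital, ref in references.items():
        sub = radar_rates[radar_rates["vital"] == vital]
        merged = sub.merge(ref, on="window_start_s", suffixes=("_radar", "_ref"))
        ok = np.isfinite(merged["rate_bpm_radar"]) & np.isfinite(merged["rate_bpm_ref"])
        if not ok.any():
            out[vital] = {"error": "no windows with both rates defined"}
            continue
        summary = error_summary(merged.loc[ok, "rate_bpm_ref"].to_numpy(),
                                merged.loc[ok, "rate_bpm_radar"].to_numpy())
        out[vital] = summary.to_dict()
    return out


def run_artifact_report(matrix: RangeTimeMatrix, breath_mask, config: PipelineConfig):
    prepared = prepare(matrix, config)
    report = artifact_report(prepared, config.grid)
    return report, group_exceedance(report, breath_mask)
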