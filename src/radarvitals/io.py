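"""HDF5/NPZ/CSV readers and writers for recordings, masks and rates.

Recording layout (HDF5): ``/range_time`` [bin x time] complex64 or
``/if_cube`` [frame x chirp x sample] complex64; root attributes hold every
device field plus the matrix level; ``/ground_truth/*`` holds label arrays
when the recording is synthetic.  Reference traces are written as two-column
CSV (time_s, value).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .device import DeviceConfig
from .processing import RangeTimeMatrix
from .selection import SelectionMask
from .simulate import GroundTruth

FORMAT_VERSION = "1"


def config_hash(obj) -> str:
    """Stable short hash of a (nested dataclass-ish) configuration."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=repr).encode()
    ).hexdigest()[:12]


def write_recording(path, matrix: RangeTimeMatrix,
                    truth: GroundTruth | None = None,
                    cube: np.ndarray | None = None,
                    extra_attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["level"] = matrix.level
        f.attrs["fs"] = matrix.fs
        for k, v in matrix.device.to_attrs().items():
            f.attrs[k] = v
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v
        f.create_dataset("range_time", data=matrix.data.astype(np.complex64))
        f.create_dataset("bin_indices", data=matrix.bin_indices)
        if cube is not None:
            f.create_dataset("if_cube", data=cube.astype(np.complex64))
        if truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("breathing_bins", data=truth.breathing_bins)
            g.create_dataset("heartbeat_bins", data=truth.heartbeat_bins)
            g.create_dataset("breathing_rate_bpm", data=truth.breathing_rate_bpm)
            g.create_dataset("heart_rate_bpm", data=truth.heart_rate_bpm)
            g.create_dataset("artifact_active", data=truth.artifact_active)
            g.attrs["frame_rate"] = truth.frame_rate


def read_recording(path):
    """Returns (matrix, truth-or-None)."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"cannot open recording {path!r}: {exc}") from exc
    with f:
        if "range_time" not in f:
            raise ValueError(f"{path!r} has no /range_time dataset")
        device = DeviceConfig.from_attrs(f.attrs)
        matrix = RangeTimeMatrix(
            data=f["range_time"][()].astype(np.complex128),
            fs=float(f.attrs["fs"]),
            bin_indices=f["bin_indices"][()],
            device=device,
            level=str(f.attrs["level"]),
        )
        truth = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            truth = GroundTruth(
                breathing_bins=g["breathing_bins"][()].astype(bool),
                heartbeat_bins=g["heartbeat_bins"][()].astype(bool),
                breathing_rate_bpm=g["breathing_rate_bpm"][()],
                heart_rate_bpm=g["heart_rate_bpm"][()],
                artifact_active=g["artifact_active"][()].astype(bool),
                frame_rate=float(g.attrs["frame_rate"]),
            )
    return matrix, truth


def write_trace_csv(path, t: np.ndarray, values: np.ndarray) -> None:
    pd.DataFrame({"time_s": t, "value": values}).to_csv(path, index=False)


def read_trace_csv(path):
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(), df["value"].to_numpy()


def write_masks(path, masks: list[SelectionMask],
                merged: dict | None = None,
                extra_attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v
        for mask in masks:
            g = f.create_group(mask.vital)
            g.create_dataset("selected", data=mask.selected)
            g.create_dataset("bin_indices", data=mask.bin_indices)
            g.create_dataset("window_starts_s", data=mask.window_starts_s)
            g.attrs["window_length_s"] = mask.window_length_s
            if merged and mask.vital in merged:
                g.create_dataset("merged", data=merged[mask.vital])


def read_masks(path) -> dict[str, SelectionMask]:
    out = {}
    with h5py.File(path, "r") as f:
        for vital in f:
            g = f[vital]
            out[vital] = SelectionMask(
                selected=g["selected"][()].astype(bool),
                bin_indices=g["bin_indices"][()],
                window_starts_s=g["window_starts_s"][()],
                window_length_s=float(g.attrs["window_length_s"]),
                vital=vital,
            )
    return out


def evidence_to_csv(path, evidence: list[dict]) -> None:
    pd.json_normalize(evidence).to_csv(path, index=False)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=float) + "\n")
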