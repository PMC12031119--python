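"""Range processing: range FFT, chirp median, phase/magnitude extraction
and the range-bin restriction.

Coordinate conventions: bins are 0-based, the center range of bin ``k`` is
``k * delta_r``, and the fast-time FFT length equals the sample count (no
zero padding).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .device import DeviceConfig, range_resolution  # noqa: F401  (re-export)


@dataclass
class RangeTimeMatrix:
    """Complex reflection per (range bin x chirp-or-frame).

    ``level`` is ``"chirp"`` (columns are individual chirps) or ``"frame"``
    (one column per frame).  ``bin_indices`` are the original device bin
    indices of the rows, preserved across :func:`restrict_bins`.
    """

    data: np.ndarray
    fs: float
    bin_indices: np.ndarray
    device: DeviceConfig
    level: str = "chirp"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.bin_indices = np.asarray(self.bin_indices)
        if self.data.ndim != 2:
            raise ValueError("data must be [bins x time]")
        if len(self.bin_indices) != self.data.shape[0]:
            raise ValueError("bin_indices length must match data rows")
        if self.level not in ("chirp", "frame"):
            raise ValueError(f"level must be 'chirp' or 'frame', got {self.level!r}")

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def bin_ranges(self) -> np.ndarray:
        """Center range [m] of each row."""
        return self.bin_indices * self.device.delta_r

    @property
    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_cols) / self.fs

    def row(self, bin_index: int) -> np.ndarray:
        """Complex series of the row whose *device* bin index matches."""
        pos = np.flatnonzero(self.bin_indices == bin_index)
        if len(pos) == 0:
            raise KeyError(f"bin {bin_index} not present (restricted away?)")
        return self.data[pos[0]]


def range_fft(cube: np.ndarray, device: DeviceConfig) -> RangeTimeMatrix:
    """Hanning-windowed fast-time FFT of a raw IF cube.

    ``cube`` is [frame, chirp, fast-time]; the output matrix has one column
    per chirp (chirp level) and one row per unaliased range bin.
    """
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError("cube must be [frame, chirp, sample]")
    if cube.shape[2] < 2:
        raise ValueError("need at least 2 fast-time samples")
    if not np.all(np.isfinite(cube.real)) or not np.all(np.isfinite(cube.imag)):
        raise ValueError("cube contains non-finite samples")
    window = np.hanning(cube.shape[2])
    spectra = np.fft.fft(cube * window, axis=2)
    n_frames, n_chirps, n_samples = cube.shape
    n_bins = n_samples // 2
    data = spectra.reshape(n_frames * n_chirps, n_samples).T[:n_bins]
    return RangeTimeMatrix(
        data=data,
        fs=device.frame_rate * n_chirps,
        bin_indices=np.arange(n_bins),
        device=device,
        level="chirp",
    )


def _wrap(angles: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * angles))


def chirp_median(matrix: RangeTimeMatrix) -> RangeTimeMatrix:
    """Collapse the chirps of each frame to one value by the median.

    The median is taken separately over the per-chirp magnitudes and the
    per-chirp phases.  Phases within a frame are first re-wrapped around
    their circular mean so a frame straddling the +/- pi branch cut does
    not corrupt the median.  An incomplete final frame is dropped.
    """
    if matrix.level != "chirp":
        raise ValueError("chirp_median expects a chirp-level matrix")
    n_c = matrix.device.chirps_per_frame
    n_frames = matrix.n_cols // n_c
    if n_frames == 0:
        raise ValueError("fewer columns than chirps_per_frame")
    x = matrix.data[:, : n_frames * n_c].reshape(matrix.n_bins, n_frames, n_c)

    mag = np.median(np.abs(x), axis=2)
    ang = np.angle(x)
    center = np.angle(np.mean(np.exp(1j * ang), axis=2, keepdims=True))
    phase = np.median(_wrap(ang - center), axis=2) + center[..., 0]
    return RangeTimeMatrix(
        data=mag * np.exp(1j * phase),
        fs=matrix.device.frame_rate,
        bin_indices=matrix.bin_indices,
        device=matrix.device,
        level="frame",
    )


def first_chirp(matrix: RangeTimeMatrix) -> RangeTimeMatrix:
    """Baseline frame-level matrix using each frame's first chirp only."""
    if matrix.level != "chirp":
        raise ValueError("first_chirp expects a chirp-level matrix")
    n_c = matrix.device.chirps_per_frame
    n_frames = matrix.n_cols // n_c
    return RangeTimeMatrix(
        data=matrix.data[:, : n_frames * n_c : n_c],
        fs=matrix.device.frame_rate,
        bin_indices=matrix.bin_indices,
        device=matrix.device,
        level="frame",
    )


def extract_phase(matrix: RangeTimeMatrix, bin_index: int) -> np.ndarray:
    """Unwrapped arctangent-demodulated phase of one bin across time [rad]."""
    return np.unwrap(np.angle(matrix.row(bin_index)))


def extract_magnitude(matrix: RangeTimeMatrix, bin_index: int) -> np.ndarray:
    """Magnitude of one bin across time."""
    return np.abs(matrix.row(bin_index))


def all_phases(matrix: RangeTimeMatrix) -> np.ndarray:
    """Unwrapped phase of every bin, [bins x time]."""
    return np.unwrap(np.angle(matrix.data), axis=1)


def all_magnitudes(matrix: RangeTimeMatrix) -> np.ndarray:
    return np.abs(matrix.data)


def phase_to_displacement(phase: np.ndarray, wavelength: float) -> np.ndarray:
    """Displacement [m] relative to the window start, ``d = phi lambda/(4 pi)``."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    phase = np.asarray(phase, dtype=float)
    return (phase - phase[..., :1]) * wavelength / (4.0 * np.pi)


def restrict_bins(matrix: RangeTimeMatrix, min_m: float = 0.4,
                  max_m: float = 3.0) -> RangeTimeMatrix:
    """Keep only bins whose center range lies in ``[min_m, max_m]``.

    Near bins suffer TX/RX crosstalk; far bins are dominated by multipath.
    Original bin indices are preserved in ``bin_indices``.
    """
    if max_m < min_m:
        raise ValueError(f"max_m ({max_m}) < min_m ({min_m})")
    ranges = matrix.bin_ranges
    keep = (ranges >= min_m) & (ranges <= max_m)
    if not np.any(keep):
        raise ValueError(
            f"no bins with center in [{min_m}, {max_m}] m "
            f"(available: {ranges.min():.3f}..{ranges.max():.3f} m)"
        )
    return replace(matrix, data=matrix.data[keep],
                   bin_indices=matrix.bin_indices[keep])
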