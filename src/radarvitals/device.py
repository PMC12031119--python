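"""FMCW device parameters and derived quantities.

A device is described by its carrier frequency, sweep bandwidth and chirp
timing.  Everything else (range resolution, chirp slope, wavelength, frame
rate) is derived.  Defaults correspond to a 60 GHz sensor sweeping 3 GHz
with 12 chirps per 50 ms frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

C = 299_792_458.0
"""Speed of light [m/s]."""


def range_resolution(bandwidth_hz: float, *, c: float = C) -> float:
    """Range-bin width ``c / (2 B)`` [m] of a linear sweep of bandwidth ``B``.

    Parameters
    ----------
    bandwidth_hz:
        Sweep bandwidth in Hz; must be positive.
    c:
        Propagation speed; defaults to the speed of light in vacuum.
    """
    if bandwidth_hz <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth_hz!r}")
    return c / (2.0 * bandwidth_hz)


@dataclass(frozen=True)
class DeviceConfig:
    """Chirp timing and RF parameters of an FMCW radar.

    Attributes
    ----------
    fc:
        Carrier frequency [Hz].
    bandwidth:
        Frequency-sweep bandwidth [Hz].
    sweep_duration:
        Duration ``T`` of one linear sweep [s].
    chirp_interval:
        Start-to-start spacing of consecutive chirps [s].
    chirps_per_frame:
        Number of chirps grouped into one frame.
    frame_interval:
        Start-to-start spacing of frames [s].
    n_fast_samples:
        ADC samples per chirp (fast time).
    """

    fc: float = 60e9
    bandwidth: float = 3e9
    sweep_duration: float = 50e-6
    chirp_interval: float = 401e-6
    chirps_per_frame: int = 12
    frame_interval: float = 0.05
    n_fast_samples: int = 128
    c: float = field(default=C, repr=False)

    def __post_init__(self) -> None:
        for name in ("fc", "bandwidth", "sweep_duration", "chirp_interval",
                     "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.chirps_per_frame < 1:
            raise ValueError("chirps_per_frame must be >= 1")
        if self.n_fast_samples < 2:
            raise ValueError("n_fast_samples must be >= 2")
        if self.chirps_per_frame * self.chirp_interval > self.frame_interval:
            raise ValueError(
                "chirps do not fit in one frame: "
                f"{self.chirps_per_frame} x {self.chirp_interval} s "
                f"> {self.frame_interval} s"
            )

    @property
    def slope(self) -> float:
        """Chirp slope ``mu = B / T`` [Hz/s]."""
        return self.bandwidth / self.sweep_duration

    @property
    def wavelength(self) -> float:
        """Carrier wavelength ``lambda = c / fc`` [m]."""
        return self.c / self.fc

    @property
    def delta_r(self) -> float:
        """Range resolution ``c / (2 B)`` [m]."""
        return range_resolution(self.bandwidth, c=self.c)

    @property
    def frame_rate(self) -> float:
        """Frames per second [Hz]."""
        return 1.0 / self.frame_interval

    @property
    def frame_span(self) -> float:
        """Time from the start of a frame's first chirp to the end of its
        last chirp [s] (chirps_per_frame x chirp_interval)."""
        return self.chirps_per_frame * self.chirp_interval

    @property
    def adc_rate(self) -> float:
        """Fast-time sample rate; samples span exactly one sweep [Hz]."""
        return self.n_fast_samples / self.sweep_duration

    @property
    def n_bins(self) -> int:
        """Number of unaliased range bins (half the fast-time FFT length)."""
        return self.n_fast_samples // 2

    @property
    def max_range(self) -> float:
        """Largest unaliased target range [m]."""
        return self.n_bins * self.delta_r

    def beat_frequency(self, range_m: float) -> float:
        """IF tone frequency ``mu * 2 R / c`` of a target at ``range_m``."""
        return self.slope * 2.0 * range_m / self.c

    def range_to_bin(self, range_m: float) -> int:
        """Index of the range bin whose center is nearest ``range_m``."""
        return int(round(range_m / self.delta_r))

    def to_attrs(self) -> dict:
        """Flat dict of all fields, for HDF5 attribute storage."""
        return {
            "fc": self.fc,
            "bandwidth": self.bandwidth,
            "sweep_duration": self.sweep_duration,
            "chirp_interval": self.chirp_interval,
            "chirps_per_frame": self.chirps_per_frame,
            "frame_interval": self.frame_interval,
            "n_fast_samples": self.n_fast_samples,
        }

    @classmethod
    def from_attrs(cls, attrs) -> "DeviceConfig":
        return cls(
            fc=float(attrs["fc"]),
            bandwidth=float(attrs["bandwidth"]),
            sweep_duration=float(attrs["sweep_duration"]),
            chirp_interval=float(attrs["chirp_interval"]),
            chirps_per_frame=int(attrs["chirps_per_frame"]),
            frame_interval=float(attrs["frame_interval"]),
            n_fast_samples=int(attrs["n_fast_samples"]),
        )
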