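"""Synthetic FMCW scene generator.

Builds labeled recordings for testing the selection pipeline: a scene of
body segments (breathing torso bins, heartbeat leg bins), per-chirp complex
noise, and sporadic large motion artifacts.  Two fidelity levels exist:

* ``synthesize_matrix`` emits the complex range-time matrix directly
  (fast; unit-test level), at frame rate or chirp rate;
* ``synthesize_if_cube`` emits raw fast-time IF samples per chirp so the
  range FFT itself is exercised.

Reference streams (respiration belt, ECG-like pulse train) share the frame
clock of the radar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .device import DeviceConfig


@dataclass(frozen=True)
class Breathing:
    """Breathing displacement component of a segment.

    Rate drifts linearly from ``rate_bpm[0]`` to ``rate_bpm[1]`` over the
    scene.  ``harmonics`` are relative amplitudes of the 2nd and 3rd
    harmonic (non-sinusoidal breaths).
    """

    rate_bpm: tuple[float, float] = (15.0, 15.0)
    amplitude_m: float = 1e-3
    harmonics: tuple[float, float] = (0.2, 0.1)


@dataclass(frozen=True)
class Heartbeat:
    """Heartbeat displacement: Gaussian-windowed pulse per beat."""

    rate_bpm: tuple[float, float] = (70.0, 70.0)
    amplitude_m: float = 8e-5
    pulse_width_s: float = 0.09


@dataclass(frozen=True)
class BodySegment:
    """A reflecting body part at a fixed range."""

    range_m: float
    reflectivity: float = 1.0
    breathing: Breathing | None = None
    heartbeat: Heartbeat | None = None


@dataclass(frozen=True)
class ArtifactEvent:
    """Large broadband displacement burst plus amplitude modulation.

    ``bins`` is a (start, stop) half-open bin-index range affected by the
    event; ``amplitude_m`` should be >= 5 mm to emulate gross motion.
    """

    start_s: float
    duration_s: float
    bins: tuple[int, int]
    amplitude_m: float = 0.01
    magnitude_mod: float = 1.0


@dataclass(frozen=True)
class SceneSpec:
    segments: Sequence[BodySegment] = ()
    noise_sigma: float = 0.1
    artifact_events: Sequence[ArtifactEvent] = ()
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class DisplacementField:
    """Per-bin displacement series at frame rate, plus per-segment detail."""

    per_bin: np.ndarray               # [n_bins, n_frames] summed displacement [m]
    segment_bins: list[int]           # bin index of each segment
    segment_disp: list[np.ndarray]    # displacement series of each segment
    artifact_disp: np.ndarray         # [n_bins, n_frames] artifact component [m]
    frame_rate: float


@dataclass
class GroundTruth:
    """Scene labels on the radar frame clock."""

    breathing_bins: np.ndarray        # bool [n_bins]
    heartbeat_bins: np.ndarray        # bool [n_bins]
    breathing_rate_bpm: np.ndarray    # [n_frames] (nan if no breathing segment)
    heart_rate_bpm: np.ndarray        # [n_frames] (nan if no heartbeat segment)
    artifact_active: np.ndarray       # bool [n_frames]
    frame_rate: float


def standard_scene(duration_s: float = 1800.0, seed: int = 0,
                   noise_sigma: float = 0.05,
                   n_artifacts: int = 5) -> SceneSpec:
    """Reference labeled scene: drifting breathing over torso bins
    (11 -> 18 BPM, ~1.9-2.1 m), drifting heartbeat over leg bins
    (55 -> 80 BPM, ~0.6-0.75 m) and sporadic large motion artifacts.
    """
    torso = [BodySegment(r, reflectivity=1.0,
                         breathing=Breathing((11.0, 18.0), 1e-3))
             for r in (1.85, 1.90, 1.95, 2.00, 2.05, 2.10)]
    legs = [BodySegment(r, reflectivity=0.8,
                        heartbeat=Heartbeat((55.0, 80.0), 8e-5))
            for r in (0.60, 0.65, 0.70, 0.75)]
    events = []
    if n_artifacts > 0:
        gap = duration_s / (n_artifacts + 1)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAE]))
        for k in range(n_artifacts):
            events.append(ArtifactEvent(
                start_s=(k + 1) * gap + float(rng.uniform(-0.1, 0.1) * gap),
                duration_s=float(rng.uniform(8.0, 14.0)),
                bins=(8, 50),
                amplitude_m=0.01,
                magnitude_mod=1.5,
            ))
    return SceneSpec(segments=tuple(torso + legs), noise_sigma=noise_sigma,
                     artifact_events=tuple(events), duration_s=duration_s,
                     seed=seed)


def _rate_trajectory(rate_bpm: tuple[float, float], t: np.ndarray) -> np.ndarray:
    t_end = t[-1] if len(t) > 1 and t[-1] > 0 else 1.0
    return rate_bpm[0] + (rate_bpm[1] - rate_bpm[0]) * (t / t_end)


def _breathing_waveform(b: Breathing, t: np.ndarray) -> np.ndarray:
    rate_hz = _rate_trajectory(b.rate_bpm, t) / 60.0
    # integrate instantaneous frequency on the uniform frame grid
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    theta = 2.0 * np.pi * np.concatenate([[0.0], np.cumsum(rate_hz[:-1]) * dt])
    h2, h3 = b.harmonics
    return b.amplitude_m * (
        np.sin(theta) + h2 * np.sin(2 * theta) + h3 * np.sin(3 * theta)
    )


def _beat_times(rate_bpm: tuple[float, float], t: np.ndarray) -> np.ndarray:
    rate_hz = _rate_trajectory(rate_bpm, t) / 60.0
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    phase = np.concatenate([[0.0], np.cumsum(rate_hz[:-1]) * dt])
    n_beats = int(np.floor(phase[-1])) if len(phase) else 0
    return np.interp(np.arange(1, n_beats + 1), phase, t)


def _heartbeat_waveform(h: Heartbeat, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for bt in _beat_times(h.rate_bpm, t):
        out += np.exp(-0.5 * ((t - bt) / h.pulse_width_s) ** 2)
    return h.amplitude_m * out


def _artifact_waveform(ev: ArtifactEvent, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smoothed random burst of displacement, tapered at the edges."""
    active = (t >= ev.start_s) & (t < ev.start_s + ev.duration_s)
    n = int(np.sum(active))
    if n == 0:
        return np.zeros_like(t)
    raw = rng.standard_normal(n + 8)
    kernel = np.hanning(9)
    smooth = np.convolve(raw, kernel / kernel.sum(), mode="valid")[:n]
    peak = np.max(np.abs(smooth))
    if peak > 0:
        smooth = smooth / peak
    out = np.zeros_like(t)
    out[active] = ev.amplitude_m * smooth * np.hanning(n)
    return out


def frame_times(spec: SceneSpec, device: DeviceConfig) -> np.ndarray:
    n_frames = int(np.floor(spec.duration_s / device.frame_interval))
    return np.arange(n_frames) * device.frame_interval


def displacement_field(spec: SceneSpec, device: DeviceConfig) -> DisplacementField:
    """Per-bin superposition of breathing/heartbeat/artifact displacement.

    One series per range bin at the frame rate; each segment's motion is
    assigned to the bin containing its range.  Segments outside the
    simulated range are rejected.
    """
    t = frame_times(spec, device)
    n_bins = device.n_bins
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD15]))
    per_bin = np.zeros((n_bins, len(t)))
    seg_bins: list[int] = []
    seg_disp: list[np.ndarray] = []
    for seg in spec.segments:
        b = device.range_to_bin(seg.range_m)
        if seg.range_m < 0 or b >= n_bins:
            raise ValueError(
                f"segment at {seg.range_m} m outside simulated range "
                f"[0, {device.max_range}) m"
            )
        d = np.zeros_like(t)
        if seg.breathing is not None:
            d += _breathing_waveform(seg.breathing, t)
        if seg.heartbeat is not None:
            d += _heartbeat_waveform(seg.heartbeat, t)
        per_bin[b] += d
        seg_bins.append(b)
        seg_disp.append(d)
    artifact = np.zeros_like(per_bin)
    for ev in spec.artifact_events:
        w = _artifact_waveform(ev, t, rng)
        lo, hi = ev.bins
        artifact[lo:hi] += w
    per_bin += artifact
    return DisplacementField(per_bin, seg_bins, seg_disp, artifact,
                             device.frame_rate)


def ground_truth(spec: SceneSpec, device: DeviceConfig) -> GroundTruth:
    """Labels consistent with the scene by construction."""
    t = frame_times(spec, device)
    n_bins = device.n_bins
    breathing_bins = np.zeros(n_bins, dtype=bool)
    heartbeat_bins = np.zeros(n_bins, dtype=bool)
    br_rate = np.full(len(t), np.nan)
    hr_rate = np.full(len(t), np.nan)
    for seg in spec.segments:
        b = device.range_to_bin(seg.range_m)
        if seg.breathing is not None and seg.breathing.amplitude_m > 0:
            breathing_bins[b] = True
            br_rate = _rate_trajectory(seg.breathing.rate_bpm, t)
        if seg.heartbeat is not None and seg.heartbeat.amplitude_m > 0:
            heartbeat_bins[b] = True
            hr_rate = _rate_trajectory(seg.heartbeat.rate_bpm, t)
    artifact = np.zeros(len(t), dtype=bool)
    for ev in spec.artifact_events:
        artifact |= (t >= ev.start_s) & (t < ev.start_s + ev.duration_s)
    return GroundTruth(breathing_bins, heartbeat_bins, br_rate, hr_rate,
                       artifact, device.frame_rate)


def _phase(disp: np.ndarray, wavelength: float) -> np.ndarray:
    # phi(t) = 4 pi (d(t) + d(t0)) / lambda; d(t0) is a constant offset
    return 4.0 * np.pi * (disp + disp[0]) / wavelength


def _magnitude_modulation(spec: SceneSpec, t: np.ndarray, n_bins: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Multiplicative amplitude factor per (bin, frame) from artifacts."""
    mod = np.ones((n_bins, len(t)))
    for ev in spec.artifact_events:
        if ev.magnitude_mod <= 0:
            continue
        active = (t >= ev.start_s) & (t < ev.start_s + ev.duration_s)
        n = int(np.sum(active))
        if n == 0:
            continue
        lo, hi = ev.bins
        for b in range(lo, min(hi, n_bins)):
            raw = rng.standard_normal(n + 8)
            kernel = np.hanning(9)
            smooth = np.convolve(raw, kernel / kernel.sum(), mode="valid")[:n]
            # squared bursts: heavy-tailed, one-sided magnitude excursions
            # as a moving reflector sweeps through the bin
            mod[b, active] += ev.magnitude_mod * np.hanning(n) * smooth**2 * 3.0
    return mod


def synthesize_matrix(spec: SceneSpec, device: DeviceConfig,
                      level: str = "frame"):
    """Complex range-time matrix of the scene (no fast-time synthesis).

    ``level="frame"`` emits one column per frame; ``level="chirp"`` emits
    ``chirps_per_frame`` columns per frame, all sharing the frame's
    displacement sample but with independent complex noise, which is the
    regime the chirp median exploits.

    Returns a :class:`radarvitals.processing.RangeTimeMatrix`.
    """
    from .processing import RangeTimeMatrix

    if level not in ("frame", "chirp"):
        raise ValueError(f"level must be 'frame' or 'chirp', got {level!r}")
    field = displacement_field(spec, device)
    t = frame_times(spec, device)
    n_bins, n_frames = field.per_bin.shape
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA0]))
    mod = _magnitude_modulation(spec, t, n_bins,
                                np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB1])))

    clean = np.zeros((n_bins, n_frames), dtype=np.complex128)
    for seg, b, d in zip(spec.segments, field.segment_bins, field.segment_disp):
        total = d + field.artifact_disp[b]
        clean[b] += seg.reflectivity * np.exp(1j * _phase(total, device.wavelength))
    # artifact bins without a segment still reflect during the event
    art_extra = np.zeros((n_bins, n_frames))
    for ev in spec.artifact_events:
        lo, hi = ev.bins
        active = (t >= ev.start_s) & (t < ev.start_s + ev.duration_s)
        for b in range(lo, min(hi, n_bins)):
            art_extra[b, active] = 1.0
    seg_bin_set = set(field.segment_bins)
    for b in range(n_bins):
        if b not in seg_bin_set and np.any(art_extra[b] > 0):
            clean[b] += art_extra[b] * np.exp(
                1j * _phase(field.per_bin[b], device.wavelength))
    clean *= mod

    reps = 1 if level == "frame" else device.chirps_per_frame
    data = np.repeat(clean, reps, axis=1)
    if spec.noise_sigma > 0:
        noise = rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        data = data + spec.noise_sigma / np.sqrt(2.0) * noise
    fs = device.frame_rate * reps
    return RangeTimeMatrix(
        data=data,
        fs=fs,
        bin_indices=np.arange(n_bins),
        device=device,
        level=level,
    )


def synthesize_if_cube(field: DisplacementField, spec: SceneSpec,
                       device: DeviceConfig) -> np.ndarray:
    """Raw IF cube [frame, chirp, fast-time sample], complex.

    Each segment contributes a tone at the beat frequency of its range with
    phase tracking the frame's displacement; chirps within a frame share
    the displacement but carry independent noise.  Beat frequencies at or
    above the IF Nyquist rate are rejected.
    """
    n_frames = field.per_bin.shape[1]
    n_c = device.chirps_per_frame
    n_s = device.n_fast_samples
    ts = np.arange(n_s) / device.adc_rate
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC2]))

    cube = np.zeros((n_frames, n_c, n_s), dtype=np.complex128)
    for seg, d in zip(spec.segments, field.segment_disp):
        df = device.beat_frequency(seg.range_m)
        if df >= device.adc_rate / 2.0:
            raise ValueError(
                f"beat frequency {df:.3g} Hz of segment at {seg.range_m} m "
                f"is at/above IF Nyquist {device.adc_rate / 2:.3g} Hz"
            )
        tone = seg.reflectivity * np.exp(2j * np.pi * df * ts)
        phase = _phase(d, device.wavelength)
        cube += np.exp(1j * phase)[:, None, None] * tone[None, None, :]
    if spec.noise_sigma > 0:
        noise = rng.standard_normal(cube.shape) + 1j * rng.standard_normal(cube.shape)
        cube = cube + spec.noise_sigma / np.sqrt(2.0) * noise
    return cube


def make_reference_streams(spec: SceneSpec, device: DeviceConfig,
                           *, ecg_fs: float = 200.0, belt_noise: float = 0.02):
    """Reference belt and ECG traces for the scene.

    Returns ``((t_belt, belt), (t_ecg, ecg))``.  The belt is the breathing
    displacement (first breathing segment) plus mild noise at the frame
    rate; the ECG is a QRS-like biphasic pulse train at the heartbeat rate
    trajectory, sampled at ``ecg_fs``.  Raises if the scene lacks the
    corresponding segment.
    """
    t = frame_times(spec, device)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xE3]))

    breathing = next((s.breathing for s in spec.segments if s.breathing), None)
    if breathing is None:
        raise ValueError("scene has no breathing segment for a belt trace")
    belt = _breathing_waveform(breathing, t)
    belt = belt + belt_noise * breathing.amplitude_m * rng.standard_normal(len(t))

    heartbeat = next((s.heartbeat for s in spec.segments if s.heartbeat), None)
    if heartbeat is None:
        raise ValueError("scene has no heartbeat segment for an ECG trace")
    t_ecg = np.arange(int(np.floor(spec.duration_s * ecg_fs))) / ecg_fs
    ecg = np.zeros_like(t_ecg)
    w = 0.012  # QRS half-width [s]
    for bt in _beat_times(heartbeat.rate_bpm, t_ecg):
        x = t_ecg - bt
        # biphasic: sharp positive R deflection flanked by negative lobes
        ecg += np.exp(-0.5 * (x / w) ** 2) - 0.35 * np.exp(-0.5 * ((x - 2.2 * w) / (1.6 * w)) ** 2) \
            - 0.2 * np.exp(-0.5 * ((x + 2.2 * w) / (1.6 * w)) ** 2)
    ecg += 0.02 * rng.standard_normal(len(t_ecg))
    return (t, belt), (t_ecg, ecg)
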