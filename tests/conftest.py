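import numpy as np
import pytest

import radarvitals as rv


@pytest.fixture(scope="session")
def device() -> rv.DeviceConfig:
    return rv.DeviceConfig()


@pytest.fixture(scope="session")
def fs(device) -> float:
    return device.frame_rate


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def small_scene(duration_s=120.0, seed=1, noise_sigma=0.05,
                breathing_ranges=(1.9, 1.95, 2.0, 2.05, 2.1),
                heartbeat_ranges=(0.6, 0.65, 0.7),
                breathing_bpm=(15.0, 15.0), heartbeat_bpm=(70.0, 70.0),
                artifact_events=()):
    segments = tuple(
        [rv.BodySegment(r, breathing=rv.Breathing(breathing_bpm, 1e-3))
         for r in breathing_ranges]
        + [rv.BodySegment(r, reflectivity=0.8,
                          heartbeat=rv.Heartbeat(heartbeat_bpm, 8e-5))
           for r in heartbeat_ranges]
    )
    return rv.SceneSpec(segments=segments, noise_sigma=noise_sigma,
                        artifact_events=tuple(artifact_events),
                        duration_s=duration_s, seed=seed)


@pytest.fixture(scope="session")
def labeled_recording(device):
    """120 s labeled scene with breathing torso bins and heartbeat leg bins."""
    spec = small_scene()
    matrix = rv.synthesize_matrix(spec, device, level="frame")
    truth = rv.ground_truth(spec, device)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def breathing_window(device, labeled_recording):
    """One clean low-pass-filtered 15 s breathing phase window."""
    _, matrix, _ = labeled_recording
    phase = rv.extract_phase(matrix, device.range_to_bin(2.0))
    low = rv.band_filter(phase, "breathing", matrix.fs)
    return low[:300]


@pytest.fixture(scope="session")
def heartbeat_window(device, labeled_recording):
    """One band-passed 15 s heartbeat phase window."""
    _, matrix, _ = labeled_recording
    phase = rv.extract_phase(matrix, device.range_to_bin(0.7))
    band = rv.band_filter(phase, "heartbeat", matrix.fs)
    return band[:300]
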