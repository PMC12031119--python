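# Demo scene: breathing torso bins ~1.9-2.1 m, heartbeat leg bins ~0.6-0.7 m,
# one large motion artifact. Amplitudes in meters.
duration_s: 180.0
seed: 1
noise_sigma: 0.05
segments:
  - range_m: 1.90
    breathing: {rate_bpm: [13.0, 16.0], amplitude_m: 1.0e-3}
  - range_m: 1.95
    breathing: {rate_bpm: [13.0, 16.0], amplitude_m: 1.0e-3}
  - range_m: 2.00
    breathing: {rate_bpm: [13.0, 16.0], amplitude_m: 1.2e-3}
  - range_m: 2.05
    breathing: {rate_bpm: [13.0, 16.0], amplitude_m: 1.0e-3}
  - range_m: 0.60
    reflectivity: 0.8
    heartbeat: {rate_bpm: [62.0, 70.0], amplitude_m: 8.0e-5}
  - range_m: 0.65
    reflectivity: 0.8
    heartbeat: {rate_bpm: [62.0, 70.0], amplitude_m: 8.0e-5}
  - range_m: 0.70
    reflectivity: 0.8
    heartbeat: {rate_bpm: [62.0, 70.0], amplitude_m: 8.0e-5}
artifact_events:
  - {start_s: 90.0, duration_s: 10.0, bins: [8, 50], amplitude_m: 0.01, magnitude_mod: 1.5}
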