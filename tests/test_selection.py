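import dataclasses

import numpy as np
import pytest
import radarvitals as rv
from radarvitals import selection
from radarvitals.selection import SelectionCriteria

FS = 20.0


def sine(freq_hz, duration_s=15.0, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t + phase)


def attenuation_db(kind, freq_hz, fs=FS):
    """Frequency-response oracle: RMS ratio through the filter."""
    x = sine(freq_hz, duration_s=60.0, fs=fs)
    y = rv.band_filter(x, kind, fs)
    core = slice(int(5 * fs), int(55 * fs))  # ignore edge transients
    return 20 * np.log10(np.std(y[core]) / np.std(x[core]))


class TestBandFilter:
    def test_breathing_passband(self):
        assert abs(attenuation_db("breathing", 0.25)) < 0.1

    def test_heartbeat_rejects_breathing(self):
        assert attenuation_db("heartbeat", 0.25) < -20.0

    def test_breathing_rejects_8hz(self):
        assert attenuation_db("breathing", 8.0) < -20.0

    def test_heartbeat_passband(self):
        assert abs(attenuation_db("heartbeat", 1.2)) < 0.5

    def test_bad_kind(self):
        with pytest.raises(ValueError, match="kind"):
            rv.band_filter(np.zeros(100), "pulse", FS)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            rv.band_filter(np.zeros(100), "breathing", 8.0)

    def test_same_length(self):
        x = np.random.default_rng(0).standard_normal(300)
        assert len(rv.band_filter(x, "breathing", FS)) == 300


class TestDbscanDiagram:
    def test_near_diagonal_cluster_plus_outlier(self):
        rng = np.random.default_rng(0)
        noise = np.column_stack([rng.uniform(0, 1, 10), rng.uniform(0, 0.1, 10)])
        pts = np.vstack([noise, [[0.5, 10.0]]])
        eps = rv.diagram_spread(noise)
        labels = rv.dbscan_diagram(pts, eps, 2)
        assert labels[-1] == -1
        assert set(labels[:-1]) == {0}
        # brute-force neighborhood check: the outlier has no eps-neighbor
        dists = np.linalg.norm(pts[:-1] - pts[-1], axis=1)
        assert np.all(dists > eps)

    def test_identical_points_one_cluster(self):
        pts = np.ones((5, 2))
        labels = rv.dbscan_diagram(pts, 0.0, 2)
        assert set(labels) == {0}

    def test_single_point_is_outlier(self):
        assert rv.dbscan_diagram(np.array([[1.0, 2.0]]), 1.0, 2)[0] == -1

    def test_empty(self):
        assert len(rv.dbscan_diagram(np.empty((0, 2)), 1.0, 2)) == 0


class TestBreathingVrBranch:
    def test_clean_breathing_true(self):
        rng = np.random.default_rng(1)
        x = sine(15 / 60.0) + 0.01 * rng.standard_normal(300)
        x = rv.band_filter(x, "breathing", FS)
        assert selection.breathing_vr_branch(x).decision

    def test_white_noise_false_monte_carlo(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rv.band_filter(rng.standard_normal(300), "breathing", FS)
            hits += selection.breathing_vr_branch(x).decision
        assert hits <= 10  # >= 95% rejected

    def test_constant_false(self):
        v = selection.breathing_vr_branch(np.zeros(300))
        assert not v.decision
        assert v.evidence["reason"] == "degenerate"

    def test_strict_implies_lax(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            x = rv.band_filter(rng.standard_normal(300), "breathing", FS)
            v = selection.breathing_vr_branch(x)
            assert not (v.strict_decision and not v.decision)


class TestBreathingSublevelBranch:
    def test_clean_breathing_true(self):
        rng = np.random.default_rng(3)
        x = sine(15 / 60.0) + 0.02 * rng.standard_normal(300)
        x = rv.band_filter(x, "breathing", FS)
        v = selection.breathing_sublevel_branch(x)
        assert v.decision
        assert 2 <= v.evidence["signal_count"] <= 6  # 3.75 breaths in 15 s

    def test_40bpm_count_rejected(self):
        rng = np.random.default_rng(4)
        x = sine(40 / 60.0) + 0.02 * rng.standard_normal(300)
        x = rv.band_filter(x, "breathing", FS)
        v = selection.breathing_sublevel_branch(x)
        assert not v.decision  # 10 oscillations, outside [2, 6]

    def test_flat_line_false(self):
        rng = np.random.default_rng(5)
        x = 1e-6 * rng.standard_normal(300)
        assert not selection.breathing_sublevel_branch(x).decision

    def test_count_ranges(self):
        crit = SelectionCriteria()
        assert crit.breathing_count_range(15.0) == (2, 6)
        assert crit.heartbeat_count_range(15.0) == (10, 50)
        assert crit.sublevel_min_samples(15.0) == 2
        assert crit.heartbeat_min_samples(15.0) == 10

    def test_minsamp_literal_mode(self):
        crit = SelectionCriteria(minsamp_per_window=False)
        assert crit.sublevel_min_samples(15.0) == 10
        assert crit.heartbeat_min_samples(15.0) == 40


class TestCombineBreathing:
    def make(self, decision, strict):
        return selection.BranchVerdict(decision, strict)

    def test_both_lax_true(self):
        assert rv.combine_breathing(self.make(True, False), self.make(True, False))

    def test_single_strict_true(self):
        assert rv.combine_breathing(self.make(True, True), self.make(False, False))
        assert rv.combine_breathing(self.make(False, False), self.make(True, True))

    def test_both_false(self):
        assert not rv.combine_breathing(self.make(False, False),
                                        self.make(False, False))

    def test_one_lax_only_false(self):
        assert not rv.combine_breathing(self.make(True, False),
                                        self.make(False, False))

    def test_strict_requires_lax(self):
        with pytest.raises(ValueError):
            selection.BranchVerdict(False, True)


class TestHeartbeatSelection:
    def pulse_train(self, bpm, duration_s=15.0, fs=FS, amp=1.0, noise=0.02,
                    seed=0):
        t = np.arange(int(duration_s * fs)) / fs
        x = np.zeros_like(t)
        for bt in np.arange(0.3, duration_s, 60.0 / bpm):
            x += amp * np.exp(-0.5 * ((t - bt) / 0.06) ** 2)
        x += noise * amp * np.random.default_rng(seed).standard_normal(len(t))
        return rv.band_filter(x, "heartbeat", fs)

    def test_clean_70bpm_true(self):
        assert selection.heartbeat_selection(self.pulse_train(70)).decision

    def test_breathing_leakage_removed(self):
        t = np.arange(300) / FS
        breathing = 2.0 * np.sin(2 * np.pi * 0.25 * t)
        x = self.pulse_train(70) + rv.band_filter(breathing, "heartbeat", FS)
        assert selection.heartbeat_selection(x).decision
        # breathing alone does not pass after the 0.65 Hz high-pass
        alone = rv.band_filter(10.0 * breathing + 1e-3 * np.random.default_rng(0)
                               .standard_normal(300), "heartbeat", FS)
        assert not selection.heartbeat_selection(alone).decision

    def test_white_noise_false_monte_carlo(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            x = rv.band_filter(rng.standard_normal(300), "heartbeat", FS)
            hits += selection.heartbeat_selection(x).decision
        assert hits <= 10

    def test_scale_invariance(self):
        """eps and lifespans both scale with amplitude: decisions match."""
        x = self.pulse_train(65, seed=3)
        a = selection.heartbeat_selection(x)
        b = selection.heartbeat_selection(1000.0 * x)
        c = selection.heartbeat_selection(1e-4 * x)
        assert a.decision == b.decision == c.decision
        assert a.strict_decision == b.strict_decision == c.strict_decision

    def test_degenerate_false(self):
        assert not selection.heartbeat_selection(np.zeros(300)).decision


class TestSelectBins:
    def test_labeled_scene_masks(self, device, labeled_recording):
        _, matrix, truth = labeled_recording
        prepared = rv.restrict_bins(matrix)
        breath, heart, _ = rv.select_bins(prepared)
        from radarvitals import evaluate
        b_sens, b_spec = evaluate.sensitivity_specificity(breath, truth, "breathing")
        h_sens, h_spec = evaluate.sensitivity_specificity(heart, truth, "heartbeat")
        assert b_sens >= 0.8 and b_spec >= 0.9
        assert h_sens >= 0.8 and h_spec >= 0.9

    def test_breathing_masks_heartbeat_in_torso(self, device, labeled_recording):
        """Heartbeat is not claimed in bins dominated by breathing motion."""
        _, matrix, truth = labeled_recording
        prepared = rv.restrict_bins(matrix)
        _, heart, _ = rv.select_bins(prepared)
        torso = np.isin(heart.bin_indices, np.flatnonzero(truth.breathing_bins))
        assert heart.selected[torso].mean() < 0.2

    def test_frame_level_required(self, device, labeled_recording):
        _, matrix, _ = labeled_recording
        chirpy = dataclasses.replace(matrix, level="chirp")
        with pytest.raises(ValueError, match="frame-level"):
            rv.select_bins(chirpy)

    def test_evidence_records(self, device, labeled_recording):
        _, matrix, _ = labeled_recording
        prepared = rv.restrict_bins(matrix)
        sub = dataclasses.replace(prepared, data=prepared.data[:3, :400],
                                  bin_indices=prepared.bin_indices[:3])
        _, _, evidence = rv.select_bins(sub, collect_evidence=True)
        assert len(evidence) == 3 * 2  # 3 bins x 2 windows
        assert {"vr", "sublevel", "heartbeat"} <= set(evidence[0])


class TestAllNoiseRecording:
    def test_mostly_empty_masks(self, device):
        """Pure-noise recordings produce almost no selections per cell, and
        the 7-of-10 quorum merge wipes out the residual false positives."""
        from radarvitals.epoching import WindowGrid, merge_selections
        spec = rv.SceneSpec(segments=(), noise_sigma=0.05, duration_s=120.0,
                            seed=77)
        matrix = rv.synthesize_matrix(spec, device, level="frame")
        prepared = rv.restrict_bins(matrix)
        breath, heart, _ = rv.select_bins(prepared)
        assert breath.selected.mean() < 0.05
        assert heart.selected.mean() < 0.05
        assert (~breath.selected.any(axis=0)).mean() >= 0.7
        assert merge_selections(breath.selected, WindowGrid()).sum() == 0
        assert merge_selections(heart.selected, WindowGrid()).sum() == 0
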