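"""Persistence-diagram-based range-bin selection.

Per 15 s window and per range bin, decides whether the unwrapped phase
series contains breathing and/or heartbeat.

Breathing uses two branches that are finally combined:

* Vietoris-Rips branch: 5 Hz low-pass -> time-delay embedding
  (tau = 10 samples, m = 3) -> Rips H0/H1 -> birth-lifespan -> DBSCAN on
  the H1 points (minSamp = 2, eps from the diagram spread) -> outliers are
  tested for birth (close to the largest finite H0 death, or inside the
  noise cluster's birth range) and lifespan (dominating both the noise
  cluster and the largest H0 lifespan).
* Sublevel-set branch: 5 Hz low-pass -> sublevel H0 -> birth-lifespan ->
  DBSCAN (minSamp = expected minimum breaths in the window, eps from the
  diagram spread) -> the signal cluster's point count must match the
  physiologic breathing range and its lifespans must dominate the noise
  cluster and a fraction of the amplitude range.

A window shows breathing if both branches agree, or if a single branch
passes strict (tightened-threshold) versions of its criteria.

Heartbeat uses only the sublevel branch on the 0.65-5 Hz band-passed
series, with minSamp from the lowest expected heart rate and eps as a
fixed fraction of the amplitude range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal
from sklearn.cluster import DBSCAN

from . import tda
from .epoching import WindowGrid, make_windows
from .processing import RangeTimeMatrix, all_phases

_EPS_FLOOR = 1e-12


@dataclass(frozen=True)
class SelectionCriteria:
    """All empirical thresholds of the selection algorithm.

    The bands and minSamp rates are from physiology; the factors are
    empirical defaults exposed for sensitivity analysis.
    """

    breathing_band_bpm: tuple[float, float] = (10.0, 22.0)
    heartbeat_band_bpm: tuple[float, float] = (40.0, 200.0)
    breathing_lowpass_hz: float = 5.0
    heartbeat_band_hz: tuple[float, float] = (0.65, 5.0)
    filter_order: int = 4
    dbscan_min_samples_vr: int = 2
    birth_proximity_tol: float = 0.2
    lifespan_dominance_factor: float = 2.0
    sublevel_amp_fraction: float = 0.25
    heartbeat_amp_fraction: float = 0.6
    strict_factor: float = 2.5
    heartbeat_eps_fraction: float = 0.15
    embedding: tda.EmbeddingParams = field(default_factory=tda.EmbeddingParams)
    vr_max_points: int = 48
    spread_mode: str = "connection"
    minsamp_per_window: bool = True

    def breathing_count_range(self, window_s: float) -> tuple[int, int]:
        lo, hi = self.breathing_band_bpm
        return int(np.floor(lo * window_s / 60.0)), int(np.ceil(hi * window_s / 60.0))

    def heartbeat_count_range(self, window_s: float) -> tuple[int, int]:
        lo, hi = self.heartbeat_band_bpm
        return int(np.floor(lo * window_s / 60.0)), int(np.ceil(hi * window_s / 60.0))

    def sublevel_min_samples(self, window_s: float) -> int:
        if not self.minsamp_per_window:
            return int(self.breathing_band_bpm[0])
        return max(self.breathing_count_range(window_s)[0], 1)

    def heartbeat_min_samples(self, window_s: float) -> int:
        if not self.minsamp_per_window:
            return int(self.heartbeat_band_bpm[0])
        return max(self.heartbeat_count_range(window_s)[0], 1)


@dataclass(frozen=True)
class BranchVerdict:
    decision: bool
    strict_decision: bool
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strict_decision and not self.decision:
            raise ValueError("strict_decision implies decision")


@dataclass
class SelectionMask:
    """Boolean [bin x window] selection plus window metadata."""

    selected: np.ndarray
    bin_indices: np.ndarray
    window_starts_s: np.ndarray
    window_length_s: float
    vital: str


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _sos(kind: str, fs: float, order: int, lo: float, hi: float):
    nyq = fs / 2.0
    if kind == "lowpass":
        if hi >= nyq:
            raise ValueError(f"cutoff {hi} Hz >= Nyquist {nyq} Hz")
        return signal.butter(order, hi, btype="low", fs=fs, output="sos")
    if hi >= nyq:
        raise ValueError(f"upper cutoff {hi} Hz >= Nyquist {nyq} Hz")
    return signal.butter(order, (lo, hi), btype="band", fs=fs, output="sos")


def band_filter(series: np.ndarray, kind: str, fs: float,
                criteria: SelectionCriteria | None = None) -> np.ndarray:
    """Zero-phase Butterworth filter for one vital sign.

    ``kind="breathing"``: low-pass at 5 Hz.  ``kind="heartbeat"``:
    band-pass 0.65-5 Hz, which removes the breathing component.
    """
    criteria = criteria or SelectionCriteria()
    x = np.asarray(series, dtype=float)
    if kind == "breathing":
        sos = _sos("lowpass", fs, criteria.filter_order,
                   0.0, criteria.breathing_lowpass_hz)
    elif kind == "heartbeat":
        lo, hi = criteria.heartbeat_band_hz
        sos = _sos("bandpass", fs, criteria.filter_order, lo, hi)
    else:
        raise ValueError(f"kind must be 'breathing' or 'heartbeat', got {kind!r}")
    return signal.sosfiltfilt(sos, x, axis=-1)


# ---------------------------------------------------------------------------
# DBSCAN on diagram points
# ---------------------------------------------------------------------------


def dbscan_diagram(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Standard DBSCAN labels for birth-lifespan diagram points.

    Label -1 marks DBSCAN noise, which the selection logic interprets as
    informative outlier candidates.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return np.empty(0, dtype=int)
    eps = max(float(eps), _EPS_FLOOR)
    return DBSCAN(eps=eps, min_samples=min_samples).fit(pts).labels_


def _spread_eps(points: np.ndarray, criteria: SelectionCriteria) -> float:
    try:
        return tda.diagram_spread(points, mode=criteria.spread_mode)
    except ValueError:
        return 0.0


def _cluster_stats(points: np.ndarray, labels: np.ndarray):
    """Split diagram points into signal/noise clusters by mean lifespan.

    Returns (signal_points, noise_points, n_clusters).  The signal cluster
    has the highest mean lifespan, the noise cluster the lowest; points of
    intermediate clusters are ignored.  DBSCAN outliers are not part of
    either cluster.
    """
    ids = sorted(set(labels) - {-1})
    if not ids:
        return None, None, 0
    means = [points[labels == c][:, 1].mean() for c in ids]
    sig = points[labels == ids[int(np.argmax(means))]]
    noi = points[labels == ids[int(np.argmin(means))]]
    return sig, noi, len(ids)


# ---------------------------------------------------------------------------
# Breathing: Vietoris-Rips branch
# ---------------------------------------------------------------------------


def _vr_outlier_tests(outliers, noise, max_h0_death, max_h0_life,
                      tol, factor, evidence):
    """Birth and lifespan criteria for VR-branch outlier points."""
    if noise is not None and len(noise):
        nb_lo, nb_hi = noise[:, 0].min(), noise[:, 0].max()
        mid, half = (nb_lo + nb_hi) / 2.0, (nb_hi - nb_lo) / 2.0
        noise_life = float(noise[:, 1].max())
    else:
        mid = half = None
        noise_life = 0.0
    life_floor = factor * max(noise_life, max_h0_life)
    for birth, life in outliers:
        near_h0 = abs(birth - max_h0_death) <= tol * max_h0_death
        # tightened tol shrinks the allowed noise-birth interval too
        in_noise = (mid is not None
                    and abs(birth - mid) <= half * min(tol / 0.2, 1.0))
        if (near_h0 or in_noise) and life >= life_floor:
            evidence["passing_outlier"] = (float(birth), float(life))
            return True
    return False


def breathing_vr_branch(series: np.ndarray,
                        criteria: SelectionCriteria | None = None) -> BranchVerdict:
    """Vietoris-Rips branch of breathing detection.

    ``series`` must already be low-pass filtered and sampled at the frame
    rate; a 15 s window at 20 Hz gives 300 samples.
    """
    criteria = criteria or SelectionCriteria()
    x = np.asarray(series, dtype=float)
    evidence: dict = {"branch": "vr"}
    span = (criteria.embedding.m - 1) * criteria.embedding.tau
    if len(x) <= span or np.ptp(x) <= 0:
        return BranchVerdict(False, False, evidence | {"reason": "degenerate"})

    cloud = tda.time_delay_embed(x, criteria.embedding)
    cloud = tda.farthest_point_subsample(cloud, criteria.vr_max_points)
    diagrams = tda.rips_persistence(cloud, maxdim=1)
    h0 = tda.to_birth_lifespan(diagrams[0])
    h1 = tda.to_birth_lifespan(diagrams[1])
    if len(h1) == 0:
        return BranchVerdict(False, False, evidence | {"reason": "no_h1"})

    eps = _spread_eps(h1.pairs, criteria)
    labels = dbscan_diagram(h1.pairs, eps, criteria.dbscan_min_samples_vr)
    outliers = h1.pairs[labels == -1]
    clustered = h1.pairs[labels != -1]
    noise = clustered if len(clustered) else None
    if len(outliers) == 0:
        return BranchVerdict(False, False, evidence | {"reason": "no_outliers"})

    max_h0_death = float(h0.deaths.max()) if len(h0) else 0.0
    max_h0_life = float(h0.lifespans.max()) if len(h0) else 0.0
    evidence.update(n_outliers=len(outliers), eps=eps,
                    max_h0_death=max_h0_death, max_h0_life=max_h0_life)

    tol = criteria.birth_proximity_tol
    factor = criteria.lifespan_dominance_factor
    strict = criteria.strict_factor
    decision = _vr_outlier_tests(outliers, noise, max_h0_death, max_h0_life,
                                 tol, factor, evidence)
    strict_decision = decision and _vr_outlier_tests(
        outliers, noise, max_h0_death, max_h0_life,
        tol / strict, factor * strict, {})
    return BranchVerdict(decision, strict_decision, evidence)


# ---------------------------------------------------------------------------
# Sublevel branches (breathing and heartbeat)
# ---------------------------------------------------------------------------


def _sublevel_cluster_decision(x, min_samples, eps, count_range,
                               factor, amp_fraction, evidence) -> bool:
    diagram = tda.to_birth_lifespan(tda.sublevel_persistence(x))
    if len(diagram) == 0:
        evidence["reason"] = "empty_diagram"
        return False
    labels = dbscan_diagram(diagram.pairs, eps, min_samples)
    sig, noi, n_clusters = _cluster_stats(diagram.pairs, labels)
    evidence["n_clusters"] = n_clusters
    if sig is None:
        evidence["reason"] = "no_clusters"
        return False
    if n_clusters < 2:
        # no distinct noise cluster: DBSCAN outliers below the signal
        # cluster stand in; a clean window may have no noise points at
        # all, in which case the count criterion does the rejecting
        out_pts = diagram.pairs[labels == -1]
        below = out_pts[out_pts[:, 1] < sig[:, 1].min()] if len(out_pts) else out_pts
        noi = below if len(below) else None
        evidence["no_noise_cluster"] = True
    n_sig = len(sig)
    evidence["signal_count"] = n_sig
    if not (count_range[0] <= n_sig <= count_range[1]):
        evidence["reason"] = "count_out_of_range"
        return False
    noise_life = float(noi[:, 1].max()) if noi is not None and len(noi) else 0.0
    sig_life = float(np.median(sig[:, 1]))
    amp = float(np.ptp(x))
    evidence.update(signal_lifespan=sig_life, noise_lifespan=noise_life, amplitude=amp)
    ok = sig_life >= factor * noise_life and sig_life >= amp_fraction * amp
    if not ok:
        evidence["reason"] = "lifespan_too_small"
    return ok


def breathing_sublevel_branch(series: np.ndarray,
                              criteria: SelectionCriteria | None = None,
                              window_s: float | None = None,
                              fs: float = 20.0) -> BranchVerdict:
    """Sublevel-set branch of breathing detection (low-pass filtered input)."""
    criteria = criteria or SelectionCriteria()
    x = np.asarray(series, dtype=float)
    window_s = window_s if window_s is not None else len(x) / fs
    evidence: dict = {"branch": "sublevel"}
    if len(x) < 2 or np.ptp(x) <= 0:
        return BranchVerdict(False, False, evidence | {"reason": "degenerate"})

    diagram = tda.to_birth_lifespan(tda.sublevel_persistence(x))
    eps = _spread_eps(diagram.pairs, criteria)
    min_samples = criteria.sublevel_min_samples(window_s)
    count_range = criteria.breathing_count_range(window_s)
    factor = criteria.lifespan_dominance_factor
    fraction = criteria.sublevel_amp_fraction
    strict = criteria.strict_factor
    decision = _sublevel_cluster_decision(
        x, min_samples, eps, count_range, factor, fraction, evidence)
    strict_decision = decision and _sublevel_cluster_decision(
        x, min_samples, eps, count_range, factor * strict, fraction * strict, {})
    return BranchVerdict(decision, strict_decision, evidence)


def combine_breathing(vr: BranchVerdict, sl: BranchVerdict) -> bool:
    """Final breathing rule: both branches agree, or one passes strictly."""
    return (vr.decision and sl.decision) or vr.strict_decision or sl.strict_decision


def heartbeat_selection(series: np.ndarray,
                        criteria: SelectionCriteria | None = None,
                        window_s: float | None = None,
                        fs: float = 20.0) -> BranchVerdict:
    """Heartbeat detection: sublevel branch only, on the band-passed series.

    eps is a fixed fraction of the amplitude range (the data-driven spread
    did not work well for heartbeat diagrams); the count range corresponds
    to 40-200 BPM.  The branch verdict is the final output.
    """
    criteria = criteria or SelectionCriteria()
    x = np.asarray(series, dtype=float)
    window_s = window_s if window_s is not None else len(x) / fs
    evidence: dict = {"branch": "heartbeat"}
    if len(x) < 2 or np.ptp(x) <= 0:
        return BranchVerdict(False, False, evidence | {"reason": "degenerate"})

    eps = criteria.heartbeat_eps_fraction * float(np.ptp(x))
    min_samples = criteria.heartbeat_min_samples(window_s)
    count_range = criteria.heartbeat_count_range(window_s)
    factor = criteria.lifespan_dominance_factor
    fraction = criteria.heartbeat_amp_fraction
    strict = criteria.strict_factor
    decision = _sublevel_cluster_decision(
        x, min_samples, eps, count_range, factor, fraction, evidence)
    strict_decision = decision and _sublevel_cluster_decision(
        x, min_samples, eps, count_range, factor * strict, fraction * strict, {})
    return BranchVerdict(decision, strict_decision, evidence)


# ---------------------------------------------------------------------------
# Full selection over a recording
# ---------------------------------------------------------------------------


def select_bins(matrix: RangeTimeMatrix, grid: WindowGrid | None = None,
                criteria: SelectionCriteria | None = None,
                *, collect_evidence: bool = False):
    """Run breathing and heartbeat selection on every (bin, window).

    ``matrix`` must be frame-level and already bin-restricted.  Filtering is
    applied once per bin over the whole recording (zero-phase, so window
    content is unaffected apart from negligible edge transients), then
    windowed.  Per-bin failures are recorded as "not selected".

    Returns ``(breathing_mask, heartbeat_mask, evidence)`` where evidence is
    a list of per-(window, bin) records (empty unless requested).
    """
    grid = grid or WindowGrid()
    criteria = criteria or SelectionCriteria()
    if matrix.level != "frame":
        raise ValueError("select_bins expects a frame-level matrix "
                         "(apply chirp_median or first_chirp)")
    fs = matrix.fs
    duration = matrix.n_cols / fs
    windows = make_windows(duration, grid)
    phases = all_phases(matrix)
    low = band_filter(phases, "breathing", fs, criteria)
    band = band_filter(phases, "heartbeat", fs, criteria)

    n_bins = matrix.n_bins
    breath = np.zeros((n_bins, len(windows)), dtype=bool)
    heart = np.zeros((n_bins, len(windows)), dtype=bool)
    evidence = []
    for w, win in enumerate(windows):
        sl = win.sample_slice(fs)
        for b in range(n_bins):
            try:
                vr = breathing_vr_branch(low[b, sl], criteria)
                sub = breathing_sublevel_branch(low[b, sl], criteria,
                                                win.length_s, fs)
                breath[b, w] = combine_breathing(vr, sub)
                hb = heartbeat_selection(band[b, sl], criteria,
                                         win.length_s, fs)
                heart[b, w] = hb.decision
            except Exception as exc:  # defensive: never abort the sweep
                evidence.append({"window": w, "bin": int(matrix.bin_indices[b]),
                                 "error": repr(exc)})
                continue
            if collect_evidence:
                evidence.append({
                    "window": w, "window_start_s": win.start_s,
                    "bin": int(matrix.bin_indices[b]),
                    "vr": vr.evidence | {"decision": vr.decision,
                                         "strict": vr.strict_decision},
                    "sublevel": sub.evidence | {"decision": sub.decision,
                                                "strict": sub.strict_decision},
                    "heartbeat": hb.evidence | {"decision": hb.decision},
                })
    starts = np.array([w.start_s for w in windows])
    return (
        SelectionMask(breath, matrix.bin_indices, starts,
                      grid.window_length_s, "breathing"),
        SelectionMask(heart, matrix.bin_indices, starts,
                      grid.window_length_s, "heartbeat"),
        evidence,
    )
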