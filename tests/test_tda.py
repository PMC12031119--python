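"""TDA core: embeddings, sublevel/Rips persistence, diagram utilities.

The sublevel and Rips implementations are checked against independent
oracles: a threshold-sweep/connected-component oracle built on
scipy.ndimage.label, and explicit minimum spanning trees from
scipy.sparse.csgraph.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from radarvitals import tda

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def sublevel_oracle(values):
    """Brute-force H0 sublevel persistence: sweep every sample value,
    track components via scipy.ndimage.label, record merges (elder rule).
    """
    values = np.asarray(values, dtype=float)
    levels = np.unique(values)
    birth_of = {}   # component representative (leftmost index) -> birth value
    pairs = []
    prev_labels = np.zeros(len(values), dtype=int)
    for level in levels:
        labels, n = ndimage.label(values <= level)
        for c in range(1, n + 1):
            idx = np.flatnonzero(labels == c)
            # previous components swallowed by this one
            old = sorted({prev_labels[i] for i in idx if prev_labels[i] > 0})
            reps = [min(np.flatnonzero(prev_labels == o)) for o in old]
            if not reps:
                birth_of[idx[0]] = level
            else:
                births = [(birth_of[r], r) for r in reps]
                births.sort()
                elder = births[0][1]
                for b, r in births[1:]:
                    if level > b:
                        pairs.append((b, level))
                    del birth_of[r]
                new_rep = min(idx)
                if new_rep != elder:
                    birth_of[new_rep] = birth_of.pop(elder)
        prev_labels = labels
    # essential component closes at the global max
    (rep, birth), = birth_of.items()
    if values.max() > birth:
        pairs.append((birth, values.max()))
    return sorted(pairs)


def mst_edge_lengths(points):
    d = squareform(pdist(points))
    mst = minimum_spanning_tree(d).toarray()
    return np.sort(mst[mst > 0])


# ---------------------------------------------------------------------------
# time_delay_embed
# ---------------------------------------------------------------------------


class TestTimeDelayEmbed:
    def test_definition(self):
        cloud = tda.time_delay_embed([0, 1, 2, 3, 4], tda.EmbeddingParams(tau=1, m=2))
        assert cloud.tolist() == [[1, 0], [2, 1], [3, 2], [4, 3]]

    def test_constant_series_degenerate_cloud(self):
        cloud = tda.time_delay_embed(np.ones(50), tda.EmbeddingParams())
        assert np.allclose(cloud, cloud[0])
        assert len(cloud) == 50 - 2 * 10

    def test_sine_quarter_period_circle(self):
        x = np.sin(2 * np.pi * np.arange(400) / 40)
        cloud = tda.time_delay_embed(x, tda.EmbeddingParams(tau=10, m=2))
        radius = np.linalg.norm(cloud, axis=1)
        assert np.max(np.abs(radius - 1.0)) < 1e-6

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            tda.time_delay_embed(np.zeros(20), tda.EmbeddingParams(tau=10, m=3))

    def test_point_count(self):
        p = tda.EmbeddingParams(tau=3, m=4)
        cloud = tda.time_delay_embed(np.arange(100.0), p)
        assert len(cloud) == 100 - (p.m - 1) * p.tau

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            tda.EmbeddingParams(tau=0)
        with pytest.raises(ValueError):
            tda.EmbeddingParams(m=1)


# ---------------------------------------------------------------------------
# sublevel_persistence
# ---------------------------------------------------------------------------


class TestSublevelPersistence:
    def test_hand_run_example(self):
        d = tda.sublevel_persistence([0.0, 1.0, 0.2, 0.8, 0.1, 1.0])
        got = sorted(map(tuple, d.pairs))
        assert got == [(0.0, 1.0), (0.1, 1.0), (0.2, 0.8)]

    def test_monotone_series_single_pair(self):
        d = tda.sublevel_persistence(np.linspace(-2.0, 5.0, 30))
        assert sorted(map(tuple, d.pairs)) == [(-2.0, 5.0)]

    def test_sine_pair_count_and_lifespan(self):
        # k full periods -> k+O(1) pairs, lifespans ~ peak-to-peak
        k = 5
        x = np.sin(2 * np.pi * k * np.arange(500) / 500)
        d = tda.sublevel_persistence(x)
        assert abs(len(d) - k) <= 1
        # full oscillations span the peak-to-peak range; the boundary
        # half-oscillation may contribute one smaller pair
        assert np.sum(d.lifespans > 1.9) >= k - 1

    def test_matches_oracle_on_random_series(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 101))
            x = np.round(rng.standard_normal(n), 3)  # induce ties
            got = sorted(map(tuple, tda.sublevel_persistence(x).pairs))
            want = sublevel_oracle(x)
            assert np.allclose(got, want), f"mismatch for {x!r}"

    def test_shift_invariance(self, rng):
        x = rng.standard_normal(80)
        a = tda.sublevel_persistence(x)
        b = tda.sublevel_persistence(x + 7.5)
        assert np.allclose(a.pairs + 7.5, b.pairs)
        assert np.allclose(a.lifespans, b.lifespans)

    def test_pair_count_equals_local_minima(self, rng):
        for _ in range(50):
            x = rng.standard_normal(60)  # continuous: ties a.s. absent
            n_min = np.sum((x[1:-1] < x[:-2]) & (x[1:-1] < x[2:]))
            n_min += x[0] < x[1]
            n_min += x[-1] < x[-2]
            assert len(tda.sublevel_persistence(x)) == n_min

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            tda.sublevel_persistence([0.0, np.nan, 1.0])

    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_oracle_equivalence_property(self, xs):
        got = sorted(map(tuple, tda.sublevel_persistence(xs).pairs))
        assert np.allclose(got, sublevel_oracle(xs)) or got == sublevel_oracle(xs)


# ---------------------------------------------------------------------------
# rips_persistence
# ---------------------------------------------------------------------------


class TestRipsPersistence:
    def test_two_points(self):
        d = tda.rips_persistence(np.array([[0.0, 0.0], [3.0, 4.0]]), maxdim=1)
        assert np.allclose(d[0].pairs, [[0.0, 5.0]])
        assert len(d[1]) == 0

    def test_unit_square_h1(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = tda.rips_persistence(square, maxdim=1)
        assert np.allclose(np.sort(d[0].deaths), [1, 1, 1])
        assert np.allclose(d[1].pairs, [[1.0, np.sqrt(2.0)]])

    def test_h0_deaths_equal_mst_edges(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 51))
            pts = rng.standard_normal((n, int(rng.integers(2, 4))))
            d = tda.rips_persistence(pts, maxdim=0)
            assert np.allclose(np.sort(d[0].deaths), mst_edge_lengths(pts))

    def test_circle_h1_death_closed_form(self):
        # dense circle of radius R: the loop dies at sqrt(3) R
        R = 2.0
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        pts = R * np.column_stack([np.cos(theta), np.sin(theta)])
        d = tda.rips_persistence(pts, maxdim=1)
        top = d[1].pairs[np.argmax(d[1].lifespans)]
        assert abs(top[1] - np.sqrt(3) * R) / (np.sqrt(3) * R) < 0.05

    def test_h1_deaths_at_least_births(self, rng):
        pts = rng.standard_normal((40, 3))
        d = tda.rips_persistence(pts, maxdim=1)
        assert np.all(d[1].deaths > d[1].births)

    def test_single_point(self):
        d = tda.rips_persistence(np.zeros((1, 3)), maxdim=1)
        assert len(d[0]) == 0 and len(d[1]) == 0

    def test_large_cloud_guard(self):
        pts = np.zeros((10_001, 2))
        with pytest.raises(ValueError, match="subsample"):
            tda.rips_persistence(pts, maxdim=0)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            tda.rips_persistence(np.empty((0, 2)))


# ---------------------------------------------------------------------------
# to_birth_lifespan / diagram_spread / subsampling
# ---------------------------------------------------------------------------


class TestDiagramUtilities:
    def test_birth_lifespan_transform(self):
        d = tda.PersistenceDiagram(0, [[0.2, 0.8]])
        bl = tda.to_birth_lifespan(d)
        assert np.allclose(bl.pairs, [[0.2, 0.6]])

    def test_empty_diagram(self):
        d = tda.PersistenceDiagram(1, np.empty((0, 2)))
        assert len(tda.to_birth_lifespan(d)) == 0

    def test_involution(self, rng):
        b = rng.uniform(0, 1, 20)
        pairs = np.column_stack([b, b + rng.uniform(0, 1, 20)])
        d = tda.PersistenceDiagram(1, pairs)
        back = tda.to_birth_death(tda.to_birth_lifespan(d))
        assert np.allclose(back.pairs, d.pairs)

    def test_spread_collinear(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]])
        assert tda.diagram_spread(pts) == pytest.approx(4.0)

    def test_spread_two_points(self):
        assert tda.diagram_spread(np.array([[0, 0], [0, 3.0]])) == pytest.approx(3.0)

    def test_spread_equilateral_triangle(self):
        s = 2.0
        pts = s * np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        assert tda.diagram_spread(pts) == pytest.approx(s)

    def test_spread_single_point_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            tda.diagram_spread(np.array([[1.0, 1.0]]))

    def test_spread_diameter_mode(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]])
        assert tda.diagram_spread(pts, mode="diameter") == pytest.approx(5.0)

    def test_fps_subsample(self, rng):
        pts = rng.standard_normal((200, 3))
        sub = tda.farthest_point_subsample(pts, 50)
        assert sub.shape == (50, 3)
        # selected points are actual cloud members
        assert all(any(np.allclose(s, p) for p in pts) for s in sub[:5])
        # small clouds pass through untouched
        assert np.allclose(tda.farthest_point_subsample(pts[:10], 50), pts[:10])
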