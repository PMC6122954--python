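"""Correlations, rate maps, field detection, trace persistence."""

import numpy as np
import pytest

from scenemem.analysis import (
    RateMap,
    SimulationTrace,
    compute_rate_map,
    correlation_report,
    detect_trace_field,
    detect_vector_field,
    novelty_mismatch,
    population_vector_correlation,
    read_trace,
    write_trace,
)
from scenemem.geometry import AgentState


def synthetic_trace(rng, n_steps=600, n_cells=30, tuning_center=None):
    """Trace of a random walk with one planted Gaussian-tuned cell."""
    tr = SimulationTrace(populations=("X",))
    tr.meta["extent"] = (0.0, 0.0, 100.0, 100.0)
    pos = np.array([50.0, 50.0])
    for t in range(n_steps):
        pos = np.clip(pos + rng.normal(0, 2.0, 2), 2, 98)
        rates = rng.random(n_cells) * 0.05
        if tuning_center is not None:
            d2 = ((pos - tuning_center) ** 2).sum()
            rates[0] = np.exp(-0.5 * d2 / 10.0**2)
        tr.record(t, AgentState(pos.copy(), 0.0), "bottom_up", {"X": rates},
                  None)
    return tr


class TestCorrelation:
    def test_identical_vectors(self, rng):
        v = rng.random(50)
        assert population_vector_correlation(v, v) == pytest.approx(1.0)

    def test_complement_is_anticorrelated(self, rng):
        v = rng.random(50)
        assert population_vector_correlation(v, 3.0 - v) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        a = np.array([0.1, 0.5, 0.9, 0.2, 0.7])
        b = np.array([0.3, 0.4, 0.8, 0.1, 0.9])
        am, bm = a - a.mean(), b - b.mean()
        expect = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
        assert population_vector_correlation(a, b) == pytest.approx(expect)

    def test_symmetry_and_affine_invariance(self, rng):
        a, b = rng.random(40), rng.random(40)
        r = population_vector_correlation(a, b)
        assert population_vector_correlation(b, a) == pytest.approx(r)
        assert population_vector_correlation(2.5 * a + 0.3, b) == \
            pytest.approx(r)

    def test_both_constant_raises(self):
        with pytest.raises(ValueError):
            population_vector_correlation(np.ones(5), np.ones(5))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            population_vector_correlation(np.ones(5), np.ones(6))


class TestCorrelationReport:
    def test_recall_equal_to_encoding_gives_unity(self, rng):
        tr = SimulationTrace(populations=("X",))
        pattern = rng.random(20)
        for t in range(400):
            snap = {"X": rng.random(20)} if t < 300 else {"X": pattern}
            mode = "bottom_up" if t < 300 else "top_down"
            tr.record(t, AgentState(np.zeros(2), 0.0), mode, snap, None)
        rep = correlation_report(tr, {"X": pattern}, (300, 400),
                                 sample_every=50, populations=["X"])
        assert rep.rve["X"] == pytest.approx(1.0)
        assert rep.n_samples["X"] == len(np.arange(0, 300)[::50])

    def test_sample_count_honors_interval(self, rng):
        tr = SimulationTrace(populations=("X",))
        for t in range(1050):
            tr.record(t, AgentState(np.zeros(2), 0.0),
                      "bottom_up" if t < 1000 else "top_down",
                      {"X": rng.random(10)}, None)
        rep = correlation_report(tr, {"X": rng.random(10)}, (1000, 1050),
                                 sample_every=100, populations=["X"])
        assert abs(rep.n_samples["X"] - 10) <= 1


class TestNoveltyMismatch:
    def test_identical_patterns_zero(self, rng):
        v = rng.random(30)
        assert novelty_mismatch({"1": v}, {"1": v.copy()})["1"] == \
            pytest.approx(0.0)

    def test_disjoint_patterns_high(self):
        a = np.zeros(30); a[:5] = 1.0
        b = np.zeros(30); b[20:25] = 1.0
        assert novelty_mismatch({"1": a}, {"1": b})["1"] > 0.9

    def test_object_set_mismatch_raises(self, rng):
        with pytest.raises(KeyError):
            novelty_mismatch({"1": rng.random(5)}, {"2": rng.random(5)})


class TestRateMap:
    def test_occupancy_conserved(self, rng):
        tr = synthetic_trace(rng, n_steps=500)
        m = compute_rate_map(tr, "X", 0, bin_size=5.0)
        assert m.occupancy.sum() == 500

    def test_silent_cell_all_zero(self, rng):
        tr = synthetic_trace(rng, n_steps=300)
        tr._rates["X"] = [np.zeros(30, dtype=np.float32) for _ in range(300)]
        m = compute_rate_map(tr, "X", 0, bin_size=5.0)
        vals = m.rate[~np.isnan(m.rate)]
        assert (vals == 0).all()

    def test_constant_cell_uniform(self, rng):
        tr = synthetic_trace(rng, n_steps=300)
        tr._rates["X"] = [np.full(30, 0.4, dtype=np.float32)
                          for _ in range(300)]
        m = compute_rate_map(tr, "X", 0, bin_size=5.0)
        vals = m.rate[~np.isnan(m.rate)]
        assert np.allclose(vals, 0.4, atol=1e-6)

    def test_planted_gaussian_recovered(self, rng):
        center = np.array([35.0, 65.0])
        tr = synthetic_trace(rng, n_steps=4000, tuning_center=center)
        m = compute_rate_map(tr, "X", 0, bin_size=4.0, smooth_bins=1.0)
        r = np.nan_to_num(m.rate, nan=0.0)
        cx, cy = m.bin_centers()
        ix, iy = np.unravel_index(r.argmax(), r.shape)
        assert np.hypot(cx[ix] - center[0], cy[iy] - center[1]) <= 2 * 4.0


class TestFieldDetection:
    def _map_with_fields(self, centers, extent=(0, 0, 100, 100), bin_size=4.0):
        ex = np.arange(extent[0], extent[2] + bin_size, bin_size)
        ey = np.arange(extent[1], extent[3] + bin_size, bin_size)
        cx = 0.5 * (ex[:-1] + ex[1:])
        cy = 0.5 * (ey[:-1] + ey[1:])
        X, Y = np.meshgrid(cx, cy, indexing="ij")
        r = np.zeros_like(X)
        for c in centers:
            r += np.exp(-0.5 * ((X - c[0]) ** 2 + (Y - c[1]) ** 2) / 5.0**2)
        return RateMap(r, np.ones_like(r), ex, ey)

    def test_planted_offsets_recovered(self):
        objs = np.array([[30.0, 30.0], [70.0, 60.0], [40.0, 75.0]])
        offset = np.array([8.0, -6.0])
        m = self._map_with_fields(objs + offset)
        res = detect_vector_field(m, objs)
        for off, _ in res:
            assert np.abs(off - offset).max() <= 4.0

    def test_single_field(self):
        m = self._map_with_fields([[50.0, 50.0]])
        res = detect_vector_field(m, [[45.0, 45.0]])
        assert len(res) == 1

    def test_empty_map_raises(self):
        m = self._map_with_fields([])
        with pytest.raises(ValueError):
            detect_vector_field(m, [[50.0, 50.0]])

    def test_trace_field_against_segment(self):
        seg = np.array([[40.0, 45.0], [40.0, 75.0]])
        # cell tuned 10 cm East: fires 10 cm West of the boundary
        m = self._map_with_fields([[30.0, 60.0]])
        present, peak, dist = detect_trace_field(
            m, seg, preferred_offset=(10.0, 0.0)
        )
        assert present and dist < 2.0
        absent, _, far = detect_trace_field(
            m, seg, preferred_offset=(-30.0, 0.0)
        )
        assert not absent and far > 15.0


class TestTracePersistence:
    def test_lossless_round_trip(self, rng, tmp_path):
        tr = synthetic_trace(rng, n_steps=50)
        tr.events.append((10, "1", 20.0, 30.0, 0.5))
        tr.mark_segment("recall", 30, 50)
        path = tmp_path / "trace.h5"
        write_trace(tr, path)
        back = read_trace(path)
        assert np.array_equal(back.rates("X"), tr.rates("X"))
        assert np.array_equal(back.pose, tr.pose)
        assert back.events == tr.events
        assert back.segments == tr.segments

    def test_empty_trace_round_trip(self, tmp_path):
        tr = SimulationTrace(populations=("X",))
        path = tmp_path / "empty.h5"
        write_trace(tr, path)
        assert len(read_trace(path)) == 0

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(OSError):
            read_trace(tmp_path / "nope.h5")

    def test_timestamps_must_increase(self, rng):
        tr = synthetic_trace(rng, n_steps=5)
        with pytest.raises(ValueError):
            tr.record(2, AgentState(np.zeros(2), 0.0), "bottom_up",
                      {"X": np.zeros(30)}, None)


class TestRendering:
    def test_snapshot_and_rate_map_pngs(self, grid, rng, tmp_path):
        from scenemem.analysis import render_polar_snapshot, render_rate_map

        render_polar_snapshot(grid, rng.random(grid.n_cells),
                              tmp_path / "snap.png", ego=True)
        m = TestFieldDetection()._map_with_fields([[50.0, 50.0]])
        render_rate_map(m, tmp_path / "map.png")
        assert (tmp_path / "snap.png").stat().st_size > 1000
        assert (tmp_path / "map.png").stat().st_size > 1000
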