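"""The medial-temporal attractor: training, Hebbian encoding, completion."""

import numpy as np
import pytest

from scenemem.memory import (
    BindingAmbiguityError,
    MTLState,
    encode_object_event,
    hebbian_update,
    load_weights,
    pattern_complete,
    save_weights,
    train_context,
)
from scenemem.populations import hd_init, place_rates


def stored_state(weights, layout, grid, p, competition):
    s = MTLState.zeros(layout.n_cells, grid.n_cells,
                       weights.n_prb, weights.n_pro)
    s.pc = place_rates(layout, weights.pc_drive_from_bvc(weights.stored_bvc[p]),
                       n_steps=200, competition=competition)
    s.bvc = weights.stored_bvc[p].copy()
    s.prb = weights.stored_prb[p].copy()
    return s


def mask_half(v, rng, thr=0.02):
    active = np.nonzero(v > thr)[0]
    kill = rng.choice(active, len(active) // 2, replace=False)
    out = v.copy()
    out[kill] = 0.0
    return out


class TestTrainContext:
    def test_center_pattern_shows_four_equidistant_walls(self, trained_weights,
                                                         layout, grid):
        p = int(np.argmin(np.hypot(*(layout.centers - [50, 50]).T)))
        pat = trained_weights.stored_bvc[p]
        d, a = grid.cell_tuning()
        rates = []
        for ang in (0, np.pi / 2, np.pi, 3 * np.pi / 2):
            sel = (np.abs(np.angle(np.exp(1j * (a - ang)))) < np.deg2rad(8)) \
                & (np.abs(d - 50) < 10)
            rates.append(pat[sel].max())
        assert min(rates) > 0.5
        assert max(rates) - min(rates) < 0.3 * max(rates)

    def test_every_stored_pattern_is_fixed_point(self, trained_weights, layout,
                                                 grid, competition, rng):
        picks = list(rng.choice(layout.n_cells, 8, replace=False)) + [0, 242]
        for p in picks:
            s = stored_state(trained_weights, layout, grid, p, competition)
            out, _ = pattern_complete(s, trained_weights, n_steps=600,
                                      competition=competition)
            assert np.corrcoef(out.bvc, s.bvc)[0, 1] >= 0.95
            assert np.corrcoef(out.pc, s.pc)[0, 1] >= 0.95

    def test_barrier_present_in_stored_patterns(self, layout, grid):
        from scenemem.experiments import barrier_arena

        env = barrier_arena(100.0)
        w = train_context(env, layout, grid)
        # location just East of the barrier: West-tuned short-range cells
        # must respond in the stored pattern
        p = int(np.argmin(np.hypot(*(layout.centers - [48, 60]).T)))
        d, a = grid.cell_tuning()
        sel = (np.abs(np.angle(np.exp(1j * (a - np.pi)))) < np.deg2rad(10)) \
            & (d < 15)
        assert w.stored_bvc[p][sel].max() > 0.4

    def test_recovery_from_own_pc_cue(self, trained_weights, layout, grid,
                                      competition):
        p = 250
        s = stored_state(trained_weights, layout, grid, p, competition)
        cue = MTLState.zeros(layout.n_cells, grid.n_cells,
                             trained_weights.n_prb, trained_weights.n_pro)
        cue.pc = s.pc.copy()
        out, _ = pattern_complete(cue, trained_weights, n_steps=600,
                                  competition=competition)
        assert np.corrcoef(out.bvc, s.bvc)[0, 1] >= 0.95


class TestBasins:
    def test_half_deleted_cues_recover_the_cued_memory(
        self, trained_weights, layout, grid, competition, rng
    ):
        for p in rng.choice(layout.n_cells, 20, replace=False):
            s = stored_state(trained_weights, layout, grid, p, competition)
            cue = s.copy()
            cue.bvc = mask_half(s.bvc, rng)
            cue.pc = mask_half(s.pc, rng)
            out, _ = pattern_complete(cue, trained_weights, n_steps=600,
                                      competition=competition)
            concat_out = np.concatenate([out.pc, out.bvc, out.prb])
            concat_ref = np.concatenate([s.pc, s.bvc, s.prb])
            assert np.corrcoef(concat_out, concat_ref)[0, 1] >= 0.9
            from scenemem.populations import decode_position

            off = np.hypot(*(decode_position(out.pc, layout)
                             - layout.centers[p]))
            assert off <= layout.spacing + 1e-9

    def test_prb_only_cue_settles_into_a_trained_pattern(
        self, trained_weights, layout, grid, competition
    ):
        cue = MTLState.zeros(layout.n_cells, grid.n_cells,
                             trained_weights.n_prb, trained_weights.n_pro)
        cue.prb = np.ones(trained_weights.n_prb)
        out, _ = pattern_complete(cue, trained_weights, n_steps=800,
                                  competition=competition)
        sims = trained_weights.bvc_unit @ (out.bvc / np.linalg.norm(out.bvc))
        assert sims.max() >= 0.95  # member of the stored set


class TestHebbianUpdate:
    def test_zero_pre_is_noop(self, rng):
        W = rng.random((5, 7))
        out = hebbian_update(np.zeros(7), rng.random(5), W)
        assert np.array_equal(out, W)

    def test_one_hot_increments_single_entry(self):
        W = np.zeros((4, 3))
        pre = np.array([0.0, 1.0, 0.0])
        post = np.array([0.0, 0.0, 1.0, 0.0])
        out = hebbian_update(pre, post, W, rate=0.5)
        assert out[2, 1] == 0.5
        assert out.sum() == 0.5

    def test_propagation_peaks_at_post_argmax(self, rng):
        pre = rng.random(20)
        post = rng.random(15)
        W = hebbian_update(pre, post, np.zeros((15, 20)))
        assert (W @ pre).argmax() == post.argmax()


class TestEncoding:
    def _state_with_object(self, weights, layout, grid, competition,
                           pro_rates):
        s = stored_state(weights, layout, grid, 150, competition)
        s.ovc = np.zeros(grid.n_cells)
        s.ovc[100:104] = 0.7
        s.pro = np.asarray(pro_rates, dtype=float)
        return s

    def _arena_weights(self, layout, grid):
        from scenemem.geometry import square_arena

        env = square_arena(100.0, objects=[(30, 70), (70, 70)])
        return train_context(env, layout, grid)

    def test_encoding_changes_only_learned_blocks(self, layout, grid,
                                                  competition):
        w = self._arena_weights(layout, grid)
        before_ctx = (w.stored_bvc.copy(), w.stored_prb.copy())
        s = self._state_with_object(w, layout, grid, competition, [1.0, 0.0])
        ev = encode_object_event(s, hd_init(0.3).rates, w)
        assert ev is not None and ev.object_id == "1"
        assert np.array_equal(w.stored_bvc, before_ctx[0])
        assert np.array_equal(w.stored_prb, before_ctx[1])
        for name, W in w.learned_blocks().items():
            if name.endswith("_pro") or name.startswith("W_pro") or \
                    "hd" in name:
                continue
        assert w.W_pc_ovc.any() and w.W_ovc_pro.any() and w.W_hd_pro.any()

    def test_second_encounter_is_noop(self, layout, grid, competition):
        w = self._arena_weights(layout, grid)
        s = self._state_with_object(w, layout, grid, competition, [1.0, 0.0])
        encode_object_event(s, hd_init(0.3).rates, w)
        snap = {k: v.copy() for k, v in w.learned_blocks().items()}
        assert encode_object_event(s, hd_init(2.0).rates, w) is None
        for k, v in w.learned_blocks().items():
            assert np.array_equal(v, snap[k])

    def test_two_attended_objects_raise_binding_error(self, layout, grid,
                                                      competition):
        w = self._arena_weights(layout, grid)
        s = self._state_with_object(w, layout, grid, competition, [0.9, 0.8])
        with pytest.raises(BindingAmbiguityError):
            encode_object_event(s, hd_init(0.3).rates, w)

    def test_pro_cue_drives_encoding_pcs(self, layout, grid, competition):
        w = self._arena_weights(layout, grid)
        s = self._state_with_object(w, layout, grid, competition, [1.0, 0.0])
        encode_object_event(s, hd_init(0.3).rates, w)
        drive = w.pc_drive_learned(np.zeros(grid.n_cells),
                                   np.array([1.0, 0.0]))
        assert drive.argmax() == s.pc.argmax()


class TestPersistence:
    def test_round_trip(self, trained_weights, layout, grid, tmp_path):
        path = tmp_path / "weights.h5"
        save_weights(trained_weights, path)
        back = load_weights(path, layout, grid)
        assert np.array_equal(back.stored_bvc, trained_weights.stored_bvc)
        assert back.boundary_ids == trained_weights.boundary_ids
        for k, v in trained_weights.learned_blocks().items():
            assert np.array_equal(getattr(back, k), v)

    def test_grid_mismatch_rejected(self, trained_weights, layout, tmp_path):
        from scenemem.populations import make_polar_grid

        path = tmp_path / "weights.h5"
        save_weights(trained_weights, path)
        with pytest.raises(ValueError):
            load_weights(path, layout, make_polar_grid(12, 41, 120.0))
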