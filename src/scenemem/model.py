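"""The assembled spatial-memory model and its operating modes.

A :class:`Model` wires together the agent's sensory drive, the parietal
window, the head-direction ring, the retrosplenial transformation
circuit, the medial-temporal attractor, and the grid-cell system, and
steps them as one network.

Bottom-up (perception): boundary and object samples in the frontal field
of view drive the parietal window; the transformation circuit projects
the egocentric patterns onto boundary/object vector cells; BVCs (with
perirhinal identity input) drive the place-cell competition, letting the
model self-localize from vision alone while grid cells contribute a
small stabilizing input.  Memory-driven connections idle at 5% gain.

Top-down (imagery): perceptual transmission drops to 5%, memory-driven
connections rise to full strength, and grid input becomes the dominant
drive to place cells.  Cueing an object identity reinstates the encoding
head direction, completes the stored pattern, and reconstructs the
parietal window from the allocentric populations — the model's account
of recall as scene construction.  Mock motor efference moves the
imagined position, producing mental navigation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .geometry import AgentState, Environment, Trajectory, wrap_positive
from .grids import GCPCWeights, GridModules, build_grid_modules, gc_drive, learn_gc_pc
from .memory import (
    EncodingEvent,
    MTLState,
    MTLWeights,
    mtl_step,
    pattern_complete,
    train_context,
)
from .populations import (
    HDRing,
    N_HD,
    PlaceCompetition,
    PlaceLayout,
    PolarGrid,
    TAU,
    boundary_gain,
    decode_hd,
    decode_position,
    hd_init,
    hd_step,
    make_place_layout,
    make_polar_grid,
    vector_field_response,
    wrap_angle,
)
from .transform import (
    BOTTOM_UP,
    TOP_DOWN,
    GainMode,
    TransformationWeights,
    allo_to_ego,
    build_transformation,
    ego_to_allo,
    hd_gain,
)

SALIENCE_RADIUS = 55.0  # cm; proximity at which an object is encoded
ATTENTION_CYCLE = 600  # steps per attended object
UNATTENDED_GAIN = 0.1
ENCODE_DWELL = 60  # steps of attended salience before one-shot encoding
HD_REINSTATE_AMP = 2.0
GC_GAIN_BOTTOM_UP = 0.1
GC_GAIN_TOP_DOWN = 1.0


@dataclass
class RateNoise:
    """Multiplicative firing-rate perturbation, drawn fresh each step."""

    mean: float = 0.2
    sd: float = 0.05
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    def apply(self, rates: np.ndarray) -> np.ndarray:
        eps = self.rng.normal(self.mean, self.sd, rates.shape)
        sign = self.rng.integers(0, 2, rates.shape) * 2 - 1
        return np.clip(rates * (1.0 + sign * eps), 0.0, 1.0)


class Model:
    """Full multi-region model bound to one familiar environment."""

    POPULATIONS = ("PWb", "PWo", "BVC", "OVC", "PC", "PRb", "PRo", "HD")

    def __init__(
        self,
        env: Environment,
        seed: int = 0,
        grid: PolarGrid | None = None,
        layout: PlaceLayout | None = None,
        weights: MTLWeights | None = None,
        train_mask=None,
        gc_seed: int | None = None,
    ):
        self.env = env
        self.seed = int(seed)
        self.grid = grid or make_polar_grid()
        self.layout = layout or make_place_layout(env.extent)
        self.tw: TransformationWeights = build_transformation(self.grid)
        self.comp = PlaceCompetition(self.layout)
        self.weights: MTLWeights = (
            weights
            if weights is not None
            else train_context(env, self.layout, self.grid)
        )
        if train_mask is not None:
            self.weights.stored_bvc = self.weights.stored_bvc * np.asarray(
                train_mask, dtype=float
            )[:, None]
            self.weights.bvc_unit = self.weights.stored_bvc / np.maximum(
                np.linalg.norm(self.weights.stored_bvc, axis=1, keepdims=True), 1e-9
            )
            self.weights.stored_prb = self.weights.stored_prb * np.asarray(
                train_mask, dtype=float
            )[:, None]
        self.gc: GridModules = build_grid_modules(
            self.seed if gc_seed is None else gc_seed
        )
        self.gcpc: GCPCWeights = learn_gc_pc(self.layout, self.gc)

        self.mode: GainMode = BOTTOM_UP
        self.ring: HDRing = hd_init(0.0)
        self.state: MTLState = MTLState.zeros(
            self.layout.n_cells, self.grid.n_cells,
            self.weights.n_prb, self.weights.n_pro,
        )
        self.pw_b = np.zeros(self.grid.n_cells)
        self.pw_o = np.zeros(self.grid.n_cells)
        self.t = 0
        self.imagined_pos: np.ndarray | None = None

        # perturbations
        self.hd_lesion = False
        self.pc_lesion = False
        self.ablation_masks: dict[str, np.ndarray] = {}
        self.noise: RateNoise | None = None

        self._encode_dwell: dict[str, int] = {}
        self._att_idx = 0
        self._att_timer = 0
        self._bgain = boundary_gain(self.grid)
        # steps of sustained attended salience required before the one-shot
        # association is laid down (longer in multi-object protocols, where
        # binding must wait for a stable vantage)
        self.encode_dwell = ENCODE_DWELL

    def reset_state(self) -> None:
        """Zero all population states (e.g. after swapping in a context
        trained on a different boundary set)."""
        self.state = MTLState.zeros(
            self.layout.n_cells, self.grid.n_cells,
            self.weights.n_prb, self.weights.n_pro,
        )
        self.pw_b = np.zeros(self.grid.n_cells)
        self.pw_o = np.zeros(self.grid.n_cells)

    def set_heading(self, heading: float) -> None:
        """Re-pin the head-direction bump (e.g. before a stationary run)."""
        self.ring = hd_init(heading)

    # -- perturbation hooks --------------------------------------------------

    def _perturb(self, name: str, rates: np.ndarray) -> np.ndarray:
        if name in self.ablation_masks:
            rates = rates * self.ablation_masks[name]
        if self.noise is not None:
            rates = self.noise.apply(rates)
        return rates

    # -- transformation with lesion handling --------------------------------

    def _ego_to_allo(self, pw, mode=None):
        if self.hd_lesion:
            return np.zeros_like(pw)
        return ego_to_allo(pw, self.ring, self.tw, mode or self.mode)

    def _allo_to_ego(self, allo, mode=None):
        if self.hd_lesion:
            return np.zeros_like(allo)
        return allo_to_ego(allo, self.ring, self.tw, mode or self.mode)

    # -- attention -----------------------------------------------------------

    def attended_object(self, t: int, visible_ids: list[str]) -> str | None:
        """Sequential attention over the visible objects.

        One object is attended at a time; after ATTENTION_CYCLE steps (or
        as soon as the attended object leaves the field of view) attention
        advances to the next visible object in the environment's order.
        """
        ids = [o.identity for o in self.env.objects]
        if not ids or not visible_ids:
            self._att_timer = 0
            return None
        cur = ids[self._att_idx % len(ids)]
        self._att_timer += 1
        if cur not in visible_ids or self._att_timer > ATTENTION_CYCLE:
            for j in range(1, len(ids) + 1):
                cand = ids[(self._att_idx + j) % len(ids)]
                if cand in visible_ids:
                    self._att_idx = (self._att_idx + j) % len(ids)
                    self._att_timer = 0
                    return cand
            self._att_timer = 0
            return None
        return cur

    # -- one bottom-up step --------------------------------------------------

    def step_bottom_up(self, agent: AgentState, trace=None, theta_top_down=False):
        """Advance the network one step while the agent perceives.

        ``theta_top_down`` runs this step in the top-down phase of the
        theta-like gating: sensory input remains engaged but perceptual
        transmission is suppressed and memory-driven connections are at
        full strength (periodic probing of the stored context).
        """
        mode = TOP_DOWN if theta_top_down else BOTTOM_UP
        self.mode = mode
        self.ring = hd_step(self.ring, agent.angular_velocity)
        if "HD" in self.ablation_masks:  # ablation never targets the ring
            pass

        # perceptual parietal drive
        d, b, ids, w = geo.visible_boundary_points(self.env, agent)
        pwb_target = vector_field_response(
            self.grid, np.stack([d, b], axis=1), weights=w, gain=self._bgain
        )
        objs = geo.visible_objects(self.env, agent)
        visible_ids = [i for _, _, i, v in objs if v]
        attended = self.attended_object(self.t, visible_ids)
        pwo_target = np.zeros(self.grid.n_cells)
        pro_input = np.zeros(self.weights.n_pro)
        obj_info = {}
        for dist, bear, oid, vis in objs:
            if not vis:
                continue
            gain = 1.0 if oid == attended else UNATTENDED_GAIN
            pwo_target += gain * vector_field_response(
                self.grid, [(dist, bear)]
            )
            oi = self.weights.object_ids.index(oid)
            pro_input[oi] = max(pro_input[oi], gain)
            obj_info[oid] = (dist, bear)

        # parietal window: perception plus (suppressed) imagery bleed
        pwb_in = np.clip(
            pwb_target + self._allo_to_ego(self.state.bvc, mode), 0, 1
        )
        pwo_in = np.clip(
            pwo_target + self._allo_to_ego(self.state.ovc, mode), 0, 1
        )
        from .populations import TAU_RELAY

        self.pw_b = self._perturb(
            "PWb", np.clip(self.pw_b + (1.0 / TAU_RELAY) * (pwb_in - self.pw_b), 0, 1)
        )
        self.pw_o = self._perturb(
            "PWo", np.clip(self.pw_o + (1.0 / TAU_RELAY) * (pwo_in - self.pw_o), 0, 1)
        )

        # transformation to allocentric drive
        ego_bvc = self._ego_to_allo(self.pw_b, mode)
        ego_ovc = self._ego_to_allo(self.pw_o, mode)

        prb_input = np.zeros(self.weights.n_prb)
        for bid in set(ids):
            prb_input[self.weights.boundary_ids.index(bid)] = 1.0

        gcd = gc_drive(self.gcpc, self.gc, agent.position)
        gc_gain = (
            self.gcpc.top_down_gain if theta_top_down else self.gcpc.bottom_up_gain
        )
        self.state = mtl_step(
            self.state, self.weights,
            ego_drive_bvc=ego_bvc, ego_drive_ovc=ego_ovc,
            prb_input=prb_input, pro_input=pro_input,
            bottom_up_gain=mode.ego_gain, top_down_gain=mode.allo_gain,
            gc_drive=gcd, gc_gain=gc_gain,
            competition=self.comp, pc_lesion=self.pc_lesion,
        )
        for pop, key in (("PC", "pc"), ("BVC", "bvc"), ("OVC", "ovc"),
                         ("PRb", "prb"), ("PRo", "pro")):
            setattr(self.state, key, self._perturb(pop, getattr(self.state, key)))

        event = None
        if attended != getattr(self, "_last_attended", None):
            # attention moved: salience dwell restarts (and the identity
            # competition gets time to settle on the new winner)
            self._encode_dwell = {}
            self._last_attended = attended
        if attended is not None and not theta_top_down:
            event = self._maybe_encode(agent, attended, obj_info)

        if trace is not None:
            trace.record(self.t, agent, mode.mode, self.snapshot(), event,
                         attended=attended)
        self.t += 1
        return event

    def _maybe_encode(self, agent, attended: str, obj_info) -> EncodingEvent | None:
        """One-shot salience-triggered encoding of the attended object."""
        from .memory import encode_object_event

        if attended in self.weights.events or attended not in obj_info:
            self._encode_dwell[attended] = 0
            return None
        dist = obj_info[attended][0]
        if dist > SALIENCE_RADIUS:
            self._encode_dwell[attended] = 0
            return None
        if self.hd_lesion:
            return None  # no OVC representation can form; nothing to bind
        self._encode_dwell[attended] = self._encode_dwell.get(attended, 0) + 1
        if self._encode_dwell[attended] < self.encode_dwell:
            return None
        if self.state.ovc.max() <= 0.05 or self.state.pro.max() <= 0.1:
            return None
        return encode_object_event(
            self.state, self.ring.rates, self.weights,
            t=self.t, position=agent.position, heading=agent.heading,
            pw_b=self.pw_b, pw_o=self.pw_o,
        )

    # -- trajectory driver ---------------------------------------------------

    def run_trajectory(self, traj: Trajectory, trace=None, theta=None):
        """Run the bottom-up pipeline along a trajectory.

        ``theta`` is an optional callable ``t -> bool`` returning True for
        steps that run in the top-down phase of the theta-like gating.
        """
        events = []
        if len(traj):
            # the agent is assumed oriented at trajectory onset: re-pin the
            # ring if its decoded heading disagrees with the start pose
            # (e.g. after a scripted relocation between protocol phases)
            try:
                cur = decode_hd(self.ring)
            except ValueError:
                cur = None
            start = traj.states[0].heading
            if (
                self.t == 0
                or cur is None
                or abs(float(wrap_angle(cur - start))) > np.deg2rad(10)
            ):
                self.ring = hd_init(start)
        for s in traj:
            td = bool(theta(self.t)) if theta is not None else False
            ev = self.step_bottom_up(s, trace=trace, theta_top_down=td)
            if ev is not None:
                events.append(ev)
        return events

    # -- recall (imagery) ----------------------------------------------------

    def cue_recall(
        self,
        object_id: str,
        n_settle: int = 500,
        record_steps: int = 200,
        trace=None,
        agent: AgentState | None = None,
    ):
        """Object-cued recall into visuo-spatial imagery.

        Injects current into the object's identity neuron, switches the
        network to top-down mode, reinstates the encoding head direction
        through the learned identity-to-head-direction weights, completes
        the stored pattern in the medial temporal lobe, and reconstructs
        the parietal window.  Returns a dict with the settled state, the
        reconstructed parietal patterns, the imagined heading, and a
        ``failed`` flag for un-encoded cues.
        """
        self.mode = TOP_DOWN
        result = {
            "object_id": object_id, "failed": False, "state": None,
            "pw_b": np.zeros(self.grid.n_cells),
            "pw_o": np.zeros(self.grid.n_cells),
            "heading": None,
        }
        if object_id not in self.weights.object_ids:
            raise KeyError(f"unknown object {object_id!r}")
        oi = self.weights.object_ids.index(object_id)
        if object_id not in self.weights.events and not (
            self.weights.W_pc_pro[:, oi].any()
            or self.weights.W_ovc_pro[:, oi].any()
        ):
            result["failed"] = True
            return result

        pro_in = np.zeros(self.weights.n_pro)
        pro_in[oi] = 1.0

        # head-direction reinstatement through the learned projection
        hd_ext = HD_REINSTATE_AMP * self.weights.hd_drive_from_pro(pro_in)
        for _ in range(400):
            self.ring = hd_step(self.ring, 0.0, external=hd_ext)

        cue = MTLState.zeros(
            self.layout.n_cells, self.grid.n_cells,
            self.weights.n_prb, self.weights.n_pro,
        )
        settled, _ = pattern_complete(
            cue, self.weights, n_steps=n_settle, competition=self.comp,
            pro_input=pro_in, top_down_gain=1.0,
            pc_lesion=self.pc_lesion,
        )
        for pop, key in (("PC", "pc"), ("BVC", "bvc"), ("OVC", "ovc"),
                         ("PRb", "prb"), ("PRo", "pro")):
            setattr(settled, key, self._perturb(pop, getattr(settled, key)))
        self.state = settled
        self.pw_b = self._perturb("PWb", np.clip(self._allo_to_ego(settled.bvc, TOP_DOWN), 0, 1))
        self.pw_o = self._perturb("PWo", np.clip(self._allo_to_ego(settled.ovc, TOP_DOWN), 0, 1))
        if settled.pc.sum() > 0:
            self.imagined_pos = decode_position(settled.pc, self.layout)

        result["state"] = settled
        result["pw_b"] = self.pw_b.copy()
        result["pw_o"] = self.pw_o.copy()
        try:
            result["heading"] = decode_hd(self.ring)
        except ValueError:
            result["heading"] = None
        if result["pw_b"].max() < 0.02 and result["pw_o"].max() < 0.02:
            result["failed"] = self.hd_lesion or object_id not in self.weights.events
        if trace is not None:
            pose = agent or AgentState(
                self.imagined_pos
                if self.imagined_pos is not None
                else np.zeros(2),
                result["heading"] or 0.0,
            )
            for _ in range(record_steps):
                self.ring = hd_step(self.ring, 0.0, external=hd_ext)
                trace.record(self.t, pose, "top_down", self.snapshot(), None)
                self.t += 1
        return result

    # -- mental navigation ---------------------------------------------------

    def mental_navigate(self, commands, trace=None, agent_pose=None):
        """Imagined movement driven by mock motor efference.

        ``commands`` is a sequence of ``(speed, heading)`` per step.  The
        imagined position integrates the commands; grid cells evaluated
        at the imagined position drive the place bump (dominant input in
        top-down mode); pattern completion updates the boundary/object
        populations, and the transformation circuit repaints the parietal
        window.  Returns the list of per-step snapshot dicts.
        """
        if self.imagined_pos is None:
            if self.state.pc.sum() <= 0:
                raise RuntimeError("mental navigation needs a settled imagery state")
            self.imagined_pos = decode_position(self.state.pc, self.layout)
        self.mode = TOP_DOWN
        # the recall query is resolved once navigation starts; encoded
        # objects re-activate their identity neurons as the imagined
        # position crosses their encoding areas
        self.state.pro = np.zeros_like(self.state.pro)
        out = []
        xmin, ymin, xmax, ymax = self.env.extent
        for speed, heading in commands:
            step_v = np.array([np.cos(heading), np.sin(heading)]) * speed
            nxt = self.imagined_pos + step_v
            clipped = np.clip(nxt, [xmin + 2, ymin + 2], [xmax - 2, ymax - 2])
            if not np.allclose(nxt, clipped):
                import warnings

                warnings.warn("mental navigation command exits the arena; clipped")
            self.imagined_pos = clipped

            # imagined heading written to the ring as external current
            pref = self.ring.preferred
            ext = 1.0 * np.exp(
                -0.5 * (wrap_angle(pref - heading) / np.deg2rad(15.0)) ** 2
            )
            self.ring = hd_step(self.ring, 0.0, external=ext)

            gcd = gc_drive(self.gcpc, self.gc, self.imagined_pos)
            self.state = mtl_step(
                self.state, self.weights,
                bottom_up_gain=TOP_DOWN.ego_gain, top_down_gain=TOP_DOWN.allo_gain,
                gc_drive=gcd, gc_gain=self.gcpc.top_down_gain,
                competition=self.comp, pc_lesion=self.pc_lesion,
            )
            self.pw_b = np.clip(self._allo_to_ego(self.state.bvc, TOP_DOWN), 0, 1)
            self.pw_o = np.clip(self._allo_to_ego(self.state.ovc, TOP_DOWN), 0, 1)
            snap = {
                "imagined_pos": self.imagined_pos.copy(),
                "heading": heading,
                "pw_b": self.pw_b.copy(),
                "pw_o": self.pw_o.copy(),
                "state": self.state.copy(),
            }
            out.append(snap)
            if trace is not None:
                pose = AgentState(self.imagined_pos.copy(), heading)
                trace.record(self.t, pose, "top_down", self.snapshot(), None)
            self.t += 1
        return out

    # -- snapshots -----------------------------------------------------------

    def snapshot(self) -> dict[str, np.ndarray]:
        return {
            "PWb": self.pw_b, "PWo": self.pw_o,
            "BVC": self.state.bvc, "OVC": self.state.ovc,
            "PC": self.state.pc, "PRb": self.state.prb, "PRo": self.state.pro,
            "HD": self.ring.rates,
        }

    def population_size(self, name: str) -> int:
        return {
            "PWb": self.grid.n_cells, "PWo": self.grid.n_cells,
            "BVC": self.grid.n_cells, "OVC": self.grid.n_cells,
            "PC": self.layout.n_cells, "PRb": self.weights.n_prb,
            "PRo": self.weights.n_pro, "HD": N_HD,
        }[name]


def cue_recall(model: Model, object_id: str, **kw):
    """Functional alias for :meth:`Model.cue_recall`."""
    return model.cue_recall(object_id, **kw)


def mental_navigate(model: Model, commands, **kw):
    """Functional alias for :meth:`Model.mental_navigate`."""
    return model.mental_navigate(commands, **kw)
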