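"""Attention, perturbations, theta-like gating, and the scripted
simulation protocols.

The protocols reproduce the standard assay battery for this model
family: object-cued recall; recall under diffuse neuron loss or firing
rate noise; head-direction (Papez' circuit) lesions before or after
encoding (anterograde/retrograde amnesia); moved-object novelty with an
intact or lesioned hippocampus; boundary and object trace responses
under theta-like alternation of bottom-up and top-down gains; identity
inference by attending to residual peaks in imagery; grid-cell driven
mental navigation; and planning/short-cutting across unexplored space
with reservoir-cell recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .analysis import SimulationTrace
from .geometry import AgentState, Environment, generate_trajectory, square_arena
from .grids import make_reservoir, peak_order, plan_vector_trajectory, sweep_reservoir
from .memory import MTLState, hebbian_update
from .model import (
    ATTENTION_CYCLE,
    Model,
    RateNoise,
    SALIENCE_RADIUS,
    UNATTENDED_GAIN,
)
from .populations import decode_position
from .transform import BOTTOM_UP, TOP_DOWN, GainMode

AGENT_SPEED = 0.15  # cm per step (slow exploratory locomotion)

SIMULATION_IDS = ("1.0", "1.1", "1.2", "1.3", "1.4", "2.1", "2.2",
                  "3.0", "4.0", "5.0")


# ---------------------------------------------------------------------------
# attention and salience


@dataclass
class AttentionSchedule:
    """Rhythmic attention: one object drives the parietal window at a time."""

    object_ids: list[str]
    cycle: int = ATTENTION_CYCLE

    def attended(self, t: int) -> str | None:
        if not self.object_ids:
            return None
        return self.object_ids[(t // self.cycle) % len(self.object_ids)]


def attention_gain(t: int, schedule: AttentionSchedule) -> dict[str, float]:
    """Per-object parietal drive gain at step t (attended 1, others 0.1)."""
    if not schedule.object_ids:
        raise ValueError("attention schedule has no objects")
    att = schedule.attended(t)
    return {
        oid: (1.0 if oid == att else UNATTENDED_GAIN)
        for oid in schedule.object_ids
    }


def salience_trigger(
    agent: AgentState, obj, encoded: bool, threshold: float = SALIENCE_RADIUS
) -> bool:
    """One-shot proximity salience: fires iff the (visible) object is within
    ``threshold`` cm and has not been encoded yet."""
    pos, _identity = obj
    dist = float(np.hypot(*(np.asarray(pos, dtype=float) - agent.position)))
    return (dist <= threshold) and not encoded


# ---------------------------------------------------------------------------
# perturbations


def apply_hd_lesion(model: Model) -> Model:
    """Remove the head-direction input to the transformation circuit.

    Both transformation directions lose their gain modulation and output
    nothing; perirhinal recognition is spared.
    """
    model.hd_lesion = True
    return model


def apply_hippocampal_lesion(model: Model) -> Model:
    """Clamp place-cell rates to zero (OVC<->PRo learning still possible)."""
    model.pc_lesion = True
    model.state.pc = np.zeros_like(model.state.pc)
    return model


def ablate_cells(model: Model, fraction: float, seed: int) -> Model:
    """Permanently silence a random fraction of cells per population.

    The head-direction ring is excluded (too few cells to survive
    sampling); exactly ``floor(fraction * N)`` cells are silenced per
    population, deterministically per seed.
    """
    if not 0.0 <= fraction <= 0.5:
        raise ValueError("ablation fraction must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    for pop in ("PWb", "PWo", "BVC", "OVC", "PC", "PRb", "PRo"):
        n = model.population_size(pop)
        k = int(np.floor(fraction * n))
        mask = np.ones(n)
        if k:
            mask[rng.choice(n, k, replace=False)] = 0.0
        model.ablation_masks[pop] = mask
    return model


def apply_rate_noise(
    rates: np.ndarray,
    mean: float = 0.2,
    sd: float = 0.05,
    seed: int = 0,
    t: int = 0,
) -> np.ndarray:
    """Multiplicative rate noise: each rate scaled by (1 +- eps) with
    |eps| ~ Normal(mean, sd) and random sign, clipped to [0, 1]."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(t)]))
    noise = RateNoise(mean, sd, rng)
    return noise.apply(np.asarray(rates, dtype=float))


def theta_gate(t: int, period: int = 125, duty: float = 0.8) -> GainMode:
    """Theta-like alternation: bottom-up for ``duty`` of each period,
    top-down for the remainder (sensory input stays engaged throughout)."""
    if not 0.0 < duty < 1.0:
        raise ValueError("duty must be strictly between 0 and 1")
    return BOTTOM_UP if (t % period) < duty * period else TOP_DOWN


# ---------------------------------------------------------------------------
# simulation protocols


@dataclass
class SimulationConfig:
    """Configuration for one scripted protocol."""

    simulation_id: str
    seed: int = 0
    env: Environment | None = None
    perturbations: dict = field(default_factory=dict)
    out_dir: str | None = None
    options: dict = field(default_factory=dict)


@dataclass
class SimulationResult:
    trace: SimulationTrace
    model: Model
    recalls: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def _jitter(rng, xy, amount=3.0):
    return tuple(np.asarray(xy, dtype=float) + rng.uniform(-amount, amount, 2))


def _new_trace(model: Model, config: SimulationConfig) -> SimulationTrace:
    tr = SimulationTrace(populations=Model.POPULATIONS)
    tr.meta = {
        "simulation_id": config.simulation_id,
        "seed": config.seed,
        "extent": model.env.extent,
    }
    return tr


def _apply_perturbations(model: Model, config: SimulationConfig) -> None:
    p = config.perturbations
    if p.get("ablation_fraction"):
        ablate_cells(model, p["ablation_fraction"], p.get("ablation_seed", config.seed))
    if p.get("rate_noise"):
        mean, sd = p["rate_noise"]
        model.noise = RateNoise(mean, sd, np.random.default_rng(config.seed + 7))
    if p.get("hd_lesion"):
        apply_hd_lesion(model)
    if p.get("hippocampal_lesion"):
        apply_hippocampal_lesion(model)


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Execute one of the scripted protocols (Simulations 1.0-5.0)."""
    runners = {
        "1.0": _sim_recall, "1.1": _sim_hd_lesion_before,
        "1.2": _sim_hd_lesion_after, "1.3": _sim_novelty,
        "1.4": _sim_novelty, "2.1": _sim_boundary_trace,
        "2.2": _sim_object_trace, "3.0": _sim_imagery_inspection,
        "4.0": _sim_mental_navigation, "5.0": _sim_shortcut,
    }
    sid = str(config.simulation_id)
    if sid not in runners:
        raise ValueError(f"unknown simulation id {sid!r}")
    result = runners[sid](config)
    if config.out_dir:
        import os

        from .analysis import write_trace

        os.makedirs(config.out_dir, exist_ok=True)
        write_trace(
            result.trace, os.path.join(config.out_dir, f"sim_{sid}_trace.h5")
        )
    return result


#: analyzed object-vector cells of the survey: (tuning distance cm,
#: tuning direction deg), chosen so every expected firing field lies in
#: the interior of the covered area
SURVEY_CELLS = ((17.0, 0.0), (17.0, 268.0), (11.0, 0.0), (11.0, 268.0))


def ovc_field_survey(
    seed: int = 0,
    objects=((38.0, 58.0), (62.0, 62.0), (52.0, 34.0)),
    n_waypoints: int = 110,
    speed: float = 0.4,
):
    """Foraging survey of object-vector firing fields.

    The three objects are presented one per session (the design of the
    rodent experiments this mimics, where objects are moved between
    sessions); each session is a random-waypoint foraging walk with
    isotropic headings.  Because object-vector cells are identity
    agnostic, the defining property — one firing field per object at a
    shared allocentric offset — appears in the rate map accumulated over
    the sessions, without the sampling imbalance a slow attention cycle
    imposes when several objects compete within one walk.  Returns
    ``(trace, model)``.
    """
    full_env = square_arena(100.0, objects=[tuple(o) for o in objects])
    model = Model(full_env, seed=seed)
    trace = SimulationTrace(populations=Model.POPULATIONS)
    trace.meta = {"extent": full_env.extent, "seed": seed}
    rng = np.random.default_rng(seed)
    ids = [o.identity for o in full_env.objects]
    for k, keep in enumerate(ids):
        env_k = full_env
        for other in ids:
            if other != keep:
                env_k = geo.mutate_environment(env_k, "remove_object", other)
        model.env = env_k
        wps = [tuple(rng.uniform(10.0, 90.0, 2)) for _ in range(n_waypoints)]
        traj = generate_trajectory(env_k, wps, speed=speed,
                                   turn_rate=np.deg2rad(1.5))
        t0 = model.t
        model.run_trajectory(traj, trace=trace)
        trace.mark_segment(f"session_{keep}", t0, model.t)
    model.env = full_env
    return trace, model


def visibility_conditioned_map(trace, model, population: str, cell: int,
                               bin_size: float = 4.0):
    """Rate map conditioned on the session's object being in view.

    A vector cell can only fire for an object inside the frontal field
    of view, so the unconditioned occupancy average dilutes each firing
    field by the heading-dependent probability of facing the object,
    unevenly across the arena.  Filtering each survey session to the
    steps where its object's bearing is frontal (the directional
    analogue of occupancy normalization) removes that sampling bias;
    the session maps are then averaged.
    """
    from .analysis import RateMap, compute_rate_map

    pose = trace.pose
    t = trace.t
    maps, ex, ey = [], None, None
    for o in model.env.objects:
        seg = trace.segments.get(f"session_{o.identity}")
        if seg is None:
            continue
        in_seg = (t >= seg[0]) & (t < seg[1])
        rel = np.asarray(o.position)[None, :] - pose[:, :2]
        bearing = geo.wrap_angle(np.arctan2(rel[:, 1], rel[:, 0]) - pose[:, 2])
        frontal = np.abs(bearing) <= np.pi / 2
        mm = compute_rate_map(trace, population, cell, bin_size=bin_size,
                              smooth_bins=1.5, step_mask=in_seg & frontal,
                              min_occupancy=2.0)
        maps.append(np.nan_to_num(mm.rate, nan=0.0))
        ex, ey = mm.edges_x, mm.edges_y
    return RateMap(np.mean(maps, axis=0), np.ones_like(maps[0]), ex, ey)


def attention_balanced_map(trace, model, population: str, cell: int,
                           bin_size: float = 4.0):
    """Rate map averaged over attention states.

    One occupancy-normalized map is computed per attended object and the
    maps are averaged, removing the sampling imbalance introduced by the
    slow (600-step) attention cycle relative to the path geometry.
    """
    from .analysis import RateMap, compute_rate_map

    att = trace.attended
    ids = [o.identity for o in model.env.objects]
    maps, ex, ey = [], None, None
    for oid in ids:
        mm = compute_rate_map(
            trace, population, cell, bin_size=bin_size, smooth_bins=1.5,
            step_mask=(att == oid), min_occupancy=2.0,
        )
        maps.append(np.nan_to_num(mm.rate, nan=0.0))
        ex, ey = mm.edges_x, mm.edges_y
    return RateMap(np.mean(maps, axis=0), np.ones_like(maps[0]), ex, ey)


# -- Simulation 1.0: encode one object, object-cued recall -------------------


def _sim_recall(config: SimulationConfig) -> SimulationResult:
    rng = np.random.default_rng(config.seed)
    env = config.env or square_arena(100.0, objects=[(60.0, 70.0)])
    model = Model(env, seed=config.seed)
    _apply_perturbations(model, config)
    trace = _new_trace(model, config)

    # slow approach past the object (encoding en route), then a faster
    # arena-covering tour that samples many vantage points for the
    # chance-level baseline
    approach = generate_trajectory(
        env, [_jitter(rng, (15, 15)), _jitter(rng, (50, 40))],
        speed=AGENT_SPEED,
    )
    tour_wps = [tuple(approach.states[-1].position)] + [
        _jitter(rng, w, 2.0)
        for w in geo.coverage_waypoints(env, margin=15.0, n_rows=5)
    ]
    tour = generate_trajectory(env, tour_wps, speed=0.35)
    events = model.run_trajectory(approach, trace=trace)
    events += model.run_trajectory(tour, trace=trace)
    trace.mark_segment("perception", 0, model.t)

    t0 = model.t
    recall = model.cue_recall("1", trace=trace, agent=tour.states[-1])
    trace.mark_segment("recall", t0, model.t)
    return SimulationResult(
        trace, model, recalls={"1": recall}, extras={"events": events}
    )


# -- Simulations 1.1 / 1.2: head-direction lesions ---------------------------


def _sim_hd_lesion_before(config: SimulationConfig) -> SimulationResult:
    cfg = SimulationConfig(
        "1.0", config.seed, config.env,
        {**config.perturbations, "hd_lesion": True}, None, config.options,
    )
    res = _sim_recall(cfg)
    res.trace.meta["simulation_id"] = "1.1"
    return res


def _sim_hd_lesion_after(config: SimulationConfig) -> SimulationResult:
    # encode intact, then lesion, then cue the pre-lesion memory
    rng = np.random.default_rng(config.seed)
    env = config.env or square_arena(100.0, objects=[(60.0, 70.0)])
    model = Model(env, seed=config.seed)
    _apply_perturbations(model, config)
    trace = _new_trace(model, config)
    trace.meta["simulation_id"] = "1.2"

    approach = generate_trajectory(
        env, [_jitter(rng, (15, 15)), _jitter(rng, (50, 40))],
        speed=AGENT_SPEED,
    )
    tour_wps = [tuple(approach.states[-1].position)] + [
        _jitter(rng, w, 2.0)
        for w in geo.coverage_waypoints(env, margin=15.0, n_rows=5)
    ]
    tour = generate_trajectory(env, tour_wps, speed=0.35)
    events = model.run_trajectory(approach, trace=trace)
    events += model.run_trajectory(tour, trace=trace)
    trace.mark_segment("perception", 0, model.t)

    apply_hd_lesion(model)
    t0 = model.t
    recall = model.cue_recall("1", trace=trace, agent=tour.states[-1])
    trace.mark_segment("recall", t0, model.t)
    return SimulationResult(
        trace, model, recalls={"1": recall}, extras={"events": events}
    )


# -- Simulations 1.3 / 1.4: moved-object novelty -----------------------------


def _sim_novelty(config: SimulationConfig) -> SimulationResult:
    """Encode two objects from one vantage, move object 1 further North,
    then compare perceived and recalled object-vector patterns.

    Intact (1.3): tested from the encoding vantage; the moved object
    mismatches, the unmoved one matches.  Hippocampal lesion (1.4): the
    recalled pattern is unanchored, so mismatch is equal for both objects
    from a neutral vantage, but matches incidentally from the location
    whose offset to the (moved) object reproduces the encoding offset.
    """
    sid = str(config.simulation_id)
    lesioned = sid == "1.4" or config.perturbations.get("hippocampal_lesion")
    rng = np.random.default_rng(config.seed)
    env = config.env or square_arena(
        100.0, objects=[(40.0, 70.0), (62.0, 68.0)]
    )
    model = Model(env, seed=config.seed)
    model.encode_dwell = 300  # bind only after sustained attention
    _apply_perturbations(model, config)
    if lesioned:
        apply_hippocampal_lesion(model)
    trace = _new_trace(model, config)
    trace.meta["simulation_id"] = sid

    vantage = np.asarray(_jitter(rng, (50.0, 42.0), 2.0))
    objs = np.array([o.position for o in env.objects])
    face = float(np.arctan2(*(objs.mean(axis=0) - vantage)[::-1]))

    approach = generate_trajectory(
        env, [_jitter(rng, (50, 15)), tuple(vantage)], speed=AGENT_SPEED
    )
    model.run_trajectory(approach, trace=trace)
    facing = AgentState(vantage.copy(), face)
    model.set_heading(face)
    for _ in range(2 * ATTENTION_CYCLE + 400):
        model.step_bottom_up(facing, trace=trace)
    events = dict(model.weights.events)

    # leave, move object 1 North, return for testing
    away = generate_trajectory(env, [tuple(vantage), _jitter(rng, (20, 20))],
                               speed=AGENT_SPEED)
    model.run_trajectory(away, trace=trace)
    moved_env = geo.mutate_environment(
        env, "move_object", "1",
        np.asarray(env.objects[0].position) + np.array([0.0, 25.0]),
    )
    model.env = moved_env

    if lesioned:
        # neutral vantage plus the incidental-match vantage, from which
        # the moved object reproduces the learned egocentric offset
        enc_offset = objs[0] - vantage
        match_vantage = np.asarray(moved_env.objects[0].position) - enc_offset
        test_points = {"neutral": np.asarray(_jitter(rng, (28.0, 30.0), 2.0)),
                       "match_1": match_vantage}
    else:
        test_points = {"vantage": vantage}

    perceived = {}
    for name, pt in test_points.items():
        objs_now = np.array([o.position for o in moved_env.objects])
        h = float(np.arctan2(*(objs_now.mean(axis=0) - pt)[::-1]))
        back = generate_trajectory(moved_env, [_jitter(rng, (20, 20)),
                                               tuple(pt)], speed=0.35)
        model.run_trajectory(back, trace=trace)
        pose = AgentState(np.asarray(pt, dtype=float), h)
        model.set_heading(h)
        snap = {}
        for _ in range(2 * ATTENTION_CYCLE + 200):
            model.step_bottom_up(pose, trace=trace)
            att = model._last_attended
            # record once the attended object's representation has
            # settled deep into its attention phase
            if att is not None and model._att_timer > 400:
                snap[att] = model.state.ovc.copy()
        perceived[name] = snap

    # recall each object in imagery (the recalled pattern does not depend
    # on the agent's physical location)
    recalled, recalls = {}, {}
    for oid in ("1", "2"):
        t0 = model.t
        rec = model.cue_recall(oid, trace=trace,
                               agent=AgentState(vantage.copy(), face))
        recalls[oid] = rec
        recalled[oid] = (rec["state"].ovc.copy() if rec["state"] is not None
                         else np.zeros(model.grid.n_cells))
        trace.mark_segment(f"recall_{oid}", t0, model.t)

    from .analysis import novelty_mismatch

    mismatch = {
        name: novelty_mismatch(snap, recalled)
        for name, snap in perceived.items() if len(snap) == 2
    }
    return SimulationResult(
        trace, model, recalls=recalls,
        extras={
            "perceived_ovc": perceived, "recalled_ovc": recalled,
            "mismatch": mismatch, "events": events, "moved_env": moved_env,
            "vantage": vantage, "test_points": test_points,
        },
    )


# -- Simulation 2.1: boundary trace fields -----------------------------------


def barrier_arena(side: float = 100.0, objects=()) -> Environment:
    """Square arena with an interior barrier wall segment."""
    s = side
    spec = {
        "extent": [0, 0, s, s],
        "boundaries": [
            {"id": "wall_S", "points": [[0, 0], [s, 0]]},
            {"id": "wall_E", "points": [[s, 0], [s, s]]},
            {"id": "wall_N", "points": [[s, s], [0, s]]},
            {"id": "wall_W", "points": [[0, s], [0, 0]]},
            {"id": "barrier", "points": [[0.4 * s, 0.45 * s], [0.4 * s, 0.75 * s]]},
        ],
        "objects": [{"id": str(i + 1), "xy": list(xy)}
                    for i, xy in enumerate(objects)],
    }
    return geo.build_environment(spec)


def _sim_boundary_trace(config: SimulationConfig) -> SimulationResult:
    """Context trained with a barrier; the barrier is absent during the
    theta-gated exploration, leaving BVC trace fields at its former
    location (control: context trained without the barrier)."""
    control = bool(config.options.get("control", False))
    rng = np.random.default_rng(config.seed)
    trained_env = square_arena(100.0) if control else barrier_arena(100.0)
    run_env = square_arena(100.0)
    from .memory import train_context

    model = Model(run_env, seed=config.seed)
    # stored context comes from the barrier-trained environment
    model.weights = train_context(trained_env, model.layout, model.grid)
    model.reset_state()
    _apply_perturbations(model, config)
    trace = _new_trace(model, config)
    trace.meta["simulation_id"] = "2.1"

    wps = [_jitter(rng, w, 1.5)
           for w in geo.coverage_waypoints(run_env, margin=10.0, n_rows=8)]
    xs = np.linspace(10.0, 90.0, 8)
    for i, x in enumerate(xs):  # second, vertical pass
        pair = [(x, 10.0), (x, 90.0)] if i % 2 == 0 else [(x, 90.0), (x, 10.0)]
        wps += [_jitter(rng, w, 1.5) for w in pair]
    # weave across the (former) barrier region so both of its flanks are
    # sampled during the brief top-down probes
    for rep in range(2):
        for y in (46.0, 52.0, 58.0, 64.0, 70.0, 74.0):
            wps += [_jitter(rng, (28.0, y), 1.5), _jitter(rng, (54.0, y), 1.5)]
    traj = generate_trajectory(run_env, wps, speed=0.45)
    period = config.options.get("theta_period", 125)
    duty = config.options.get("theta_duty", 0.8)
    model.run_trajectory(
        traj, trace=trace,
        theta=lambda t: theta_gate(t, period, duty).mode == "top_down",
    )
    barrier = (
        None if control
        else trained_env.boundaries[trained_env.boundary_index("barrier")].points
    )
    return SimulationResult(trace, model, extras={"barrier": barrier,
                                                  "control": control})


# -- Simulation 2.2: object trace fields -------------------------------------


def _sim_object_trace(config: SimulationConfig) -> SimulationResult:
    """Weights carry an encoded object; the object is removed and the agent
    explores under theta gating.  The object's OVC and identity (PRo)
    cells develop trace fields near the encoding location."""
    control = bool(config.options.get("control", False))
    rng = np.random.default_rng(config.seed)
    env = square_arena(100.0, objects=[(60.0, 70.0)])
    model = Model(env, seed=config.seed)
    _apply_perturbations(model, config)
    trace = _new_trace(model, config)
    trace.meta["simulation_id"] = "2.2"

    enc_pos = None
    if not control:
        approach = generate_trajectory(
            env, [_jitter(rng, (15, 15)), _jitter(rng, (50, 40)),
                  _jitter(rng, (80, 20))], speed=AGENT_SPEED,
        )
        events = model.run_trajectory(approach, trace=trace)
        if events:
            enc_pos = events[0].position

    removed = geo.mutate_environment(env, "remove_object", "1")
    model.env = removed
    wps = [_jitter(rng, w, 1.5) for w in
           geo.coverage_waypoints(removed, margin=12.0, n_rows=6)]
    # repeated crossings of the encoding site from several directions, so
    # the brief top-down probes sample the reactivation zone well
    if enc_pos is not None:
        ex_, ey_ = float(enc_pos[0]), float(enc_pos[1])
        for dx, dy in ((20, 0), (0, 20), (14, 14), (14, -14)):
            wps += [
                _jitter(rng, (ex_ - dx, ey_ - dy), 1.0),
                _jitter(rng, (ex_ + dx, ey_ + dy), 1.0),
            ]
    traj = generate_trajectory(removed, wps, speed=0.2)
    t_explore = model.t
    period = config.options.get("theta_period", 125)
    duty = config.options.get("theta_duty", 0.8)
    model.run_trajectory(
        traj, trace=trace,
        theta=lambda t: theta_gate(t, period, duty).mode == "top_down",
    )
    trace.mark_segment("exploration", t_explore, model.t)
    return SimulationResult(
        trace, model,
        extras={"encoding_position": enc_pos, "control": control,
                "object_position": np.array([60.0, 70.0])},
    )


# -- Simulation 3.0: inspecting scene elements in imagery --------------------


def _sim_imagery_inspection(config: SimulationConfig) -> SimulationResult:
    """Encode two objects from one vantage; recall object 1; attend to the
    residual parietal peak of object 2; the boosted drive flows through
    the transformation circuit to the OVCs and the learned OVC-to-PRo
    weights switch the identity winner to object 2."""
    rng = np.random.default_rng(config.seed)
    env = config.env or square_arena(
        100.0, objects=[(38.0, 68.0), (62.0, 68.0)]
    )
    model = Model(env, seed=config.seed)
    model.encode_dwell = 300  # bind only after sustained attention
    _apply_perturbations(model, config)
    trace = _new_trace(model, config)
    trace.meta["simulation_id"] = "3.0"

    vantage = _jitter(rng, (50.0, 42.0), 2.0)
    approach = generate_trajectory(env, [_jitter(rng, (50, 15)), vantage],
                                   speed=AGENT_SPEED)
    model.run_trajectory(approach, trace=trace)
    facing = AgentState(np.asarray(vantage, dtype=float), np.deg2rad(90.0))
    model.set_heading(facing.heading)
    for _ in range(2 * ATTENTION_CYCLE + 200):
        model.step_bottom_up(facing, trace=trace)

    away = generate_trajectory(env, [vantage, _jitter(rng, (80, 20))],
                               speed=AGENT_SPEED)
    model.run_trajectory(away, trace=trace)

    recall = model.cue_recall("1", trace=trace, agent=facing)
    winner_before = int(np.argmax(model.state.pro))

    # locate the residual secondary peak in the reconstructed PWo
    pw = recall["pw_o"].copy()
    primary = pw.argmax()
    resid = _mask_around(model.grid, pw, primary)
    secondary = int(resid.argmax())

    # attention: inject current at the residual peak, withdraw the cue
    inject = np.zeros_like(pw)
    inject[_neighborhood(model.grid, secondary)] = 0.5 * pw.max()
    switched = _attend_in_imagery(model, inject, n_steps=400)
    winner_after = int(np.argmax(model.state.pro))
    return SimulationResult(
        trace, model, recalls={"1": recall},
        extras={
            "winner_before": winner_before, "winner_after": winner_after,
            "secondary_cell": secondary, "switched": switched,
        },
    )


def _neighborhood(grid, cell: int, ang_span: int = 2, rad_span: int = 1):
    """Indices of the polar-grid cells around ``cell``."""
    r0, a0 = divmod(int(cell), grid.n_angular)
    idx = []
    for dr in range(-rad_span, rad_span + 1):
        r = r0 + dr
        if not 0 <= r < grid.n_radial:
            continue
        for da in range(-ang_span, ang_span + 1):
            a = (a0 + da) % grid.n_angular
            idx.append(r * grid.n_angular + a)
    return np.asarray(idx)


def _mask_around(grid, pattern: np.ndarray, cell: int, ang_excl: int = 4):
    """Copy of ``pattern`` with the angular sector around ``cell`` zeroed
    (to expose the secondary local maximum)."""
    out = pattern.copy()
    _, a0 = divmod(int(cell), grid.n_angular)
    da = np.abs((np.arange(grid.n_angular) - a0 + grid.n_angular // 2)
                % grid.n_angular - grid.n_angular // 2)
    sector = np.tile(da <= ang_excl, grid.n_radial)
    out[sector] = 0.0
    return out


def _attend_in_imagery(model: Model, pw_injection: np.ndarray, n_steps=300):
    """Boost a parietal cluster during imagery and let the identity
    competition resolve.

    Attention restores full transmission for the boosted cluster (gain
    modulation), so the injected parietal current reaches the OVCs at
    full strength even though the bottom-up direction is globally
    suppressed during imagery; the learned OVC-to-identity weights then
    drive the corresponding identity neuron, whose mutual inhibition
    suppresses the previous winner.  Returns True if the winner changed.
    """
    from .memory import mtl_step
    from .transform import BOTTOM_UP as _FULL

    before = int(np.argmax(model.state.pro))
    for _ in range(n_steps):
        model.pw_o = np.clip(
            model._allo_to_ego(model.state.ovc, TOP_DOWN) + pw_injection, 0, 1
        )
        # attended cluster passes at full gain; the rest at the
        # suppressed imagery gain
        att_ovc = model._ego_to_allo(pw_injection, _FULL)
        rest_ovc = model._ego_to_allo(model.pw_o, TOP_DOWN)
        model.state = mtl_step(
            model.state, model.weights,
            ego_drive_ovc=np.clip(att_ovc + rest_ovc, 0, 1),
            bottom_up_gain=TOP_DOWN.ego_gain, top_down_gain=TOP_DOWN.allo_gain,
            competition=model.comp, pc_lesion=model.pc_lesion,
        )
    return int(np.argmax(model.state.pro)) != before


# -- Simulation 4.0: mental navigation ---------------------------------------


def _sim_mental_navigation(config: SimulationConfig) -> SimulationResult:
    """Encode three objects along a trajectory, recall object 1, then
    mentally navigate East.  The imagined path crosses the area where
    object 3 was encoded — approached from the North during perception,
    but from the West in imagery — so the object populates the imagined
    scene on a side never experienced."""
    rng = np.random.default_rng(config.seed)
    env = config.env or square_arena(
        100.0, objects=[(35.0, 65.0), (65.0, 80.0), (60.0, 40.0)]
    )
    model = Model(env, seed=config.seed)
    _apply_perturbations(model, config)
    trace = _new_trace(model, config)
    trace.meta["simulation_id"] = "4.0"

    # object 1 encoded heading East near (13, 65); object 2 en route;
    # object 3 encoded heading South near (61, 70)
    wps = [
        _jitter(rng, (10, 65), 1.0), (20.0, 65.0), _jitter(rng, (45, 76), 1.5),
        (62.0, 76.0), (58.0, 45.0), _jitter(rng, (30, 25), 2.0),
    ]
    traj = generate_trajectory(env, wps, speed=AGENT_SPEED)
    events = model.run_trajectory(traj, trace=trace)

    recall = model.cue_recall("1", trace=trace, agent=traj.states[-1])

    # imagined straight line from the recalled viewpoint through the area
    # where object 3 was encoded, continuing past it
    start_pos = (model.imagined_pos if model.imagined_pos is not None
                 else np.array([15.0, 65.0]))
    target = (model.weights.events["3"].position
              if "3" in model.weights.events else np.array([61.0, 70.0]))
    heading = float(np.arctan2(*(target - start_pos)[::-1]))
    n_cmd = int((np.hypot(*(target - start_pos)) + 25.0) / 0.25)
    commands = [(0.25, heading)] * n_cmd
    t0 = model.t
    nav = model.mental_navigate(commands, trace=trace)
    trace.mark_segment("mental_navigation", t0, model.t)
    return SimulationResult(
        trace, model, recalls={"1": recall},
        extras={"nav": nav, "events": events},
    )


# -- Simulation 5.0: planning, short-cutting, preplay ------------------------


def shortcut_arena(side: float = 100.0) -> Environment:
    """Arena whose north-west pocket is walled off by a barrier hanging
    from the North wall (reachable only the long way around)."""
    s = side
    spec = {
        "extent": [0, 0, s, s],
        "boundaries": [
            {"id": "wall_S", "points": [[0, 0], [s, 0]]},
            {"id": "wall_E", "points": [[s, 0], [s, s]]},
            {"id": "wall_N", "points": [[s, s], [0, s]]},
            {"id": "wall_W", "points": [[0, s], [0, 0]]},
            {"id": "barrier", "points": [[0.4 * s, s], [0.4 * s, 0.4 * s]]},
        ],
        "objects": [],
    }
    return geo.build_environment(spec)


def _sim_shortcut(config: SimulationConfig) -> SimulationResult:
    """Plan a straight path across the unexplored blocked pocket
    (reservoir preplay), traverse it for real once the barrier is gone
    (Hebbian binding), then image the shortcut (replay plus a
    reconstructed scene)."""
    blocked = shortcut_arena(100.0)
    open_env = square_arena(100.0)
    from .memory import train_context

    model = Model(open_env, seed=config.seed)
    # the context is familiar everywhere except the blocked pocket
    centers = model.layout.centers
    explored = ~((centers[:, 0] < 40.0) & (centers[:, 1] > 42.0))
    model.weights = train_context(blocked, model.layout, model.grid)
    model.weights.stored_bvc *= explored[:, None]
    model.weights.stored_prb *= explored[:, None]
    model.weights.bvc_unit = model.weights.stored_bvc / np.maximum(
        np.linalg.norm(model.weights.stored_bvc, axis=1, keepdims=True), 1e-9
    )
    _apply_perturbations(model, config)
    trace = _new_trace(model, config)
    trace.meta["simulation_id"] = "5.0"

    pool = make_reservoir(200, model.gc, seed=config.seed)
    start, goal = np.array([68.0, 75.0]), np.array([14.0, 75.0])
    heading = float(np.arctan2(*(goal - start)[::-1]))

    # phase 1: plan and imagine the straight shortcut
    path = plan_vector_trajectory(start, goal, step=0.25)
    preplay = sweep_reservoir(pool, model.gc, path[:: 4])

    model.state = MTLState.zeros(model.layout.n_cells, model.grid.n_cells,
                                 model.weights.n_prb, model.weights.n_pro)
    from .grids import gc_drive as _gcd
    from .populations import place_rates as _pr

    model.state.pc = _pr(model.layout, _gcd(model.gcpc, model.gc, start),
                         n_steps=150, competition=model.comp)
    model.imagined_pos = start.copy()
    model.set_heading(heading)
    nav_pre = model.mental_navigate([(0.25, heading)] * (len(path) - 1))
    pw_pre = np.array([s["pw_b"] for s in nav_pre])
    pos_pre = np.array([s["imagined_pos"] for s in nav_pre])

    # phase 2: the barrier is removed; real bottom-up traversal with
    # Hebbian binding of reservoir units to the perceived boundary scene
    model.env = open_env
    traj = generate_trajectory(open_env, [tuple(start), tuple(goal)],
                               speed=0.25)
    model.set_heading(heading)
    model.mode = BOTTOM_UP
    t0 = model.t
    replay_rates, bvc_seq = [], []
    for s in traj:
        model.step_bottom_up(s, trace=trace)
        r_res = sweep_reservoir(pool, model.gc, s.position[None, :])[0]
        replay_rates.append(r_res)
        bvc_seq.append(model.state.bvc.copy())
    trace.mark_segment("traversal", t0, model.t)
    replay_rates = np.array(replay_rates)
    W_bvc_res = bind_reservoir(pool, replay_rates, np.array(bvc_seq))

    # phase 3: imagery along the now-familiar shortcut
    pw_post, pos_post = [], []
    for xy in path[1:]:
        r_res = sweep_reservoir(pool, model.gc, xy[None, :])[0]
        bvc_rec = np.clip(W_bvc_res @ r_res / max(r_res.sum(), 1e-9), 0, 1)
        pw = np.clip(model._allo_to_ego(bvc_rec, TOP_DOWN), 0, 1)
        pw_post.append(pw)
        pos_post.append(xy.copy())
    pw_post = np.array(pw_post)
    pos_post = np.array(pos_post)

    return SimulationResult(
        trace, model,
        extras={
            "pool": pool, "path": path, "heading": heading,
            "preplay": preplay, "replay": replay_rates,
            "pw_pre": pw_pre, "pos_pre": pos_pre,
            "pw_post": pw_post, "pos_post": pos_post,
            "W_bvc_res": W_bvc_res, "explored_mask": explored,
        },
    )


def bind_reservoir(pool, traversal_rates, bvc_rates):
    """Hebbian binding of reservoir units to perceived boundary patterns.

    ``traversal_rates`` (n_steps, n_units) and ``bvc_rates``
    (n_steps, n_bvc) come from a real bottom-up traversal; returns the
    (n_bvc, n_units) association matrix, normalized per unit by its total
    firing so that imagery drive reconstructs the typical boundary
    pattern at the unit's firing locations.
    """
    R = np.asarray(traversal_rates, dtype=float)
    B = np.asarray(bvc_rates, dtype=float)
    W = np.zeros((B.shape[1], R.shape[1]))
    for r, b in zip(R, B):
        W += np.outer(b, r)
    return W / np.maximum(R.sum(axis=0), 1e-9)[None, :]
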