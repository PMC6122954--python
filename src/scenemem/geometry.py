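"""Environments, the moving agent, and egocentric sensing.

Environments are flat 2D arenas made of labeled boundary polylines and
labeled point objects.  The agent is a point with an allocentric heading;
it senses boundary segments and objects within a 180-degree forward field
of view, with occlusion.  All distances are in centimetres; angles are in
radians, counterclockwise from +x (East), so "facing North" is heading
pi/2.  Egocentric bearing 0 means straight ahead, positive bearings are to
the agent's left (allocentric direction = bearing + heading).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.ops import polygonize, unary_union


class GeometryError(ValueError):
    """Invalid or degenerate environment geometry."""


def wrap_angle(a):
    """Wrap angle(s) to [-pi, pi)."""
    return (np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi


def wrap_positive(a):
    """Wrap angle(s) to [0, 2*pi)."""
    return np.asarray(a) % (2.0 * np.pi)


@dataclass(frozen=True)
class Boundary:
    """A labeled polyline boundary element (walls, barriers)."""

    identity: str
    points: np.ndarray  # (n, 2), n >= 2

    def segments(self) -> np.ndarray:
        """Return (n-1, 2, 2) array of consecutive segments."""
        p = self.points
        return np.stack([p[:-1], p[1:]], axis=1)


@dataclass(frozen=True)
class Obj:
    """A labeled point object."""

    identity: str
    position: np.ndarray  # (2,)


@dataclass(frozen=True)
class Environment:
    """A closed 2D arena with labeled boundaries and point objects."""

    boundaries: tuple[Boundary, ...]
    objects: tuple[Obj, ...]
    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    _polygon: Polygon = field(repr=False, compare=False, default=None)

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    def boundary_index(self, identity: str) -> int:
        for i, b in enumerate(self.boundaries):
            if b.identity == identity:
                return i
        raise KeyError(f"unknown boundary identity {identity!r}")

    def object_index(self, identity: str) -> int:
        for i, o in enumerate(self.objects):
            if o.identity == identity:
                return i
        raise KeyError(f"unknown object identity {identity!r}")

    def all_segments(self) -> tuple[np.ndarray, np.ndarray]:
        """All boundary segments as ((m,2) starts, (m,2) ends)."""
        cached = getattr(self, "_segcache", None)
        if cached is not None:
            return cached
        a, b = [], []
        for bd in self.boundaries:
            s = bd.segments()
            a.append(s[:, 0])
            b.append(s[:, 1])
        out = (np.concatenate(a), np.concatenate(b))
        object.__setattr__(self, "_segcache", out)
        return out

    def contains(self, xy) -> bool:
        return self._polygon.contains(Point(float(xy[0]), float(xy[1])))


@dataclass
class AgentState:
    """Pose of the point agent at one time step."""

    position: np.ndarray  # (2,) cm
    heading: float  # rad, allocentric, in [0, 2pi)
    angular_velocity: float = 0.0  # rad per step
    speed: float = 0.0  # cm per step


@dataclass
class Trajectory:
    """Ordered agent states at a fixed time step."""

    states: list[AgentState]
    dt: float = 1.0

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.states])

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            (i * self.dt, s.position[0], s.position[1], s.heading, s.angular_velocity)
            for i, s in enumerate(self.states)
        ]
        pd.DataFrame(
            rows, columns=["t", "x", "y", "heading", "angular_velocity"]
        ).to_csv(path, index=False)


def build_environment(spec: dict) -> Environment:
    """Construct and validate an :class:`Environment` from a spec dict.

    The spec mirrors the JSON interchange format::

        {"boundaries": [{"id": ..., "points": [[x, y], ...]}, ...],
         "objects": [{"id": ..., "xy": [x, y]}, ...],
         "extent": [xmin, ymin, xmax, ymax]}

    The union of boundary segments must enclose a region of nonzero area
    (a closed arena); objects must lie inside it.
    """
    extent = tuple(float(v) for v in spec["extent"])
    boundaries = tuple(
        Boundary(str(b["id"]), np.asarray(b["points"], dtype=float))
        for b in spec["boundaries"]
    )
    if len({b.identity for b in boundaries}) != len(boundaries):
        raise GeometryError("boundary identities must be unique")
    objects = tuple(
        Obj(str(o["id"]), np.asarray(o["xy"], dtype=float))
        for o in spec.get("objects", [])
    )
    if len({o.identity for o in objects}) != len(objects):
        raise GeometryError("object identities must be unique")

    n_segments = sum(len(b.points) - 1 for b in boundaries)
    if n_segments < 3:
        raise GeometryError("need at least 3 boundary segments to enclose an arena")

    from shapely.geometry import LineString

    lines = unary_union(
        [LineString(b.points) for b in boundaries if len(b.points) >= 2]
    )
    polys = list(polygonize(lines))
    if not polys:
        raise GeometryError("boundaries do not enclose a region (open arena)")
    arena = max(polys, key=lambda p: p.area)

    xmin, ymin, xmax, ymax = extent
    for b in boundaries:
        p = b.points
        if (p[:, 0] < xmin).any() or (p[:, 0] > xmax).any() or (
            p[:, 1] < ymin
        ).any() or (p[:, 1] > ymax).any():
            raise GeometryError(f"boundary {b.identity!r} exceeds extent")
    for o in objects:
        if not arena.contains(Point(*o.position)):
            raise GeometryError(f"object {o.identity!r} outside the arena")

    return Environment(boundaries, objects, extent, _polygon=arena)


def square_arena(side: float = 100.0, objects=()) -> Environment:
    """Convenience constructor: a side x side square arena at the origin."""
    s = float(side)
    spec = {
        "extent": [0.0, 0.0, s, s],
        "boundaries": [
            {"id": "wall_S", "points": [[0, 0], [s, 0]]},
            {"id": "wall_E", "points": [[s, 0], [s, s]]},
            {"id": "wall_N", "points": [[s, s], [0, s]]},
            {"id": "wall_W", "points": [[0, s], [0, 0]]},
        ],
        "objects": [{"id": str(i + 1), "xy": list(xy)} for i, xy in enumerate(objects)],
    }
    return build_environment(spec)


def load_environment(path) -> Environment:
    with open(path) as fh:
        return build_environment(json.load(fh))


def save_environment(env: Environment, path) -> None:
    spec = {
        "extent": list(env.extent),
        "boundaries": [
            {"id": b.identity, "points": b.points.tolist()} for b in env.boundaries
        ],
        "objects": [
            {"id": o.identity, "xy": o.position.tolist()} for o in env.objects
        ],
    }
    with open(path, "w") as fh:
        json.dump(spec, fh, indent=1)


def mutate_environment(
    env: Environment, action: str, target: str, new_position=None
) -> Environment:
    """Return a modified copy of ``env`` (the original is unchanged).

    ``action`` is one of ``move_object``, ``remove_object``,
    ``remove_boundary``.
    """
    if action == "move_object":
        i = env.object_index(target)
        if new_position is None:
            raise ValueError("move_object requires new_position")
        objs = list(env.objects)
        objs[i] = Obj(target, np.asarray(new_position, dtype=float))
        if not env.contains(objs[i].position):
            raise GeometryError("new object position outside the arena")
        return replace(env, objects=tuple(objs))
    if action == "remove_object":
        i = env.object_index(target)
        objs = [o for j, o in enumerate(env.objects) if j != i]
        return replace(env, objects=tuple(objs))
    if action == "remove_boundary":
        i = env.boundary_index(target)
        bds = [b for j, b in enumerate(env.boundaries) if j != i]
        new = replace(env, boundaries=tuple(bds))
        # Revalidate closure with the remaining boundaries.
        from shapely.geometry import LineString

        lines = unary_union([LineString(b.points) for b in new.boundaries])
        polys = list(polygonize(lines))
        if not polys:
            raise GeometryError("removing boundary would open the arena")
        return replace(new, _polygon=max(polys, key=lambda p: p.area))
    raise ValueError(f"unknown action {action!r}")


# ---------------------------------------------------------------------------
# sensing


_SAMPLE_CACHE: dict = {}


def _sample_boundaries(env: Environment, spacing: float):
    """Sample all boundary polylines at ~spacing cm (cached per
    environment instance).

    Returns (points (n,2), boundary index per point, unit tangents).
    """
    key = (id(env), spacing)
    hit = _SAMPLE_CACHE.get(key)
    if hit is not None:
        return hit
    pts, idx, tans = [], [], []
    for bi, b in enumerate(env.boundaries):
        for seg in b.segments():
            a, c = seg
            length = float(np.hypot(*(c - a)))
            n = max(int(np.ceil(length / spacing)), 1)
            t = (np.arange(n) + 0.5) / n
            pts.append(a[None, :] + t[:, None] * (c - a)[None, :])
            idx.extend([bi] * n)
            tans.append(np.tile((c - a) / max(length, 1e-12), (n, 1)))
    out = (np.concatenate(pts), np.asarray(idx), np.concatenate(tans))
    if len(_SAMPLE_CACHE) > 64:
        _SAMPLE_CACHE.clear()
    _SAMPLE_CACHE[key] = out
    return out


def _ray_blocked(origin: np.ndarray, targets: np.ndarray, seg_a, seg_b) -> np.ndarray:
    """For each target point, is the open segment origin->target crossed
    by any boundary segment strictly before the target?

    Vectorized segment-segment intersection over (targets x segments).
    """
    d = targets - origin[None, :]  # (n, 2) ray directions
    e = seg_b - seg_a  # (m, 2) segment directions
    f = seg_a[None, :, :] - origin[None, None, :].reshape(1, 1, 2)  # (1, m, 2)
    # Solve origin + t*d = a + u*e for t, u via 2x2 cross products.
    denom = d[:, None, 0] * (-e[None, :, 1]) - d[:, None, 1] * (-e[None, :, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (f[..., 0] * (-e[None, :, 1]) - f[..., 1] * (-e[None, :, 0])) / denom
        u = (d[:, None, 0] * f[..., 1] - d[:, None, 1] * f[..., 0]) / denom
    eps = 1e-9
    hit = (
        np.isfinite(t)
        & (t > eps)
        & (t < 1.0 - 1e-6)
        & (u >= -eps)
        & (u <= 1.0 + eps)
    )
    return hit.any(axis=1)


def visible_boundary_points(
    env: Environment,
    agent: AgentState,
    sample_spacing: float = 2.5,
    fov_half_angle: float = np.pi / 2,
):
    """Boundary samples visible from the agent's pose.

    Returns ``(distances, bearings, boundary_ids, weights)`` for samples
    whose egocentric bearing lies in [-fov, +fov] and whose line of sight
    is unobstructed.  ``weights`` is the angle subtended by each sample
    (sample arc length projected onto the viewing circle), the natural
    weight for boundary-driven receptive-field responses.
    """
    pos = np.asarray(agent.position, dtype=float)
    if not env.contains(pos):
        raise GeometryError("agent is on or outside the arena boundary")
    pts, idx, tans = _sample_boundaries(env, sample_spacing)
    rel = pts - pos[None, :]
    dist = np.hypot(rel[:, 0], rel[:, 1])
    if (dist < 1e-9).any():
        raise GeometryError("agent coincides with a boundary sample")
    allo = np.arctan2(rel[:, 1], rel[:, 0])
    bearing = wrap_angle(allo - agent.heading)
    in_fov = np.abs(bearing) <= fov_half_angle + 1e-12

    seg_a, seg_b = env.all_segments()
    blocked = _ray_blocked(pos, pts, seg_a, seg_b)
    vis = in_fov & ~blocked

    # Angle subtended by each sample: spacing * sin(incidence) / distance
    # (grazing samples subtend little), capped against blow-up when the
    # agent grazes a wall.
    ray = rel / dist[:, None]
    cross = np.abs(ray[:, 0] * tans[:, 1] - ray[:, 1] * tans[:, 0])
    weights = np.minimum(sample_spacing * cross / dist, 0.5)
    ids = [env.boundaries[i].identity for i in idx[vis]]
    return dist[vis], bearing[vis], ids, weights[vis]


def surround_boundary_points(env: Environment, position, sample_spacing: float = 2.5):
    """Full 360-degree visible boundary samples from a location.

    Used to build the stored allocentric boundary representation of a
    familiar location (training sees all orientations).  Returns
    ``(distances, allocentric directions, boundary ids, weights)``.
    """
    agent = AgentState(np.asarray(position, dtype=float), 0.0)
    d, bearing, ids, w = visible_boundary_points(
        env, agent, sample_spacing, fov_half_angle=np.pi + 1e-9
    )
    return d, wrap_positive(bearing), ids, w


def visible_objects(env: Environment, agent: AgentState, fov_half_angle=np.pi / 2):
    """Distances/bearings/visibility of all objects from the agent's pose.

    Returns a list of ``(distance, bearing, identity, visible)`` tuples,
    one per object, in environment order.  ``visible`` is True iff the
    object is within the forward field of view and not occluded.
    """
    pos = np.asarray(agent.position, dtype=float)
    out = []
    if not env.objects:
        return out
    seg_a, seg_b = env.all_segments()
    targets = np.array([o.position for o in env.objects])
    rel = targets - pos[None, :]
    dist = np.hypot(rel[:, 0], rel[:, 1])
    bearing = wrap_angle(np.arctan2(rel[:, 1], rel[:, 0]) - agent.heading)
    blocked = _ray_blocked(pos, targets, seg_a, seg_b)
    for o, di, be, bl in zip(env.objects, dist, bearing, blocked):
        visible = bool((abs(be) <= fov_half_angle + 1e-12) and not bl)
        out.append((float(di), float(be), o.identity, visible))
    return out


def generate_trajectory(
    env: Environment,
    waypoints,
    speed: float = 0.25,
    dt: float = 1.0,
    turn_rate: float = np.deg2rad(3.0),
    min_states: int = 1,
) -> Trajectory:
    """Piecewise-linear waypoint-following trajectory.

    The agent walks each leg at constant ``speed`` (cm per step) and turns
    in place at ``turn_rate`` (rad per step) at the junctions, so headings
    stay consistent with the direction of travel.  A single waypoint gives
    a stationary trajectory of ``min_states`` steps.
    """
    wps = [np.asarray(w, dtype=float) for w in waypoints]
    for w in wps:
        if not env.contains(w):
            raise GeometryError(f"waypoint {w} outside the arena")
    states: list[AgentState] = []
    if len(wps) == 1:
        for _ in range(max(min_states, 1)):
            states.append(AgentState(wps[0].copy(), 0.0, 0.0, 0.0))
        return Trajectory(states, dt)

    heading = None
    pos = wps[0].copy()
    for nxt in wps[1:]:
        leg = nxt - pos
        leg_len = float(np.hypot(*leg))
        if leg_len < 1e-9:
            continue
        target_heading = float(np.arctan2(leg[1], leg[0]))
        if heading is None:
            heading = target_heading
        # turn in place toward the leg heading
        dh = float(wrap_angle(target_heading - heading))
        n_turn = int(np.ceil(abs(dh) / turn_rate))
        for k in range(n_turn):
            step = np.clip(dh, -turn_rate, turn_rate)
            heading = float(wrap_positive(heading + step))
            dh = float(wrap_angle(target_heading - heading))
            states.append(AgentState(pos.copy(), heading, step, 0.0))
        heading = float(wrap_positive(target_heading))
        # walk the leg
        n_walk = max(int(round(leg_len / (speed * dt))), 1)
        direction = leg / leg_len
        step_len = leg_len / n_walk
        for k in range(1, n_walk + 1):
            pos = wps[0] * 0 + (nxt - direction * (leg_len - k * step_len))
            states.append(AgentState(pos.copy(), heading, 0.0, step_len / dt))
        pos = nxt.copy()
    while len(states) < min_states:
        states.append(AgentState(pos.copy(), heading or 0.0, 0.0, 0.0))
    return Trajectory(states, dt)


def coverage_waypoints(env: Environment, margin: float = 10.0, n_rows: int = 8):
    """Serpentine waypoints covering the arena interior, for rate maps."""
    xmin, ymin, xmax, ymax = env.extent
    xs = (xmin + margin, xmax - margin)
    ys = np.linspace(ymin + margin, ymax - margin, n_rows)
    wps = []
    for i, y in enumerate(ys):
        pair = [(xs[0], y), (xs[1], y)] if i % 2 == 0 else [(xs[1], y), (xs[0], y)]
        wps.extend(pair)
    # drop waypoints that fall outside (e.g. inside a barrier region)
    return [w for w in wps if env.contains(np.asarray(w))]
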