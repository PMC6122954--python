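"""Quantification and I/O: population-vector correlations, novelty
scores, firing-rate maps, vector/trace-field detection, trace
persistence, and snapshot rendering.

Recall quality is measured as in the experimental literature on
representational overlap: the Pearson correlation between a population
vector at recall and at encoding (RvE), compared against the mean
correlation between the recall vector and perceptual vectors sampled at
regular intervals along the trajectory (RvRP), which is the chance
baseline.  Firing-rate maps are occupancy-normalized means over spatial
bins, the standard visualization for spatially selective neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AgentState

_EPS = 1e-12


# ---------------------------------------------------------------------------
# simulation trace


@dataclass
class SimulationTrace:
    """Time-indexed record of agent state, mode, and population rates."""

    populations: tuple[str, ...]
    meta: dict = field(default_factory=dict)
    _t: list = field(default_factory=list)
    _pose: list = field(default_factory=list)  # (x, y, heading, ang_vel)
    _mode: list = field(default_factory=list)  # 0 bottom_up, 1 top_down
    _attended: list = field(default_factory=list)  # attended object id or ""
    _rates: dict = field(default_factory=dict)
    events: list = field(default_factory=list)  # (t, object_id, x, y, heading)
    segments: dict = field(default_factory=dict)  # name -> (start, stop) step idx

    def __post_init__(self):
        for p in self.populations:
            self._rates.setdefault(p, [])

    def __len__(self) -> int:
        return len(self._t)

    def record(self, t: int, agent: AgentState, mode: str, snapshot: dict,
               event, attended: str | None = None):
        if self._t and t <= self._t[-1]:
            raise ValueError("trace timestamps must strictly increase")
        self._t.append(int(t))
        self._attended.append(attended or "")
        self._pose.append(
            (
                float(agent.position[0]), float(agent.position[1]),
                float(agent.heading), float(agent.angular_velocity),
            )
        )
        self._mode.append(0 if mode == "bottom_up" else 1)
        for p in self.populations:
            self._rates[p].append(np.asarray(snapshot[p], dtype=np.float32).copy())
        if event is not None:
            self.events.append(
                (
                    int(t), event.object_id,
                    float(event.position[0]), float(event.position[1]),
                    float(event.heading),
                )
            )

    def mark_segment(self, name: str, start: int, stop: int) -> None:
        self.segments[name] = (int(start), int(stop))

    # -- array views --------------------------------------------------------

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self._t)

    @property
    def pose(self) -> np.ndarray:
        return np.asarray(self._pose, dtype=float).reshape(-1, 4)

    @property
    def mode(self) -> np.ndarray:
        return np.asarray(self._mode)

    @property
    def attended(self) -> np.ndarray:
        return np.asarray(self._attended)

    def rates(self, population: str) -> np.ndarray:
        return np.asarray(self._rates[population], dtype=np.float32)


# ---------------------------------------------------------------------------
# correlations


def population_vector_correlation(a, b) -> float:
    """Pearson correlation between two population rate vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("population vectors must have equal length")
    if a.std() < _EPS and b.std() < _EPS:
        raise ValueError("correlation undefined: both vectors are constant")
    if a.std() < _EPS or b.std() < _EPS:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class CorrelationReport:
    """Recall-vs-encoding and recall-vs-random-pattern correlations."""

    rve: dict  # population -> r
    rvrp: dict  # population -> mean r over random samples
    n_samples: dict  # population -> number of random samples
    rvrp_sd: dict = field(default_factory=dict)


def correlation_report(
    trace: SimulationTrace,
    encoding_snapshot: dict,
    recall_segment: tuple[int, int],
    sample_every: int = 100,
    populations=None,
    settle_fraction: float = 0.25,
) -> CorrelationReport:
    """RvE and RvRP for each population.

    The recall state is the temporal mean of the last ``settle_fraction``
    of the recall segment; the random baseline samples bottom-up states
    every ``sample_every`` steps outside the recall segment.
    """
    pops = populations or [p for p in trace.populations if p != "HD"]
    lo, hi = recall_segment
    idx = np.nonzero((trace.t >= lo) & (trace.t < hi))[0]
    if len(idx) == 0:
        raise ValueError("recall segment not present in trace")
    tail = idx[int(np.floor(len(idx) * (1.0 - settle_fraction))):]
    bottom_up = np.nonzero((trace.mode == 0) & ((trace.t < lo) | (trace.t >= hi)))[0]
    samples = bottom_up[::sample_every]

    rve, rvrp, ns, sd = {}, {}, {}, {}
    for p in pops:
        r = trace.rates(p)
        recall_state = r[tail].mean(axis=0)
        enc = np.asarray(encoding_snapshot[p], dtype=float)
        try:
            rve[p] = population_vector_correlation(recall_state, enc)
        except ValueError:
            rve[p] = float("nan")  # degenerate (constant) pair, flagged
        rs = []
        for s in samples:
            try:
                rs.append(population_vector_correlation(recall_state, r[s]))
            except ValueError:
                continue
        rvrp[p] = float(np.mean(rs)) if rs else float("nan")
        sd[p] = float(np.std(rs)) if rs else float("nan")
        ns[p] = len(rs)
    return CorrelationReport(rve, rvrp, ns, sd)


def novelty_mismatch(encoded: dict, recalled: dict) -> dict:
    """Per-object novelty score: 1 - r(perceived, recalled), in [0, 1].

    ``encoded`` maps object id to the object-vector-cell pattern
    perceived at test (from the encoding vantage point); ``recalled``
    maps object id to the recalled (imagery) pattern.
    """
    if set(encoded) != set(recalled):
        raise KeyError("object sets differ between perceived and recalled input")
    out = {}
    for k in encoded:
        r = population_vector_correlation(encoded[k], recalled[k])
        out[k] = float(np.clip(1.0 - r, 0.0, 1.0))
    return out


# ---------------------------------------------------------------------------
# rate maps


@dataclass
class RateMap:
    """Occupancy-normalized firing-rate map on a square spatial binning."""

    rate: np.ndarray  # (nx, ny), nan on unvisited bins
    occupancy: np.ndarray  # (nx, ny) steps spent per bin
    edges_x: np.ndarray
    edges_y: np.ndarray

    @property
    def bin_size(self) -> float:
        return float(self.edges_x[1] - self.edges_x[0])

    def bin_centers(self):
        cx = 0.5 * (self.edges_x[:-1] + self.edges_x[1:])
        cy = 0.5 * (self.edges_y[:-1] + self.edges_y[1:])
        return cx, cy


def compute_rate_map(
    trace: SimulationTrace,
    population: str,
    cell: int,
    bin_size: float = 4.0,
    extent=None,
    step_mask=None,
    smooth_bins: float = 0.0,
    min_occupancy: float = 1.0,
) -> RateMap:
    """Time-averaged firing-rate map of one cell over a trace.

    ``step_mask`` optionally restricts the average to a subset of steps
    (e.g. the top-down phases of the theta-gated protocols, matching the
    high-top-down-gain maps used to expose memory traces).  With
    ``smooth_bins`` > 0 the rate and occupancy histograms are smoothed
    with a Gaussian of that width before division (the conventional
    occupancy-weighted smoothing of firing-rate maps).
    """
    pose = trace.pose
    rates = trace.rates(population)[:, cell].astype(float)
    if step_mask is not None:
        sel = np.asarray(step_mask, dtype=bool)
        pose, rates = pose[sel], rates[sel]
    if len(pose) == 0:
        raise ValueError("no occupancy in trace")
    if extent is None:
        extent = trace.meta.get("extent")
    if extent is None:
        extent = (
            pose[:, 0].min(), pose[:, 1].min(), pose[:, 0].max(), pose[:, 1].max()
        )
    xmin, ymin, xmax, ymax = extent
    ex = np.arange(xmin, xmax + bin_size, bin_size)
    ey = np.arange(ymin, ymax + bin_size, bin_size)
    occ, _, _ = np.histogram2d(pose[:, 0], pose[:, 1], bins=(ex, ey))
    tot, _, _ = np.histogram2d(
        pose[:, 0], pose[:, 1], bins=(ex, ey), weights=rates
    )
    occ_s, tot_s = occ, tot
    if smooth_bins > 0:
        from scipy.ndimage import gaussian_filter

        occ_s = gaussian_filter(occ, smooth_bins)
        tot_s = gaussian_filter(tot, smooth_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        # mask on the raw occupancy: smoothing must never manufacture
        # rate estimates in bins the agent never visited
        rate = np.where(
            occ >= min_occupancy, tot_s / np.maximum(occ_s, 1e-12), np.nan
        )
    return RateMap(rate, occ, ex, ey)


def _fields(map_: RateMap, threshold_frac: float = 0.5, min_bins: int = 3):
    """Connected firing fields above a fraction of the map maximum.

    Returns a list of ``(centroid_xy, peak_rate, n_bins)``.
    """
    from scipy import ndimage

    r = np.nan_to_num(map_.rate, nan=0.0)
    if r.max() <= 0:
        return []
    mask = r >= threshold_frac * r.max()
    labels, n = ndimage.label(mask)
    cx, cy = map_.bin_centers()
    out = []
    for k in range(1, n + 1):
        sel = labels == k
        if sel.sum() < min_bins:
            continue
        w = r * sel
        wx = (w.sum(axis=1) @ cx) / w.sum()
        wy = (w.sum(axis=0) @ cy) / w.sum()
        out.append((np.array([wx, wy]), float(r[sel].max()), int(sel.sum())))
    return out


def detect_vector_field(map_: RateMap, object_positions) -> list:
    """Vector-cell analysis of a rate map given object locations.

    Matches firing fields (connected regions above half the map maximum)
    one-to-one to objects by minimizing the total object-to-field
    distance (a nearest-field rule misassigns whenever the shared offset
    exceeds half the object spacing).  Returns a list of
    ``(offset_vector, peak_rate)`` in object order; raises if no field
    exceeds threshold.
    """
    from scipy.optimize import linear_sum_assignment

    flds = _fields(map_)
    if not flds:
        raise ValueError("no firing field above half-maximum")
    objs = np.atleast_2d(np.asarray(object_positions, dtype=float))
    centers = np.array([f[0] for f in flds])
    cost = np.hypot(
        objs[:, None, 0] - centers[None, :, 0],
        objs[:, None, 1] - centers[None, :, 1],
    )
    if len(flds) >= len(objs):
        rows, cols = linear_sum_assignment(cost)
        match = dict(zip(rows, cols))
    else:  # fewer fields than objects: nearest assignment, reused
        match = {i: int(np.argmin(cost[i])) for i in range(len(objs))}
    return [(centers[match[i]] - objs[i], flds[match[i]][1])
            for i in range(len(objs))]


def detect_trace_field(
    map_: RateMap,
    removed_geometry,
    preferred_offset=None,
    tolerance: float = 15.0,
):
    """Detect a memory-trace field for removed geometry.

    A trace field is present iff some connected region above half the map
    maximum lies (after shifting by the cell's preferred offset vector,
    for boundary-vector cells) within ``tolerance`` cm of the removed
    boundary segment or object point.  Returns
    ``(present, peak_rate, distance_cm)``.
    """
    geom = np.asarray(removed_geometry, dtype=float)
    off = (
        np.zeros(2) if preferred_offset is None
        else np.asarray(preferred_offset, dtype=float)
    )
    flds = _fields(map_)
    if not flds:
        return False, 0.0, float("inf")

    def dist_to_geom(pt):
        if geom.ndim == 1:
            return float(np.hypot(*(geom - pt)))
        # distance to polyline
        best = np.inf
        for a, b in zip(geom[:-1], geom[1:]):
            ab = b - a
            tt = np.clip(np.dot(pt - a, ab) / max(np.dot(ab, ab), _EPS), 0, 1)
            best = min(best, float(np.hypot(*(a + tt * ab - pt))))
        return best

    best = min(
        ((dist_to_geom(cen + off), peak) for cen, peak, _ in flds),
        key=lambda x: x[0],
    )
    return best[0] <= tolerance, best[1], best[0]


# ---------------------------------------------------------------------------
# persistence


def write_trace(trace: SimulationTrace, path) -> None:
    """Lossless HDF5 serialization of a simulation trace."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = 1
        f.attrs["populations"] = [p.encode() for p in trace.populations]
        for k, v in trace.meta.items():
            try:
                f.attrs[f"meta_{k}"] = v
            except TypeError:
                f.attrs[f"meta_{k}"] = str(v)
        f.create_dataset("t", data=trace.t)
        f.create_dataset("pose", data=trace.pose)
        f.create_dataset("mode", data=trace.mode)
        f.create_dataset(
            "attended", data=np.array(trace._attended, dtype="S32")
        )
        for p in trace.populations:
            f.create_dataset(f"rates/{p}", data=trace.rates(p))
        ev = np.array(
            [(t, oid, x, y, h) for t, oid, x, y, h in trace.events],
            dtype=[("t", "i8"), ("object", "S32"), ("x", "f8"), ("y", "f8"),
                   ("heading", "f8")],
        )
        f.create_dataset("events", data=ev)
        seg = np.array(
            [(k, a, b) for k, (a, b) in trace.segments.items()],
            dtype=[("name", "S32"), ("start", "i8"), ("stop", "i8")],
        )
        f.create_dataset("segments", data=seg)


def read_trace(path) -> SimulationTrace:
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs.get("format_version") != 1:
            raise ValueError("unsupported or corrupt trace file")
        pops = tuple(
            p.decode() if isinstance(p, bytes) else str(p)
            for p in f.attrs["populations"]
        )
        tr = SimulationTrace(populations=pops)
        tr.meta = {
            k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")
        }
        tr._t = list(f["t"][...])
        tr._pose = [tuple(row) for row in f["pose"][...]]
        tr._mode = list(f["mode"][...])
        if "attended" in f:
            tr._attended = [s.decode() for s in f["attended"][...]]
        for p in pops:
            tr._rates[p] = [row for row in f[f"rates/{p}"][...]]
        tr.events = [
            (int(e["t"]), e["object"].decode(), float(e["x"]), float(e["y"]),
             float(e["heading"]))
            for e in f["events"][...]
        ]
        tr.segments = {
            s["name"].decode(): (int(s["start"]), int(s["stop"]))
            for s in f["segments"][...]
        }
    return tr


# ---------------------------------------------------------------------------
# rendering


def render_polar_snapshot(grid, rates, path, title="", ego=False):
    """Heat map of a polar-grid population snapshot (PNG).

    Cells are drawn at their receptive-field centers; for egocentric
    (parietal-window) populations 'ahead' is up, for allocentric
    populations North is up.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = grid.cell_xy()
    if ego:  # rotate so bearing 0 (ahead) points up
        xy = np.stack([-xy[:, 1], xy[:, 0]], axis=1)
    fig, ax = plt.subplots(figsize=(4, 4))
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=rates, s=14, cmap="viridis",
                    vmin=0, vmax=1)
    ax.set_aspect("equal")
    ax.set_title(title)
    fig.colorbar(sc, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=110)
    plt.close(fig)


def render_rate_map(map_: RateMap, path, title=""):
    """Rate map rendering with the conventional jet-style colormap
    (distinct from the snapshot colormap)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(
        map_.rate.T, origin="lower", cmap="jet",
        extent=(map_.edges_x[0], map_.edges_x[-1],
                map_.edges_y[0], map_.edges_y[-1]),
    )
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=110)
    plt.close(fig)
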