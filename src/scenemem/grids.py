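"""Grid-cell modules, grid-to-place weights, and reservoir cells.

Seven modules of 100 cells each provide a periodic population code for
location.  Within a module all cells share the lattice scale and
orientation and differ only in their 2D phase offset; a cell's rate at a
position is the rectified, unit-peak-normalized sum of three plane-wave
cosines whose wave vectors are 60 degrees apart (the standard closed-form
idealization of triangular-lattice grid fields).  Rate maps are evaluated
in closed form at any coordinate, so during imagery grid rates are simply
read out at the internally maintained imagined position.

Grid-to-place weights are Hebbian: the weight from a grid cell to a place
cell is proportional to the grid cell's rate at the place-field center,
so the combined grid drive for a place cell peaks at its field center
(the seven incommensurate scales break single-module periodicity).

Reservoir cells are uncommitted hippocampal units for unexplored space:
they receive only sparse random grid inputs and an adaptive feedback gain
that holds their total activity at the place-bump set point, so a
repeatable subset of them fires along any planned trajectory before the
territory has ever been visited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .populations import PlaceCompetition, PlaceLayout

DEFAULT_SCALES = (25.0, 32.0, 41.0, 52.0, 67.0, 86.0, 110.0)  # cm, ratio ~1.28
CELLS_PER_MODULE = 100


@dataclass(frozen=True)
class GridModules:
    """Closed-form rate maps for 7 x 100 grid cells."""

    scales: tuple[float, ...]
    orientations: np.ndarray  # (n_modules,)
    phases: np.ndarray  # (n_modules, cells_per_module, 2) offsets in cm
    seed: int

    @property
    def n_modules(self) -> int:
        return len(self.scales)

    @property
    def n_cells(self) -> int:
        return self.phases.shape[0] * self.phases.shape[1]

    def wave_vectors(self, m: int) -> np.ndarray:
        """Three wave vectors (3, 2) for module m, 60 degrees apart."""
        k = 4.0 * np.pi / (np.sqrt(3.0) * self.scales[m])
        angles = self.orientations[m] + np.deg2rad([0.0, 60.0, 120.0])
        return k * np.stack([np.cos(angles), np.sin(angles)], axis=1)

    def rates(self, xy) -> np.ndarray:
        """Firing rates of all cells at position(s) ``xy``.

        ``xy`` may be a single (2,) position or an (n, 2) array; returns
        (n_cells,) or (n, n_cells) with rates in [0, 1].
        """
        pos = np.atleast_2d(np.asarray(xy, dtype=float))
        out = []
        for m in range(self.n_modules):
            kv = self.wave_vectors(m)  # (3, 2)
            rel = pos[:, None, :] - self.phases[m][None, :, :]  # (n, c, 2)
            ph = np.einsum("ncx,kx->nck", rel, kv)
            g = np.clip(np.cos(ph).sum(axis=2) / 3.0, 0.0, None)
            out.append(g)
        res = np.concatenate(out, axis=1)
        return res[0] if np.asarray(xy).ndim == 1 else res


def build_grid_modules(
    seed: int = 0, scales=DEFAULT_SCALES
) -> GridModules:
    """Deterministically construct the grid modules for a seed.

    Orientations are drawn once per module; phases cover each module's
    unit cell on a regular 10 x 10 lattice (a uniform phase code).
    """
    scales = tuple(float(s) for s in scales)
    if any(s <= 0 for s in scales) or any(
        b <= a for a, b in zip(scales, scales[1:])
    ):
        raise ValueError("scales must be positive and increasing")
    rng = np.random.default_rng(seed)
    orientations = rng.uniform(0.0, np.pi / 3.0, len(scales))
    side = int(np.sqrt(CELLS_PER_MODULE))
    phases = np.zeros((len(scales), CELLS_PER_MODULE, 2))
    for m, s in enumerate(scales):
        # lattice basis of the triangular grid for module m
        theta = orientations[m]
        e1 = s * np.array([np.cos(theta), np.sin(theta)])
        e2 = s * np.array([np.cos(theta + np.pi / 3), np.sin(theta + np.pi / 3)])
        f = (np.arange(side) + 0.5) / side
        fa, fb = np.meshgrid(f, f, indexing="ij")
        phases[m] = fa.ravel()[:, None] * e1 + fb.ravel()[:, None] * e2
    return GridModules(scales, orientations, phases, int(seed))


@dataclass
class GCPCWeights:
    """Feedforward grid-to-place weights with mode-dependent gain."""

    W: np.ndarray  # (n_pc, n_gc), L2-normalized rows (matched filters)
    bottom_up_gain: float = 0.1
    top_down_gain: float = 1.0
    #: expansive dendritic nonlinearity applied to the summed grid input;
    #: sharpens the population drive so its global peak coincides with the
    #: represented position to well under a lattice spacing
    sharpness: float = 4.0


def learn_gc_pc(layout: PlaceLayout, modules: GridModules) -> GCPCWeights:
    """Hebbian association of grid rates with place-field positions.

    weight(g, p) is proportional to grid cell g's rate at place cell p's
    field center; rows are L2-normalized so the summed drive is the
    cosine match between the current grid state and the grid state at
    each field center (1 exactly on the center).
    """
    G = modules.rates(layout.centers)  # (n_pc, n_gc)
    W = G / np.maximum(np.linalg.norm(G, axis=1, keepdims=True), 1e-9)
    return GCPCWeights(W)


def gc_drive(weights: GCPCWeights, modules: GridModules, xy) -> np.ndarray:
    """Grid-cell drive onto the place population at position ``xy``."""
    g = modules.rates(np.asarray(xy, dtype=float))
    n = np.linalg.norm(g)
    if n <= 0:
        return np.zeros(weights.W.shape[0])
    d = np.clip(weights.W @ (g / n), 0.0, None)
    return d**weights.sharpness


def plan_vector_trajectory(start, goal, step: float = 2.0) -> np.ndarray:
    """Straight-line sample sequence from start to goal (inclusive).

    Vector-based planning ignores intervening barriers: the path is the
    Euclidean shortest path regardless of obstacles.
    """
    a = np.asarray(start, dtype=float)
    b = np.asarray(goal, dtype=float)
    dist = float(np.hypot(*(b - a)))
    if dist <= 0:
        raise ValueError("start and goal coincide")
    n = max(int(np.ceil(dist / step)), 1)
    t = np.linspace(0.0, 1.0, n + 1)
    return a[None, :] + t[:, None] * (b - a)[None, :]


@dataclass
class ReservoirPool:
    """Uncommitted place units driven by sparse random grid inputs."""

    n_units: int
    W: np.ndarray  # (n_units, n_gc) sparse random, fixed by seed
    seed: int
    theta: np.ndarray = None  # (n_units,) per-unit firing threshold
    set_point: float = PlaceCompetition.SET_POINT
    gain: float = 1.0
    connectivity: float = 0.05

    def copy(self) -> "ReservoirPool":
        return ReservoirPool(
            self.n_units, self.W.copy(), self.seed,
            None if self.theta is None else self.theta.copy(),
            self.set_point, self.gain, self.connectivity,
        )


def make_reservoir(
    n_units: int, modules: GridModules, seed: int, connectivity: float = 0.05
) -> ReservoirPool:
    """Sparse random grid-to-reservoir weights, deterministic per seed.

    Weights are scaled once so that the mean total pool drive over the
    central 100 cm region equals the place-bump set point; the adaptive
    feedback gain then only has to absorb fluctuations along a path and
    stays well inside its clamp range.
    """
    rng = np.random.default_rng(seed)
    mask = rng.random((n_units, modules.n_cells)) < connectivity
    W = rng.uniform(0.0, 1.0, (n_units, modules.n_cells)) * mask
    # per-unit firing threshold at the 80th percentile of each unit's
    # drive over the arena: with ~35 summed grid inputs per unit the raw
    # drive is dense, and only clearly above-baseline drive should fire
    probe = np.stack(
        np.meshgrid(np.linspace(5, 95, 12), np.linspace(5, 95, 12), indexing="ij"),
        axis=-1,
    ).reshape(-1, 2)
    raw = modules.rates(probe) @ W.T  # (n_probe, n_units)
    theta = np.quantile(raw, 0.8, axis=0)
    resp = np.clip(raw - theta[None, :], 0.0, None)
    scale = PlaceCompetition.SET_POINT / max(float(resp.sum(axis=1).mean()), 1e-9)
    return ReservoirPool(
        n_units, W * scale, int(seed), theta=theta * scale,
        connectivity=connectivity,
    )


def sweep_reservoir(
    pool: ReservoirPool, modules: GridModules, path
) -> np.ndarray:
    """Reservoir activity along a path of positions.

    At each point the raw drive through the sparse random weights is
    scaled by an adaptive feedback gain that tracks the place-bump
    activity set point (gain multiplicatively corrected each step and
    clamped to [0.1, 10]).  Returns the (n_points, n_units) rate series;
    the pool's gain is updated in place (it persists across sweeps).
    """
    path = np.atleast_2d(np.asarray(path, dtype=float))
    out = np.zeros((len(path), pool.n_units))
    theta = pool.theta if pool.theta is not None else 0.0
    for i, xy in enumerate(path):
        raw = np.clip(pool.W @ modules.rates(xy) - theta, 0.0, None)
        total = float(pool.gain * raw.sum())
        if total > 1e-12:
            # divisive feedback: the gain is corrected before rates are
            # emitted, holding the pool total at the bump set point
            pool.gain = float(
                np.clip(pool.gain * pool.set_point / total, 0.1, 10.0)
            )
        out[i] = np.clip(pool.gain * raw, 0.0, 1.0)
    return out


def peak_order(series: np.ndarray, active_threshold: float = 0.05) -> np.ndarray:
    """Indices of active units ordered by time of maximum firing."""
    active = np.nonzero(series.max(axis=0) > active_threshold)[0]
    t_peak = series[:, active].argmax(axis=0)
    return active[np.argsort(t_peak, kind="stable")]
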