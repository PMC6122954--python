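"""Receptive-field layouts and rate dynamics for the core populations.

Four populations share one polar receptive-field layout around the agent:
the egocentric parietal window pair (PWb for boundaries, PWo for objects)
and their allocentric counterparts (boundary vector cells, BVC, and object
vector cells, OVC).  Each cell is tuned to a distance ``d_i`` and a
direction ``phi_i``; the radial tuning width grows with distance
(sigma_rad(d) = 0.08 d + 3 cm), producing the characteristic teardrop
fields, while the angular width is one angular bin.  Place cells tile the
arena on a square lattice and compete through local excitation and global
inhibition so that a single activity bump forms.  Head direction is held
by a 100-cell ring attractor updated by angular velocity.

Rates are dimensionless in [0, 1]; one simulation step is the integration
time unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import wrap_angle

TAU = 20.0  # integrative time constant (place/identity dynamics), steps
TAU_RELAY = 2.0  # relay time constant (parietal window, BVC/OVC feed), steps


def sigma_rad(d):
    """Radial tuning width (cm) at tuning distance d (cm)."""
    return 0.08 * np.asarray(d, dtype=float) + 3.0


@dataclass(frozen=True)
class PolarGrid:
    """Shared polar receptive-field layout for PW/BVC/OVC populations.

    Cells are ordered radial-major: cell ``i * n_angular + j`` is tuned to
    distance ``radial_centers[i]`` and direction ``2*pi*j/n_angular``.
    """

    n_radial: int
    n_angular: int
    max_dist: float
    radial_edges: np.ndarray  # (n_radial + 1,)
    radial_centers: np.ndarray  # (n_radial,)
    sigma_ang: float

    @property
    def n_cells(self) -> int:
        return self.n_radial * self.n_angular

    @property
    def angular_centers(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_angular) / self.n_angular

    def cell_tuning(self):
        """(distances, directions) per cell, radial-major order."""
        d = np.repeat(self.radial_centers, self.n_angular)
        a = np.tile(self.angular_centers, self.n_radial)
        return d, a

    def cell_xy(self, allocentric: bool = True) -> np.ndarray:
        """Cartesian receptive-field centers, for plotting."""
        d, a = self.cell_tuning()
        return np.stack([d * np.cos(a), d * np.sin(a)], axis=1)


def make_polar_grid(
    n_radial: int = 16, n_angular: int = 51, max_dist: float = 160.0
) -> PolarGrid:
    """Build the polar grid with radial bin widths growing with distance.

    Bin widths are proportional to the radial tuning width at the bin
    position, so neighbouring fields overlap by a constant factor; the
    proportionality constant is solved so the bins exactly tile
    [0, max_dist].
    """
    if n_radial < 2 or n_angular < 8:
        raise ValueError("need n_radial >= 2 and n_angular >= 8")
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")

    def edges_for(c: float) -> np.ndarray:
        e = [0.0]
        for _ in range(n_radial):
            e.append(e[-1] + c * float(sigma_rad(e[-1])))
        return np.asarray(e)

    lo, hi = 1e-3, 100.0
    for _ in range(80):  # bisection on the outermost edge
        mid = 0.5 * (lo + hi)
        if edges_for(mid)[-1] < max_dist:
            lo = mid
        else:
            hi = mid
    edges = edges_for(0.5 * (lo + hi))
    edges *= max_dist / edges[-1]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PolarGrid(
        n_radial=n_radial,
        n_angular=n_angular,
        max_dist=float(max_dist),
        radial_edges=edges,
        radial_centers=centers,
        sigma_ang=2.0 * np.pi / n_angular,
    )


def vector_field_response(
    grid: PolarGrid, points, weights=None, gain: float = 1.0
) -> np.ndarray:
    """Population response of a polar-grid population to a set of points.

    Each point is ``(distance, direction)``; each cell responds with the
    product of a unit-peak Gaussian in distance (width sigma_rad(d_i)) and
    a unit-peak wrapped Gaussian in direction (width sigma_ang), summed
    over points (optionally weighted, e.g. by subtended angle for boundary
    samples) and clipped to [0, 1].  A point exactly at a cell's tuning
    center contributes 1 to that cell, so the maximum single-point
    response is already 1 and no further normalization is needed.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        return np.zeros(grid.n_cells)
    if (pts[:, 0] < 0).any():
        raise ValueError("distances must be nonnegative")
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, dtype=float)

    d = pts[:, 0][:, None]  # (p, 1)
    a = pts[:, 1][:, None]
    dc = grid.radial_centers[None, :]  # (1, r)
    sr = sigma_rad(grid.radial_centers)[None, :]
    g_rad = np.exp(-0.5 * ((d - dc) / sr) ** 2)  # (p, r)
    da = wrap_angle(a - grid.angular_centers[None, :])  # (p, a)
    g_ang = np.exp(-0.5 * (da / grid.sigma_ang) ** 2)
    # response (r, a) = sum_p w_p g_rad[p, r] g_ang[p, a]
    resp = np.einsum("p,pr,pa->ra", w, g_rad, g_ang)
    return np.clip(gain * resp, 0.0, 1.0).reshape(-1)


# Gain applied to subtended-angle-weighted boundary samples so that a wall
# passing through a cell's tuning center drives it near (but below) peak
# rate: the integral of the angular Gaussian is sqrt(2*pi)*sigma_ang.
def boundary_gain(grid: PolarGrid) -> float:
    return 0.9 / (np.sqrt(2.0 * np.pi) * grid.sigma_ang)


# ---------------------------------------------------------------------------
# place cells


@dataclass(frozen=True)
class PlaceLayout:
    """Place-cell field centers on a regular lattice over the arena."""

    centers: np.ndarray  # (n, 2)
    sigma_pc: float
    spacing: float
    shape: tuple[int, int]

    @property
    def n_cells(self) -> int:
        return len(self.centers)


def make_place_layout(
    extent, n_side: int = 22, sigma_pc: float = 8.0
) -> PlaceLayout:
    xmin, ymin, xmax, ymax = extent
    sx = (xmax - xmin) / n_side
    sy = (ymax - ymin) / n_side
    xs = xmin + (np.arange(n_side) + 0.5) * sx
    ys = ymin + (np.arange(n_side) + 0.5) * sy
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    centers = np.stack([gx.ravel(), gy.ravel()], axis=1)
    spacing = float(max(sx, sy))
    if spacing >= 2.0 * sigma_pc:
        raise ValueError("lattice spacing must be < 2 * sigma_pc")
    return PlaceLayout(centers, float(sigma_pc), spacing, (n_side, n_side))


def place_field_pattern(layout: PlaceLayout, xy) -> np.ndarray:
    """Gaussian place-field activity pattern for a location (peak 1)."""
    d2 = ((layout.centers - np.asarray(xy, dtype=float)[None, :]) ** 2).sum(axis=1)
    return np.exp(-0.5 * d2 / layout.sigma_pc**2)


class PlaceCompetition:
    """Winner-reinforcing rate dynamics on the place-cell lattice.

    Local Gaussian excitation reinforces contiguous activity while an
    expansive (squaring) nonlinearity with divisive global inhibition
    normalizes total activity to a set point, so a single bump forms and
    tiny drive advantages are amplified geometrically (winner take all).
    Inhibition depends only on the instantaneous activity, so the bump
    re-anchors on the drive peak rather than on its own history.
    """

    #: target total activity of the settled bump
    SET_POINT = 3.0
    #: only cells within this fraction of the strongest input compete
    THRESHOLD = 0.30
    #: place dynamics time constant (faster than the identity populations,
    #: slower than the sensory relays)
    TAU_PC = 10.0

    def __init__(self, layout: PlaceLayout, tau: float | None = None):
        tau = self.TAU_PC if tau is None else tau
        self.layout = layout
        self.tau = tau
        d2 = (
            (layout.centers[:, None, :] - layout.centers[None, :, :]) ** 2
        ).sum(axis=2)
        k = np.exp(-0.5 * d2 / (1.0 * layout.sigma_pc) ** 2)
        np.fill_diagonal(k, 0.0)
        self.kernel = 0.08 * k

    def step(self, rates: np.ndarray, drive: np.ndarray, dt: float = 1.0):
        u = np.clip(drive + self.kernel @ rates, 0.0, None)
        m = u.max()
        if m <= 0.0:
            target = np.zeros_like(u)
        else:
            # only cells near the strongest total input compete; squaring
            # + shared divisive inhibition amplifies the winner
            v = np.clip(u - self.THRESHOLD * m, 0.0, None) ** 2
            target = np.clip(self.SET_POINT * v / (1e-12 + v.sum()), 0.0, 1.0)
        return rates + (dt / self.tau) * (target - rates)


def _bump_components(rates: np.ndarray, shape, threshold: float):
    """Connected components (4-connectivity on the lattice) of cells whose
    rate exceeds ``threshold``.  Returns a list of index arrays."""
    from scipy import ndimage

    mask = (rates >= threshold).reshape(shape)
    labels, n = ndimage.label(mask)
    labels = labels.reshape(-1)
    return [np.nonzero(labels == k)[0] for k in range(1, n + 1)]


def place_rates(
    layout: PlaceLayout,
    drive: np.ndarray,
    n_steps: int = 200,
    rates: np.ndarray | None = None,
    competition: PlaceCompetition | None = None,
) -> np.ndarray:
    """Settle the competitive place-cell dynamics under a fixed drive.

    If the settled activity still holds several disconnected bumps (the
    drive was degenerate, e.g. two equally strong distant inputs), the
    competition is resolved deterministically: the component whose peak
    cell has the lowest index wins and the others are silenced.
    """
    comp = competition or PlaceCompetition(layout)
    r = np.zeros(layout.n_cells) if rates is None else rates.copy()
    d = np.asarray(drive, dtype=float)
    if d.shape != (layout.n_cells,):
        raise ValueError("drive length must equal the number of place cells")
    for _ in range(n_steps):
        r = comp.step(r, d)
    r = np.clip(r, 0.0, 1.0)
    if r.max() <= 0:
        return r
    participation = r.sum() ** 2 / (r @ r)
    if participation > 0.1 * layout.n_cells:
        # degenerate near-uniform drive: no bump can self-organize, so a
        # deterministic seed (lowest index among maximal drives) is planted
        # and the competition resettled around it
        tie = 1e-9 * (layout.n_cells - np.arange(layout.n_cells))
        seed = int((d + tie).argmax())
        d = d.copy()
        d[seed] += max(d.max(), 0.1)
        r = np.zeros_like(r)
        for _ in range(n_steps):
            r = comp.step(r, d)
        r = np.clip(r, 0.0, 1.0)
    comps = _bump_components(r, layout.shape, 0.5 * r.max())
    if len(comps) > 1:
        # deterministic tie-break: strongest peak wins, ties to lowest index
        def key(c):
            peak = r[c].max()
            return (-round(float(peak), 6), int(c[r[c].argmax()]))

        winner = min(comps, key=key)
        mask = np.zeros_like(r)
        mask[winner] = 1.0
        r = r * mask
        # brief resettling confined to the winner keeps the bump shape
        for _ in range(30):
            r = np.clip(comp.step(r, d * mask), 0.0, 1.0)
    return r


def decode_position(rates: np.ndarray, layout: PlaceLayout) -> np.ndarray:
    """Rate-weighted centroid of place-field centers."""
    s = float(rates.sum())
    if s <= 0:
        raise ValueError("cannot decode position from all-zero rates")
    return (rates[:, None] * layout.centers).sum(axis=0) / s


# ---------------------------------------------------------------------------
# head direction ring attractor


N_HD = 100
_HD_EXC_HALFWIDTH = np.deg2rad(30.0)
_HD_J_EXC = 0.18
_HD_INH = 0.30
_HD_TAU = 4.0


@dataclass
class HDRing:
    """100-cell head-direction ring attractor.

    Preferred directions are evenly spaced on [0, 2pi).  A cosine-lobed
    local-excitation kernel (half-width 30 degrees) plus uniform
    inhibition sustains a single bump; angular velocity shifts the bump by
    rotating the rate vector (the asymmetric-weight mechanism expressed in
    its equivalent rotated-frame form) followed by one relaxation step.
    """

    rates: np.ndarray = field(default_factory=lambda: np.zeros(N_HD))
    set_point: float = 0.0

    @property
    def preferred(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(N_HD) / N_HD

    def copy(self) -> "HDRing":
        return HDRing(self.rates.copy(), self.set_point)


def _hd_kernel() -> np.ndarray:
    delta = wrap_angle(2.0 * np.pi * np.arange(N_HD) / N_HD)
    k = np.where(
        np.abs(delta) < _HD_EXC_HALFWIDTH,
        np.cos(np.pi * delta / (2.0 * _HD_EXC_HALFWIDTH)),
        0.0,
    )
    return _HD_J_EXC * k


_KERNEL_FFT = None


def _hd_convolve(r: np.ndarray) -> np.ndarray:
    global _KERNEL_FFT
    if _KERNEL_FFT is None:
        _KERNEL_FFT = np.fft.rfft(_hd_kernel())
    return np.fft.irfft(np.fft.rfft(r) * _KERNEL_FFT, n=N_HD)


def _hd_relax(r: np.ndarray, external: np.ndarray | None = None, dt: float = 1.0):
    u = _hd_convolve(r) - _HD_INH * r.mean() * N_HD / 10.0
    if external is not None:
        u = u + external
    target = np.clip(u, 0.0, 1.0)
    return np.clip(r + (dt / _HD_TAU) * (target - r), 0.0, 1.0)


def fractional_roll(r: np.ndarray, shift_bins: float) -> np.ndarray:
    """Circularly shift a vector by a fractional number of bins
    (linear interpolation between the two flanking integer shifts)."""
    f = int(np.floor(shift_bins))
    w = shift_bins - f
    return (1.0 - w) * np.roll(r, f) + w * np.roll(r, f + 1)


def hd_init(heading: float = 0.0, settle: int = 300) -> HDRing:
    """Create a ring with a settled bump at ``heading``."""
    ring = HDRing()
    pref = ring.preferred
    ring.rates = np.exp(-0.5 * (wrap_angle(pref - heading) / np.deg2rad(15)) ** 2)
    for _ in range(settle):
        ring.rates = _hd_relax(ring.rates)
    ring.set_point = float(ring.rates.sum())
    return ring


def hd_step(
    ring: HDRing,
    angular_velocity: float,
    dt: float = 1.0,
    external: np.ndarray | None = None,
) -> HDRing:
    """Advance the ring one step under angular velocity (rad/step)."""
    shift = angular_velocity * dt * N_HD / (2.0 * np.pi)
    r = fractional_roll(ring.rates, shift)
    r = _hd_relax(r, external=external, dt=dt)
    return HDRing(r, ring.set_point)


def decode_hd(ring_or_rates) -> float:
    """Circular population-vector mean of the ring rates, in [0, 2pi)."""
    r = ring_or_rates.rates if isinstance(ring_or_rates, HDRing) else ring_or_rates
    r = np.asarray(r, dtype=float)
    if r.sum() <= 0:
        raise ValueError("cannot decode heading from all-zero rates")
    pref = 2.0 * np.pi * np.arange(len(r)) / len(r)
    c = (r * np.cos(pref)).sum()
    s = (r * np.sin(pref)).sum()
    return float(np.arctan2(s, c) % (2.0 * np.pi))
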