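"""The head-direction-gated egocentric/allocentric transformation circuit.

Twenty sublayers, each a copy of the shared polar-grid population tuned to
one of 20 evenly spaced head directions, map parietal-window patterns to
allocentric (BVC/OVC) patterns and back.  Sublayer k implements a pure
rotation of the polar pattern by its preferred direction theta_k (bilinear
interpolation across angular bins; radial bins unchanged), and the head
direction bump selects sublayers through normalized wrapped-Gaussian
gains, so the net mapping rotates the egocentric pattern by the current
heading: a parietal cell tuned "ahead" drives the BVC tuned to West when
the agent faces West.

The reverse mapping is the exact adjoint (rotation by -theta_k with the
same gains).  Mode gains implement the neuromodulatory bottom-up/top-down
switch: the suppressed direction runs at 5% of maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import wrap_angle
from .populations import HDRing, PolarGrid, decode_hd

SUPPRESSED_GAIN = 0.05


@dataclass(frozen=True)
class GainMode:
    """Direction-dependent connection gains for one processing mode."""

    mode: str  # "bottom_up" | "top_down"
    ego_gain: float
    allo_gain: float


BOTTOM_UP = GainMode("bottom_up", 1.0, SUPPRESSED_GAIN)
TOP_DOWN = GainMode("top_down", SUPPRESSED_GAIN, 1.0)


@dataclass(frozen=True)
class TransformationWeights:
    """Sublayer geometry of the transformation circuit."""

    grid: PolarGrid
    n_sublayers: int
    preferred: np.ndarray  # (n_sublayers,) theta_k
    hd_tuning_width: float  # rad

    def rotate(self, pattern: np.ndarray, theta: float) -> np.ndarray:
        """Rotate a polar-grid pattern counterclockwise by theta.

        Bilinear interpolation over angular bins; radial bins unchanged.
        The rotation operator for -theta is the exact transpose of the
        operator for +theta.
        """
        g = self.grid
        p = np.asarray(pattern, dtype=float).reshape(g.n_radial, g.n_angular)
        shift = theta * g.n_angular / (2.0 * np.pi)
        f = int(np.floor(shift))
        w = shift - f
        out = (1.0 - w) * np.roll(p, f, axis=1) + w * np.roll(p, f + 1, axis=1)
        return out.reshape(-1)


def build_transformation(
    grid: PolarGrid, n_sublayers: int = 20, hd_tuning_width: float = np.deg2rad(18.0)
) -> TransformationWeights:
    """Construct the transformation circuit analytically."""
    if n_sublayers < 4:
        raise ValueError("need at least 4 sublayers")
    preferred = 2.0 * np.pi * np.arange(n_sublayers) / n_sublayers
    return TransformationWeights(grid, int(n_sublayers), preferred, hd_tuning_width)


GAIN_SHARPNESS = 12.0


def hd_gain(
    hd_rates, weights: TransformationWeights, sharpness: float = GAIN_SHARPNESS
) -> np.ndarray:
    """Per-sublayer gains from the head-direction bump.

    Each sublayer's raw drive is the wrapped-Gaussian overlap (width 18
    degrees, one sublayer spacing) between the bump and the sublayer's
    preferred direction; mutual inhibition between sublayers — only the
    maximally modulated sublayers escape suppression — is modeled as a
    power nonlinearity on the overlaps before normalizing the gains to sum
    to 1.  All-zero head-direction input raises ``ValueError`` (the
    head-direction lesion condition: the circuit receives no modulation).
    """
    r = hd_rates.rates if isinstance(hd_rates, HDRing) else np.asarray(hd_rates)
    if r.sum() <= 0:
        raise ValueError("head-direction input to the transformation circuit is zero")
    n = len(r)
    pref_hd = 2.0 * np.pi * np.arange(n) / n
    d = wrap_angle(pref_hd[None, :] - weights.preferred[:, None])
    overlap = np.exp(-0.5 * (d / weights.hd_tuning_width) ** 2) @ r
    overlap = (overlap / overlap.max()) ** sharpness
    return overlap / overlap.sum()


def _apply(
    pattern: np.ndarray,
    hd,
    weights: TransformationWeights,
    sign: float,
    gains: np.ndarray | None,
) -> np.ndarray:
    """Gain-weighted sum of sublayer rotations.

    Computed in the angular Fourier domain: every sublayer rotation is a
    circulant (linear-interpolation roll), so the mixture is one combined
    circulant applied per radial ring.
    """
    if gains is None:
        gains = hd_gain(hd, weights)
    g = weights.grid
    p = np.asarray(pattern, dtype=float).reshape(g.n_radial, g.n_angular)
    n = g.n_angular
    m = np.arange(n // 2 + 1)
    shifts = sign * weights.preferred * n / (2.0 * np.pi)
    f = np.floor(shifts)
    w = shifts - f
    # FFT of the interpolating roll kernels, gain-weighted
    phase = np.exp(-2j * np.pi * m[None, :] * f[:, None] / n)
    khat = (gains[:, None] * phase
            * ((1.0 - w[:, None]) + w[:, None]
               * np.exp(-2j * np.pi * m[None, :] / n))).sum(axis=0)
    out = np.fft.irfft(np.fft.rfft(p, axis=1) * khat[None, :], n=n, axis=1)
    return out.reshape(-1)


def ego_to_allo(
    pw: np.ndarray,
    hd,
    weights: TransformationWeights,
    mode: GainMode = BOTTOM_UP,
    gains: np.ndarray | None = None,
) -> np.ndarray:
    """Map an egocentric parietal pattern to the allocentric drive.

    Output = ego_gain * sum_k gain_k * rotate(pw, +theta_k); at full
    strength (bottom-up) this is the BVC/OVC drive.
    """
    return mode.ego_gain * _apply(pw, hd, weights, +1.0, gains)


def allo_to_ego(
    allo: np.ndarray,
    hd,
    weights: TransformationWeights,
    mode: GainMode = TOP_DOWN,
    gains: np.ndarray | None = None,
) -> np.ndarray:
    """Map an allocentric (BVC/OVC) pattern to the parietal drive.

    Output = allo_gain * sum_k gain_k * rotate(allo, -theta_k); full
    strength only in top-down (imagery) mode.  With gains fixed this is
    the exact adjoint of :func:`ego_to_allo`.
    """
    return mode.allo_gain * _apply(allo, hd, weights, -1.0, gains)
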