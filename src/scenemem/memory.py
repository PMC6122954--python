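"""The medial-temporal attractor and Hebbian object memory.

Three populations represent spatial context: place cells (PC), boundary
vector cells (BVC) and perirhinal boundary-identity neurons (PRb).  Their
mutual connections are learned in a training phase that visits every
place-field center once and associates the full-surround (360 degree)
boundary-vector pattern and the visible boundary identities with that
location, making each (PC, BVC, PRb) tuple an attractor fixed point.

Objects are encoded on the fly: at an encoding event the object-identity
neuron (PRo) is associated with the active place cells, the object vector
cells (OVC) and the current head direction, and the OVCs are associated
with place cells and the PRo neuron — the four learned weight blocks that
anchor an object to its spatial context.  Cueing a PRo neuron later
drives pattern completion, which reconstructs the full multi-population
state from the partial cue.

Recall drives use presynaptic divisive normalization (drives are
similarity scores of the current pattern against the stored patterns), a
standard stabilization of outer-product Hebbian memories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Environment, surround_boundary_points
from .populations import (
    N_HD,
    PlaceCompetition,
    PlaceLayout,
    PolarGrid,
    TAU,
    TAU_RELAY,
    boundary_gain,
    place_rates,
    vector_field_response,
)

_EPS = 1e-9

# firing threshold of the vector-cell relays: the 5% suppressed-direction
# bleed during perception sits exactly at threshold and does not elicit
# firing, while weakly driven (unattended) perceptual input passes
THETA_FIRE = 0.05


@dataclass
class MTLState:
    """Firing rates of the five medial-temporal populations."""

    pc: np.ndarray
    bvc: np.ndarray
    ovc: np.ndarray
    prb: np.ndarray
    pro: np.ndarray

    def copy(self) -> "MTLState":
        return MTLState(*(v.copy() for v in (self.pc, self.bvc, self.ovc, self.prb, self.pro)))

    @staticmethod
    def zeros(n_pc, n_polar, n_prb, n_pro) -> "MTLState":
        return MTLState(
            np.zeros(n_pc), np.zeros(n_polar), np.zeros(n_polar),
            np.zeros(n_prb), np.zeros(n_pro),
        )

    def populations(self) -> dict:
        return {"PC": self.pc, "BVC": self.bvc, "OVC": self.ovc,
                "PRb": self.prb, "PRo": self.pro}


@dataclass
class EncodingEvent:
    """Snapshot taken at the moment an object is encoded."""

    t: int
    object_id: str
    state: MTLState
    hd_rates: np.ndarray
    heading: float
    position: np.ndarray
    pw_b: np.ndarray | None = None
    pw_o: np.ndarray | None = None


@dataclass
class MTLWeights:
    """Trained context plus learned object associations.

    The trained context is held as the stored pattern matrices (one row
    per place-cell lattice location); the learned object blocks are plain
    weight matrices grown by :func:`hebbian_update` at encoding events.
    """

    layout: PlaceLayout
    grid: PolarGrid
    boundary_ids: list[str]
    object_ids: list[str]
    stored_bvc: np.ndarray  # (n_pc, n_polar) trained BVC pattern per location
    stored_prb: np.ndarray  # (n_pc, n_prb)
    bvc_unit: np.ndarray = field(default=None, repr=False)  # L2-normalized rows
    # learned blocks (zero before any encoding)
    W_pc_ovc: np.ndarray = None  # (n_pc, n_polar): OVC -> PC
    W_ovc_pc: np.ndarray = None  # (n_polar, n_pc): PC -> OVC
    W_pc_pro: np.ndarray = None  # (n_pc, n_pro): PRo -> PC
    W_pro_pc: np.ndarray = None  # (n_pro, n_pc): PC -> PRo
    W_ovc_pro: np.ndarray = None  # (n_polar, n_pro): PRo -> OVC
    W_pro_ovc: np.ndarray = None  # (n_pro, n_polar): OVC -> PRo
    W_hd_pro: np.ndarray = None  # (n_hd, n_pro): PRo -> HD reinstatement
    events: dict = field(default_factory=dict)  # object_id -> EncodingEvent

    def __post_init__(self):
        n_pc = self.layout.n_cells
        n_pol = self.grid.n_cells
        n_pro = len(self.object_ids)
        if self.bvc_unit is None:
            norms = np.linalg.norm(self.stored_bvc, axis=1, keepdims=True)
            self.bvc_unit = self.stored_bvc / np.maximum(norms, _EPS)
        shapes = {
            "W_pc_ovc": (n_pc, n_pol), "W_ovc_pc": (n_pol, n_pc),
            "W_pc_pro": (n_pc, n_pro), "W_pro_pc": (n_pro, n_pc),
            "W_ovc_pro": (n_pol, n_pro), "W_pro_ovc": (n_pro, n_pol),
            "W_hd_pro": (N_HD, n_pro),
        }
        for name, shape in shapes.items():
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(shape))

    @property
    def n_pro(self) -> int:
        return len(self.object_ids)

    @property
    def n_prb(self) -> int:
        return len(self.boundary_ids)

    def learned_blocks(self) -> dict:
        return {k: getattr(self, k) for k in
                ("W_pc_ovc", "W_ovc_pc", "W_pc_pro", "W_pro_pc",
                 "W_ovc_pro", "W_pro_ovc", "W_hd_pro")}

    def copy(self) -> "MTLWeights":
        w = MTLWeights(
            self.layout, self.grid, list(self.boundary_ids), list(self.object_ids),
            self.stored_bvc, self.stored_prb, self.bvc_unit,
            **{k: v.copy() for k, v in self.learned_blocks().items()},
        )
        w.events = dict(self.events)
        return w

    # -- drive helpers (presynaptic divisive normalization) -----------------

    # Exponent sharpening the location matched filter: stored patterns at
    # neighbouring lattice sites are highly similar (cosine ~0.95+), so the
    # raw similarity profile is nearly flat and the place bump would wander;
    # an expansive nonlinearity anchors it on the best-matching location.
    MATCH_SHARPNESS = 16.0

    def pc_drive_from_bvc(self, r_bvc: np.ndarray) -> np.ndarray:
        """Drive of the BVC pattern against each stored location pattern.

        Sharpened cosine matched filter with soft output normalization:
        a frontal-field-of-view scene matches its own stored full-surround
        pattern at cosine ~0.75 while a full-surround cue matches at ~1,
        and both should drive the winning place cell near saturation; an
        unstructured input (best cosine well below 0.5) stays suppressed.
        """
        n = np.linalg.norm(r_bvc)
        if n < _EPS:
            return np.zeros(self.layout.n_cells)
        sim = np.clip(self.bvc_unit @ (r_bvc / n), 0.0, None)
        v = sim**self.MATCH_SHARPNESS
        return v / (v.max() + 0.5**self.MATCH_SHARPNESS)

    def pc_drive_from_prb(self, r_prb: np.ndarray) -> np.ndarray:
        s = r_prb.sum()
        if s < _EPS:
            return np.zeros(self.layout.n_cells)
        d = self.stored_prb @ r_prb / s
        m = d.max()
        return d / m if m > _EPS else d

    def bvc_drive_from_pc(self, r_pc: np.ndarray) -> np.ndarray:
        # expansive weighting: the reconstruction is dominated by the bump
        # center rather than blurred across its flanks
        w = (r_pc * r_pc) ** 2
        s = w.sum()
        if s < _EPS:
            return np.zeros(self.grid.n_cells)
        return self.stored_bvc.T @ w / s

    def prb_drive_from_pc(self, r_pc: np.ndarray) -> np.ndarray:
        s = r_pc.sum()
        if s < _EPS:
            return np.zeros(self.n_prb)
        return self.stored_prb.T @ r_pc / s

    @staticmethod
    def _assoc(W: np.ndarray, r_pre: np.ndarray, energy: bool = True) -> np.ndarray:
        # divisive presynaptic normalization with a floor: weak input
        # patterns are not amplified back to full strength (loop gains
        # through reciprocal learned blocks stay below one)
        if not W.any():
            return np.zeros(W.shape[0])
        if energy:
            denom = max(float(r_pre @ r_pre), 1.0)
        else:
            denom = max(float(r_pre.sum()), 1.0)
        if denom < _EPS:
            return np.zeros(W.shape[0])
        return W @ r_pre / denom

    @staticmethod
    def _project(W: np.ndarray, r_pre: np.ndarray) -> np.ndarray:
        """Per-row projection coefficient: response scales linearly with
        how much of each row's stored pattern is present in the input."""
        energy = np.einsum("ij,ij->i", W, W)
        return W @ r_pre / np.maximum(energy, _EPS)

    def ovc_drive(self, r_pc: np.ndarray, r_pro: np.ndarray) -> np.ndarray:
        # sub-saturating gains: with several objects bound to one place
        # pattern, the identity-specific (PRo) component must dominate the
        # place-driven component so the cued object stands out while the
        # other objects remain as residual peaks
        return 0.5 * self._assoc(self.W_ovc_pc, r_pc) + 0.5 * self._assoc(
            self.W_ovc_pro, r_pro, energy=False
        )

    def pc_drive_learned(self, r_ovc: np.ndarray, r_pro: np.ndarray) -> np.ndarray:
        return self._assoc(self.W_pc_ovc, r_ovc) + self._assoc(
            self.W_pc_pro, r_pro, energy=False
        )

    def pro_drive(self, r_pc: np.ndarray, r_ovc: np.ndarray) -> np.ndarray:
        return np.clip(
            self._project(self.W_pro_pc, r_pc)
            + self._project(self.W_pro_ovc, r_ovc),
            0.0, None,
        )

    def hd_drive_from_pro(self, r_pro: np.ndarray) -> np.ndarray:
        s = r_pro.sum()
        if s < _EPS:
            return np.zeros(N_HD)
        return self.W_hd_pro @ r_pro / s


def train_context(
    env: Environment,
    layout: PlaceLayout,
    grid: PolarGrid,
    sample_spacing: float = 2.5,
) -> MTLWeights:
    """Learn the spatial-context attractor for a familiar environment.

    Visits every place-field center once and associates the full-surround
    boundary-vector pattern and visible boundary identities with that
    location (equivalent end state to prolonged exploration from all
    orientations).  Locations outside the arena (e.g. inside a blocked
    region) get zero stored patterns and never win the competition.
    """
    n_pc = layout.n_cells
    boundary_ids = [b.identity for b in env.boundaries]
    object_ids = [o.identity for o in env.objects]
    stored_bvc = np.zeros((n_pc, grid.n_cells))
    stored_prb = np.zeros((n_pc, len(boundary_ids)))
    gain = boundary_gain(grid)
    for p, xy in enumerate(layout.centers):
        if not env.contains(xy):
            continue
        d, a, ids, w = surround_boundary_points(env, xy, sample_spacing)
        stored_bvc[p] = vector_field_response(
            grid, np.stack([d, a], axis=1), weights=w, gain=gain
        )
        for bid in set(ids):
            stored_prb[p, boundary_ids.index(bid)] = 1.0
    return MTLWeights(layout, grid, boundary_ids, object_ids, stored_bvc, stored_prb)


def hebbian_update(
    pre: np.ndarray, post: np.ndarray, W: np.ndarray, rate: float = 1.0
) -> np.ndarray:
    """One-shot Hebbian association: W + rate * outer(post, pre), with the
    outer product normalized to unit maximum.  Zero-norm inputs are a
    no-op."""
    outer = np.outer(post, pre)
    m = outer.max()
    if m <= _EPS:
        return W.copy()
    return W + rate * outer / m


class BindingAmbiguityError(RuntimeError):
    """More than one object concurrently attended at encoding."""


def encode_object_event(
    state: MTLState,
    hd_rates: np.ndarray,
    weights: MTLWeights,
    t: int = 0,
    position=None,
    heading: float = 0.0,
    pw_b=None,
    pw_o=None,
) -> EncodingEvent | None:
    """Hebbian one-shot encoding of the currently attended object.

    Requires exactly one dominant PRo winner co-active with one attended
    OVC cluster; updates the four learned blocks (PC<->OVC, PC<->PRo,
    OVC<->PRo, PRo->HD) in place and records the event.  Returns None
    (weights untouched) if the winner was already encoded.
    """
    pro = state.pro
    order = np.argsort(pro)[::-1]
    if pro[order[0]] <= 0.1:
        raise ValueError("no active PRo neuron at encoding")
    if len(pro) > 1 and pro[order[1]] > 0.5 * pro[order[0]]:
        raise BindingAmbiguityError(
            "two objects concurrently attended; object-location binding ambiguous"
        )
    if state.ovc.max() <= 0.05:
        raise ValueError("no attended OVC cluster at encoding")
    obj = weights.object_ids[int(order[0])]
    if obj in weights.events:
        return None  # one-shot: no further learning for this object
    pro_onehot = np.zeros_like(pro)
    pro_onehot[order[0]] = 1.0
    weights.W_pc_ovc = hebbian_update(state.ovc, state.pc, weights.W_pc_ovc)
    weights.W_ovc_pc = hebbian_update(state.pc, state.ovc, weights.W_ovc_pc)
    weights.W_pc_pro = hebbian_update(pro_onehot, state.pc, weights.W_pc_pro)
    weights.W_pro_pc = hebbian_update(state.pc, pro_onehot, weights.W_pro_pc)
    weights.W_ovc_pro = hebbian_update(pro_onehot, state.ovc, weights.W_ovc_pro)
    weights.W_pro_ovc = hebbian_update(state.ovc, pro_onehot, weights.W_pro_ovc)
    weights.W_hd_pro = hebbian_update(pro_onehot, hd_rates, weights.W_hd_pro)
    ev = EncodingEvent(
        t, obj, state.copy(), np.asarray(hd_rates).copy(), heading,
        None if position is None else np.asarray(position, dtype=float).copy(),
        None if pw_b is None else np.asarray(pw_b).copy(),
        None if pw_o is None else np.asarray(pw_o).copy(),
    )
    weights.events[obj] = ev
    return ev


# gains of the inter-population drives inside the MTL attractor
G_BVC_TO_PC = 1.0
G_PRB_TO_PC = 0.15
G_PC_TO_BVC = 1.0
G_PRO_WTA = 1.0
# learned object->place recall drive dominates the location competition so
# the recalled bump reproduces the encoding bump rather than a compromise
# with the (re-)constructed boundary evidence
G_LEARNED_TO_PC = 1.0


def mtl_step(
    state: MTLState,
    weights: MTLWeights,
    ego_drive_bvc: np.ndarray | None = None,
    ego_drive_ovc: np.ndarray | None = None,
    prb_input: np.ndarray | None = None,
    pro_input: np.ndarray | None = None,
    bottom_up_gain: float = 1.0,
    top_down_gain: float = 0.05,
    gc_drive: np.ndarray | None = None,
    gc_gain: float = 0.0,
    competition: PlaceCompetition | None = None,
    pc_lesion: bool = False,
    dt: float = 1.0,
) -> MTLState:
    """One leaky-integrator step of the full MTL network.

    ``ego_drive_bvc``/``ego_drive_ovc`` are the (already mode-gated)
    transformation-circuit outputs; ``bottom_up_gain``/``top_down_gain``
    gate the perceptual vs memory-driven directions inside the MTL.
    """
    comp = competition or PlaceCompetition(weights.layout)
    s = state
    new = s.copy()

    # place cells: perceptual matched filter + learned recall + grid input
    if pc_lesion:
        new.pc = np.zeros_like(s.pc)
    else:
        # the learned object->place drive is kept below the grid-cell
        # drive so that during imagined movement the moving grid input,
        # not a reactivated object memory, steers the bump
        pc_drive = (
            bottom_up_gain * G_BVC_TO_PC * weights.pc_drive_from_bvc(s.bvc)
            + bottom_up_gain * G_PRB_TO_PC * weights.pc_drive_from_prb(s.prb)
            + 0.4 * top_down_gain * weights.pc_drive_learned(s.ovc, s.pro)
        )
        if gc_drive is not None and gc_gain > 0:
            pc_drive = pc_drive + gc_gain * gc_drive
        new.pc = np.clip(comp.step(s.pc, pc_drive, dt), 0.0, 1.0)

    # boundary vector cells: transformation drive + memory completion
    bvc_drive = top_down_gain * G_PC_TO_BVC * weights.bvc_drive_from_pc(s.pc)
    if ego_drive_bvc is not None:
        bvc_drive = bvc_drive + ego_drive_bvc
    bvc_target = np.clip((bvc_drive - THETA_FIRE) / (1.0 - THETA_FIRE), 0, 1)
    new.bvc = np.clip(s.bvc + (dt / TAU_RELAY) * (bvc_target - s.bvc), 0, 1)

    # object vector cells
    ovc_drive = top_down_gain * weights.ovc_drive(s.pc, s.pro)
    if ego_drive_ovc is not None:
        ovc_drive = ovc_drive + ego_drive_ovc
    ovc_target = np.clip((ovc_drive - THETA_FIRE) / (1.0 - THETA_FIRE), 0, 1)
    new.ovc = np.clip(s.ovc + (dt / TAU_RELAY) * (ovc_target - s.ovc), 0, 1)

    # perirhinal boundary identity: external recognition + completion
    prb_drive = top_down_gain * weights.prb_drive_from_pc(s.pc)
    if prb_input is not None:
        prb_drive = prb_drive + prb_input
    new.prb = np.clip(s.prb + (dt / TAU) * (np.clip(prb_drive, 0, 1) - s.prb), 0, 1)

    # perirhinal object identity: recognition/cue + learned drive + WTA
    pro_drive = top_down_gain * weights.pro_drive(s.pc, s.ovc)
    if pro_input is not None:
        pro_drive = pro_drive + pro_input
    if len(s.pro):
        inh = G_PRO_WTA * (s.pro.sum() - s.pro)  # mutual inhibition
        pro_drive = pro_drive - inh
    new.pro = np.clip(s.pro + (dt / TAU) * (np.clip(pro_drive, 0, 1) - s.pro), 0, 1)
    return new


def pattern_complete(
    cue: MTLState,
    weights: MTLWeights,
    n_steps: int = 500,
    tol: float = 1e-4,
    competition: PlaceCompetition | None = None,
    pro_input: np.ndarray | None = None,
    top_down_gain: float = 1.0,
    gc_drive=None,
    gc_gain: float = 0.0,
    pc_lesion: bool = False,
):
    """Complete a partial cue into a stored multi-population state.

    The place-cell population acts as the index of the memory: every
    outer iteration gathers the evidence for each location (match of the
    current BVC pattern against the stored patterns, boundary-identity
    input, learned object/identity drives, optional grid-cell drive),
    settles the competitive place dynamics on it, and re-projects the
    winning location back onto the BVC/OVC/perirhinal populations.  The
    iteration stops when the state changes by less than ``tol`` per cell
    or the step budget ``n_steps`` (total inner relaxation steps) is
    exhausted.  Returns ``(settled_state, converged_flag)``.
    """
    comp = competition or PlaceCompetition(weights.layout)
    s = cue.copy()
    inner = 150
    n_outer = max(1, int(n_steps) // inner)
    converged = False
    for _ in range(n_outer):
        pc_drive = (
            G_BVC_TO_PC * weights.pc_drive_from_bvc(s.bvc)
            + G_PRB_TO_PC * weights.pc_drive_from_prb(s.prb)
            + top_down_gain * G_LEARNED_TO_PC
            * weights.pc_drive_learned(s.ovc, s.pro)
        )
        if gc_drive is not None and gc_gain > 0:
            pc_drive = pc_drive + gc_gain * np.asarray(gc_drive)
        if pc_lesion:
            pc = np.zeros_like(s.pc)
        else:
            # the cue's own place activity seeds the competition as the
            # initial condition; location evidence anchors the winner
            pc = place_rates(
                weights.layout, pc_drive, n_steps=inner,
                rates=s.pc, competition=comp,
            )

        pro_drive = top_down_gain * weights.pro_drive(pc, s.ovc)
        if pro_input is not None:
            pro_drive = pro_drive + pro_input
        pro = _settle_pro(s.pro, pro_drive)

        bvc = np.clip(
            (top_down_gain * G_PC_TO_BVC * weights.bvc_drive_from_pc(pc)
             + (1.0 - top_down_gain) * cue.bvc - THETA_FIRE)
            / (1.0 - THETA_FIRE),
            0.0, 1.0,
        )
        ovc = np.clip(
            (top_down_gain * weights.ovc_drive(pc, pro) - THETA_FIRE)
            / (1.0 - THETA_FIRE),
            0.0, 1.0,
        )
        prb = np.clip(top_down_gain * weights.prb_drive_from_pc(pc), 0.0, 1.0)

        new = MTLState(pc, bvc, ovc, prb, pro)
        delta = max(
            np.abs(new.pc - s.pc).max(initial=0.0),
            np.abs(new.bvc - s.bvc).max(initial=0.0),
            np.abs(new.ovc - s.ovc).max(initial=0.0),
            np.abs(new.pro - s.pro).max(initial=0.0),
        )
        s = new
        if delta < tol:
            converged = True
            break
    return s, converged


def _settle_pro(pro0: np.ndarray, drive: np.ndarray, n_steps: int = 80):
    """Relax the object-identity population under winner-take-all mutual
    inhibition (the previously active winner is suppressed by the new)."""
    r = pro0.copy()
    for _ in range(n_steps):
        inh = G_PRO_WTA * (r.sum() - r)
        target = np.clip(drive - inh, 0.0, 1.0)
        r = r + (1.0 / TAU) * (target - r)
    return np.clip(r, 0.0, 1.0)


# ---------------------------------------------------------------------------
# persistence


def save_weights(weights: MTLWeights, path) -> None:
    """Serialize trained + learned weights to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["boundary_ids"] = [s.encode() for s in weights.boundary_ids]
        f.attrs["object_ids"] = [s.encode() for s in weights.object_ids]
        f.attrs["sigma_pc"] = weights.layout.sigma_pc
        f.attrs["layout_shape"] = weights.layout.shape
        f.attrs["grid_shape"] = (weights.grid.n_radial, weights.grid.n_angular)
        f.attrs["grid_max_dist"] = weights.grid.max_dist
        f.create_dataset("layout_centers", data=weights.layout.centers)
        f.create_dataset("stored_bvc", data=weights.stored_bvc)
        f.create_dataset("stored_prb", data=weights.stored_prb)
        for name, W in weights.learned_blocks().items():
            f.create_dataset(name, data=W)


def load_weights(path, layout: PlaceLayout, grid: PolarGrid) -> MTLWeights:
    import h5py

    with h5py.File(path, "r") as f:
        if tuple(f.attrs["grid_shape"]) != (grid.n_radial, grid.n_angular):
            raise ValueError("weight file was built for a different polar grid")
        w = MTLWeights(
            layout, grid,
            [s.decode() if isinstance(s, bytes) else s for s in f.attrs["boundary_ids"]],
            [s.decode() if isinstance(s, bytes) else s for s in f.attrs["object_ids"]],
            f["stored_bvc"][...], f["stored_prb"][...],
        )
        for name in w.learned_blocks():
            setattr(w, name, f[name][...])
    return w
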