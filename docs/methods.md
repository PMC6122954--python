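# Methods

This note documents the model equations, the parameters that matter,
the numerical choices, and what the simulated protocols do and do not
show. Units: distances in cm, angles in radians (counterclockwise from
+x = East; "facing North" is π/2; egocentric bearing 0 is straight
ahead, positive bearings to the agent's left), rates dimensionless in
[0, 1], time in integration steps.

## Environments and sensing

An environment is a set of labeled boundary polylines plus labeled
point objects inside a closed arena (validated by polygonizing the
boundary segments; shapely). The default arena is 100 × 100 cm. The
agent is a point with a heading; boundary polylines are sampled every
2.5 cm and a sample is visible iff its bearing lies within the frontal
180° field of view and no other segment intersects the line of sight
strictly before it. Each visible sample carries a weight equal to the
angle it subtends (spacing × sin(grazing angle) / distance, capped),
so near boundary sections dominate the drive, as in standard
boundary-vector models. Trajectories are piecewise-linear waypoint
paths walked at constant speed (default 0.15 cm/step) with turns in
place at 3°/step (1.5°/step for long foraging surveys, to limit
cumulative ring drift).

## Receptive fields

PWb/PWo/BVC/OVC share one polar grid: 16 radial × 51 angular bins out
to 160 cm. Radial bin widths are proportional to the radial tuning
width σ_rad(d) = 0.08 d + 3 cm (solved so the bins tile [0, 160]),
giving the characteristic teardrop fields; the angular width is one
angular bin (2π/51). A cell's response to a set of points is the
weighted sum over points of unit-peak Gaussian (radial) × wrapped
Gaussian (angular) factors, clipped to [0, 1]; because tuning curves
are unit-peak, a single point at a cell's center gives exactly rate 1.
Boundary input uses the subtended-angle weights and a gain of
0.9/(√(2π) σ_ang) so a wall through a cell's center drives it near
(but below) saturation — this keeps wall responses graded rather than
uniformly clipped.

## Head-direction ring

100 cells, preferred directions evenly spaced. A cosine-lobed local
excitation kernel (half-width 30°, gain 0.18) with uniform inhibition
(0.30) sustains a single bump (relaxation time constant 4 steps).
Angular velocity is applied by rotating the rate vector by ω·dt with
fractional-bin linear interpolation, followed by one relaxation step —
the rotated-frame form of an asymmetric-weight velocity drive. The
excitation gain was chosen to keep the bump just at saturation while
minimizing discretization pinning: residual drift is ≈ 0.3° per 300
stationary steps and full-turn integration errors stay below 2° for
constant ω between 0.5 and 3°/step. Cueing (recall) injects an
external current bump (amplitude 2 × the stored association) and the
ring re-pins within ≈ 400 steps. When a scripted protocol relocates
the agent between phases, the ring is re-pinned to the new trajectory's
initial heading (the agent is assumed oriented at trajectory onset;
there is no visual-resetting mechanism in the model).

## Transformation circuit

20 sublayers at 18° spacing; sublayer k rotates the polar pattern by
θ_k using linear interpolation across angular bins (radial bins
untouched), so rotation by −θ is the exact matrix transpose of
rotation by +θ. Sublayer gains are wrapped-Gaussian overlaps (width
18°) between the HD bump and θ_k, passed through a power nonlinearity
(exponent 12, modeling mutual inhibition between sublayers that lets
only the maximally modulated sublayers escape suppression) and
normalized to sum to 1. The gain-weighted sum of rotations is
evaluated in the angular Fourier domain (every interpolating roll is a
circulant), which is numerically identical to the direct sum. The
bottom-up/top-down switch multiplies whole directions by 1.0 or 0.05;
it is instantaneous and global.

On realistic boundary scenes the circuit is rotation-equivariant to
cosine ≥ 0.98 and a full ego→allo→ego round trip at matched gains
correlates ≥ 0.95 with the input; the sublayer mixing blurs patterns
(peaks never shift by more than one angular bin), which is why
reconstructed parietal patterns correlate ≈ 0.65–0.95 with their
perceptual originals rather than 1.0.

## Medial-temporal attractor

Training visits every place-cell lattice point once (22 × 22 lattice,
field width σ_pc = 8 cm) and stores the full-surround (360°) boundary
pattern and the visible boundary identities for that location —
equivalent in end state to prolonged exploration from all
orientations. Recall drives are similarity computations against the
stored patterns:

- BVC → PC: sharpened cosine matched filter, sim^16 with a soft output
  normalization v/(max v + 0.5^16). The exponent anchors the place
  bump (neighbouring stored patterns are ~0.96 similar; raw similarity
  is nearly flat); the normalization lets a frontal-field-of-view scene
  (which matches its own full-surround pattern at cosine ≈ 0.75) drive
  the winning place cell near saturation while unstructured input
  stays suppressed.
- PC → BVC/PRb: divisively normalized projection of the stored
  patterns through the fourth power of the place bump, so the
  reconstruction is read out at the bump center rather than blurred
  across its flanks.
- Learned object blocks (PC↔OVC, PC↔PRo, OVC↔PRo, PRo→HD) are grown by
  one-shot Hebbian outer products normalized to unit maximum. Readout
  uses presynaptic divisive normalization with a floor of 1 (PC/OVC
  directions) or per-row projection coefficients (identity neurons),
  so reciprocal learned loops have gain < 1 and a reactivated memory
  decays once its cause disappears. The identity→OVC and place→OVC
  gains (0.5 each) are sub-saturating so that when several objects are
  bound to one place pattern the cued object dominates while the
  others remain as residual peaks — the substrate of identity
  inference in imagery.
- Vector-cell relays (BVC/OVC) have a firing threshold of 0.05: the 5%
  suppressed-direction bleed during perception sits exactly at
  threshold and stays silent, while weakly driven (unattended)
  perceptual input passes at reduced rate.

Place competition: local Gaussian excitation (σ = σ_pc, gain 0.08)
plus an expansive-divisive stage — inputs within 30 % of the strongest
total input are thresholded, squared and normalized to a total
activity set point of 3.0 — so a single bump forms, tiny advantages
are amplified (winner-take-all), and the bump re-anchors on the drive
rather than on its own history. Degenerate inputs are resolved
deterministically: a near-uniform drive is seeded at the lowest-index
maximal cell, and if several disconnected bumps survive, the component
with the strongest peak (ties to lowest index) wins. Time constants:
place dynamics 10 steps, identity populations 20 steps, sensory relays
(parietal window, BVC/OVC feed) 2 steps. The relays are fast so that
the three-stage perception→PW→BVC→PC chain tracks a moving agent
within one lattice spacing; the behavioral quantities are insensitive
to the exact values as long as relays are much faster than behavior.

Pattern completion is solved as an index-based fixed-point iteration
(gather location evidence, settle the place competition, re-project
onto the other populations, iterate to change < 1e-4 per cell, budget
500 inner steps): the same computation as the joint leaky dynamics but
robust at wall-adjacent locations. Retrieval precision is one lattice
site: cues retaining half the active cells always return the cued
memory, occasionally shifted by one site (4.5 cm) when the deleted
half removes the deciding evidence.

## Grid cells and reservoir units

7 modules × 100 cells; a cell's rate is the rectified, unit-peak
normalized sum of three plane-wave cosines 60° apart (scales 25, 32,
41, 52, 67, 86, 110 cm; orientations drawn once per module from the
seed; phases on a regular 10 × 10 lattice of the unit cell). Grid→
place weights are the Hebbian association of grid rates with place
field centers, stored as L2-normalized matched filters; the summed
drive is passed through an expansive dendritic nonlinearity (power 4),
which puts the population drive's global peak within a fraction of a
lattice spacing of the represented position. Grid input contributes
gain 0.1 during perception (a stabilizing minority input) and gain 1.0
during imagery, where it dominates and mock motor efference moves the
bump (tracking error < one lattice spacing at 0.25 cm/step; closed
imagined loops return to their start within 1.5 spacings).

Reservoir units (default 200) receive sparse random grid input (5 %
connectivity, uniform positive weights, deterministic per seed), a per-
unit firing threshold at the 80th percentile of their drive over the
arena (without it the dense summed grid input makes every unit fire
everywhere), and a divisive feedback gain, corrected each step and
clamped to [0.1, 10], that holds total pool activity at the place-bump
set point. Binding during a real traversal associates each unit with
the time-integral of the perceived boundary pattern weighted by its
firing, normalized per unit.

## Attention, salience and encoding

One object is attended at a time; attention advances to the next
visible object in environment order after 600 steps, or immediately if
the attended object leaves the field of view. The attended object
drives the parietal window at gain 1, other visible objects at 0.1.
Encoding is salience-triggered and one-shot: an attended, visible
object within 55 cm for 60 consecutive steps (300 in the multi-object
vantage protocols, where binding must wait until the agent holds a
stable view of both objects) is Hebbian-associated and never learned
again. Two simultaneously dominant identity neurons raise a binding-
ambiguity error.

## Scripted protocols and their readouts

The bundled protocols are numbered 1.0–5.0. Choices worth noting:

- Recall quantification uses the temporal mean of the last 25 % of the
  recall segment, a chance baseline sampled every 100 bottom-up steps,
  and (for the recall batteries) trajectories that first approach the
  object slowly and then tour the arena so the baseline samples many
  vantage points.
- Trace-response maps (protocols 2.1/2.2) are computed over the
  top-down phases of the theta-like gating (period 125 steps, duty
  0.8 by default, 0.6 in the trace protocols for denser top-down
  sampling): the memory component would otherwise be diluted ~4:1 by
  the duty cycle. Identity-trace contrast is measured between the
  15-cm disc around the encoding site and everything beyond 25 cm; the
  6-cm map smoothing and the identity neuron's 20-step decay trail
  unavoidably spill a skirt into the 15–25 cm annulus.
- Rate maps are occupancy-normalized histograms (4-cm bins) with
  optional Gaussian smoothing of rate and occupancy before division;
  the map is masked on the raw occupancy so that smoothing never
  manufactures rate estimates in unvisited bins. Fields are connected
  components above half the map maximum with at least 3 bins; in the
  vector-field analysis, fields are matched to objects by optimal
  one-to-one assignment (a nearest-field rule is unidentifiable once
  the shared offset exceeds half the object spacing).
- The firing-field survey presents its three objects one per foraging
  session (the design of the rodent experiments it mimics, where
  objects move between sessions) and analyzes visibility-conditioned
  maps: each session's map averages only the steps on which that
  session's object lay in the frontal field of view, the directional
  analogue of occupancy normalization. A vector cell fires only during
  such steps, and in a single multi-object walk of practical length
  the slow attention cycle, the field-of-view gate and the path
  geometry jointly leave some conjunctions badly under-sampled. The
  analyzed cells (tuning 11 and 17 cm toward East and South) are
  chosen so all their expected fields lie in well-covered interior
  territory.
- Mental navigation (4.0) recalls object 1 and images a straight pass
  through the area where object 3 was encoded, approached from a
  direction never experienced; the readout compares the parietal peak
  bearing with the bearing of the stored allocentric offset under the
  imagined heading.
- Short-cutting (5.0) walls off a pocket of the arena during training
  (the stored patterns of pocket locations are zeroed), plans a
  straight path through it, and compares reservoir peak order between
  the imagined plan and the real traversal, and the imagined scene
  after binding against the perceived one.

## Problem sizes

Default simulations use the 100-cm arena, 816-cell polar populations,
484 place cells, 700 grid cells and trajectories of 1–4 × 10³ steps;
the firing-field surveys use foraging walks of ~5 × 10⁴ steps. The
recall and novelty batteries run 20 instances with independent
trajectory jitter and perturbation draws.

## What the synthetic protocols do and do not show

All experiments run on programmatically generated toy environments:
square arenas, straight barriers, point objects, noiseless geometric
sensing, and a perfectly calibrated angular-velocity signal. Passing
these protocols shows that the mechanisms — gain-field transformation,
attractor completion, one-shot binding, grid-driven imagery — are
internally consistent and robust to diffuse neuron loss and rate
noise. It does not show robustness to realistic vision (texture,
depth noise, lighting), to odometry drift without visual resetting,
to remapping across multiple environments (not modeled), or at the
compressed timescales of replay phenomena (a rate model has no
sub-theta temporal structure). The attention model is a scheduling
heuristic, not a mechanism; salience is proximity-only.

## Known limitations

- Localization assumes a trained context; in a novel environment the
  matched filter has nothing to match (by design — see the reservoir
  mechanism for territory extension).
- The square arena is rotationally ambiguous in its boundary geometry;
  heading is therefore carried entirely by the ring (plus identity
  labels), and long protocols with many sharp turns accumulate a few
  degrees of heading drift, which slightly blurs allocentric firing
  fields.
- One-site (4.5 cm) quantization of retrieved locations, set by the
  place lattice.
- Only one spatial context is supported; there is no remapping,
  consolidation or forgetting.
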