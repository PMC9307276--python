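# Methods

## Model

The simulation describes the self-organization of pericentriolar-material
(PCM) complexes in a two-dimensional circular cell of radius *R* = 10 µm.
Agents are:

* **PCM complexes** — beads of radius 50 nm carrying one microtubule
  nucleation site, one dynein motor, and (depending on the scenario)
  adhesive couples. Dynein transports a complex along microtubules grown
  from *other* complexes, producing a positive feedback that gathers
  complexes at microtubule minus ends.
* **CAMSAP-kin14 complexes** — beads of the same size carrying one
  nucleation site and five kinesin-14 motors (parameterized with typical
  kinesin-1 numbers, minus-end directed).
* **Immobile seeds** — stationary nucleation sites at fixed positions and
  orientations, optionally biased to a 1-µm annulus at the cell boundary,
  emulating stabilized minus ends pinned in the cytoplasm.

Microtubules are semiflexible rods (flexural rigidity κ = 20 pN·µm²)
discretized at 0.5 µm with their minus end tethered to the nucleation site.
Dynamic instability has no rescue: growth at v_g = 0.13 µm/s (slowed by
antagonistic tip load as `exp(-F/1.7 pN)`), catastrophe at
k_cat = v_g / L_mean = 0.13/5 = 0.026 s⁻¹, shrinkage at 0.272 µm/s, removal
below 0.25 µm with immediate renucleation in a fresh random direction, and a
hard cap at 7.5 µm (growth stops, catastrophe statistics continue) that
prevents long filaments from pushing minus ends to the periphery.

Motors bind filaments within 75 nm at rate k_on, walk toward the minus end
with the linear force–velocity law `v = v_0 (1 − F∥/F_s)` clamped to
[0, v_0], unbind as slip bonds `k_off = k_off⁰ exp(F/F_d)`, and detach on
reaching the minus end. Dynein: k_on 5 s⁻¹, k_off⁰ 0.1 s⁻¹, F_d 2 pN,
v_0 0.5 µm/s, F_s 4 pN. Kinesin-14: 1 s⁻¹, 1 s⁻¹, 3 pN, 0.8 µm/s, 7 pN.
A hand cannot bind a filament or stub belonging to its own complex.

Adhesion is an effective reversible couple: a 10-nm passive stub plus a hand
with 100 nm range, k_on 10 s⁻¹, k_off⁰ 0.01 s⁻¹, F_d 3 pN. "Weak" adhesion
is one stub and one hand per complex; "strong" adhesion places five
molecules of each at five shared attachment points (25 + 25), so touching
complexes form multiple bonds. These numbers are effective — they set an
adhesion neither weak nor strong relative to the motor forces, not a
measured molecular property.

All linking elements (motor links, adhesive bonds, minus-end anchors) are
zero-rest-length springs of 100 pN/µm. Steric repulsion acts bead–bead and
object–boundary only (harmonic, 100 pN/µm); filament–filament and
filament–bead crossings are allowed, standing in for the third dimension
that the 2-D projection removes. Thermal energy is kT = 4.2×10⁻³ pN·µm,
viscosity 1 pN·s/µm²; translational drag keeps the 3-D Stokes form 6πηr
(beads) and 6πη·(seg/2) per filament vertex.

The default run is 1800 s (30 min) at dt = 0.01 s, by which time the
organization is stationary. A 18,000 s variant exists in some
parameterizations of this model family; both durations are supported
(`WorldParams.total_time`), with 1800 s as the default because all
statistics reported here are computed at or before that time.

## Numerical scheme

Overdamped Euler–Maruyama on every mobile degree of freedom
(`Δx = F/γ·dt + √(2kT·dt/γ)·N(0,1)`), with three stabilizations that the
stiff parts of the force field require at dt = 0.01–0.02 s:

1. **Implicit bending.** The linearized discrete-rod bending force is
   `−(κ/seg³)·D x` with `D` the squared second-difference operator; its
   fastest mode relaxes in well under a millisecond, so it is integrated
   implicitly by multiplying each filament's tentative update with the
   precomputed inverse of `I + (dt·κ/(γ·seg³))·D`. The operator covers
   vertices 0..n−2; the tip segment has a variable rest length and is
   treated as a free hinge (including it in the uniform-spacing stencil
   would create phantom curvature forces).
2. **Exponential-integrator spring scaling.** Each pairwise harmonic
   interaction is scaled by `(1−e^(−λ))/λ` with
   `λ = k·dt·(1/γ_a + 1/γ_b)`; this makes an isolated spring's relaxation
   exact and overshoot-free at any stiffness (a 100 pN/µm link on a 50-nm
   bead has λ ≈ 2 at dt = 0.02 s, which a plain explicit step cannot
   handle).
3. **Length projection.** Segment inextensibility is enforced by four
   pairwise Gauss–Seidel sweeps restoring rest lengths after each update;
   post-step segment strain stays below 5% of the discretization length
   (asserted in the test suite). Immobile-seed minus ends are pinned
   exactly.

Per step, the update order is fixed: renucleation → binding attempts →
bound-motor stepping and unbinding → dynamic instability → force
accumulation → position update → constraint enforcement. The growth load on
a tip is the antagonistic component of the previous step's accumulated tip
force. All randomness flows through one PCG64 generator per run, with
per-step variates drawn in fixed order, so a (configuration, seed) pair
reproduces a trajectory bit-exactly on one platform. The inner loops are
numba-compiled over structure-of-arrays state; the first call in a fresh
environment compiles (~1 min), after which a full-scale 300-complex run
takes about two minutes.

Binding selects the nearest in-range candidate, deterministic given the
geometry; attempts are Bernoulli with probability `1 − e^(−k_on·dt)` per
step. Attachment points are fixed offsets from the bead center (beads do
not rotate; at 50 nm radius the rotational compliance of the load-bearing
links makes bead torque negligible).

## Quantification

The organization metric is deliberately simple: distances of all complexes
to their center of mass (arithmetic mean position), summarized as the mean
and the population SD (divisor n), plus the empirical CDF. Classification:
compact iff mean ≤ 0.2·R; else ring iff SD ≤ 0.3·mean; else dispersed. The
two thresholds are configuration, chosen to separate the three canonical
synthetic patterns (Gaussian blob σ = 0.05R, ring at 0.5R with 5% jitter,
uniform disc) and asserted on those patterns in the tests; they are not
measured quantities. In mixed systems both complex kinds are pooled. The
sweep post-processing reports the smallest grid value whose compact
fraction reaches 0.8 ("robust clustering") and flags grid points with
compact fraction strictly between 0.2 and 0.8 as bistable; the 0.8
criterion is an operationalization — any threshold reported with it must
cite it.

The imaging module reimplements four measurement procedures:
structure-tensor radiality decomposition (Gaussian-derivative gradients,
tensor smoothing σ = 6 px; the radial map is `|cos Δθ|·I` so radial +
non-radial reconstruct the image exactly; the origin pixel takes radial
weight 1), concentric-ring intensity profiles (default ten 2-µm rings,
normalized by total image intensity; the 20-ring variant is reachable via
parameters), photobleaching-recovery normalization (pre-bleach mean set to
100% after background subtraction), local filament density in a 2-µm disc
(baseline 20 frames = 100%), and motor-track processing: greedy
mutual-nearest-neighbor linking within 5 px with no frame gaps, rule-based
filtering (4–200 frames, turns ≤ 90°, speed 100–1500 nm/s; "speed" defaults
to path length over duration, with net displacement as an option since the
convention is not fixed by the procedure), quadrant splitting by net
displacement sign (zero counts as positive), and the minus-end-out length
fraction.

## Synthetic data

`pcm_selforg.fixtures` generates every test input with known ground truth:
filament-pattern images (radial lines through an origin, tangential arcs,
isotropic random lines; soft-edged strokes on a 512² grid at 66.7 nm/px),
point patterns with closed-form distance moments (Rayleigh mean σ√(π/2) for
a Gaussian cluster; 2R/3 and R/√18 for a uniform disc), mono-exponential
photobleaching-recovery traces, and track tables that straddle each filter
boundary (3 vs 4 frames, 89° vs 91° turns, 99/101 and 1499/1501 nm/s).
Noise is additive Gaussian clipped at zero (Poisson optional). These
fixtures emulate geometry, not optics: no point-spread function, no shot
noise model, no drift, no localization error. Passing the imaging tests
therefore shows the *arithmetic* is right on clean inputs, not that the
pipeline is robust to real microscope data.

## Reduced scale

Desk-scale testing maps the full systems (10 µm, 300 complexes, 1800 s,
dt 0.01) to 5 µm, 75 complexes, 600 s, dt 0.02 with 10 replicates.
Counts, radius and durations scale; filament parameters do not (an optional
`scale_fibers` mode scales the mean length and cap with the radius and
re-derives k_cat, preserving length ratios at the cost of faster turnover).
Scaled scenario names carry an `@scaled` tag so the two regimes cannot be
confused in output tables.

## Known limitations

* At full scale the model robustly produces compact central clustering of
  300 weakly adhesive PCM complexes (the acceptance script measures a
  final mean COM distance around 1 µm in a 10-µm cell), compaction of
  adhesive CAMSAP-kin14 and of the mixed CAMSAP-kin14 + adhesive-PCM
  systems, and dispersal when 300 immobile random microtubules dominate
  and only 50/300 complexes nucleate. The strong-adhesion rescue on the
  immobile-microtubule background coarsens more slowly than 1800 s (still
  multi-cluster at that time). The model does **not** produce a loose
  ring-like arrangement for non-adhesive complexes: without adhesion the
  minus-end directed transport still collapses the population into a
  compact aster at least as tight as the adhesive one. Mechanistically,
  motors that detach at a minus end re-bind nearby filaments within
  fractions of a second, which tethers complexes to each other as
  effectively as the explicit adhesive couples do. Suppressing near-end
  rebinding, adding a refractory period, or allowing hands to compete for
  their own complex's filament does not change this outcome, and a ring
  initialized by hand collapses within minutes, so the ring is not an
  attractor of this implementation. The ring-formation checks in the
  acceptance test suite are left failing rather than re-tuned.
* At the reduced scale above, 600 s is too short for the adhesive systems
  to coarsen into a single cluster (they remain multi-cluster, classified
  dispersed), so the reduced-scale phase-behavior battery reports compact
  fractions near zero for all conditions; the full-scale contrasts are the
  meaningful ones.
* Filament vertex drag is isotropic (6πη·seg/2 per vertex), which
  overestimates slender-body drag by a logarithmic factor; transport of a
  complex with its filament is correspondingly somewhat over-damped.
* Beads do not rotate, the tip segment is a free bending hinge, and
  renucleation is instantaneous; all three are simplifications where the
  underlying biology is unconstrained.
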