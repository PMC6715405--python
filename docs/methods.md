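# Methods

## The model family

`svbsim` simulates vascular patterning in plant stems as a stochastic
reaction–diffusion process on a voxelized domain: a disc (stem
cross-section) or a right circular cylinder (whole stem), with unit
cubic voxels, face adjacency, and reflective (zero-flux) boundaries
realized by neighbor omission. Counts within a voxel are well-mixed
integers; all species start at zero and the production channels
bootstrap the system.

The core is an activator–substrate (Gray–Scott / Schnakenberg) pair:

    d[H]/dt = D_H ∇²[H] + k1 [H]²[B] + k4 − k5 [H]
    d[B]/dt = D_B ∇²[B] − k1 [H]²[B] + k2 − k3 [B]

realized stochastically as mass-action channels X1–X5 (the dimer
channel X1 fires at `k1·nH·(nH−1)·nB`, recovering the `[H]²[B]` term to
O(1/n)). Regions of high H are read as initiating vascular bundles
(SVBs in cross-section). The extensions add:

* **P (carrier, HBP)** — immobile, produced by H (X6), decaying (X7).
  A cargo molecule leaving a voxel with `nP` carriers moves
  longitudinally with probability
  `(2D + α nP) / (6D + α nP) = 1/3 + (2/3)·nP/(6D/α + nP)` —
  Michaelis–Menten above the passive 1/3 baseline with Vmax = 2/3 and
  Km = 6D/α. The facilitated component `α·nP·n_cargo` is split equally
  between the two z-faces (symmetric) or applied wholly toward −z
  (basipetal), with components toward missing neighbors dropped at
  boundaries.
* **M (peripheral inhibitor, HBPM)** — produced only in the outer
  cortical shell (X9), diffusing inward, decaying (X10) and
  annihilating H on contact (X11; optional X12 annihilates B). M's
  penetration sets the SVB-free "zone B" and, in narrow stems, floods
  the whole cross-section.
* **A (apical hormone, HBPMA)** — produced only in the top z-layer,
  transported basipetally by P (upward facilitated transport off), in a
  feedback loop with H. The loop's return arm is configurable
  (activating `H→H+A` or degradative `H+A→H`) because its exact
  published form is not available; the forward arm is `A→A+H`.

## Sampler

Exact SSA in the spatial (RDME) setting: per-voxel total propensities
are kept under a Fenwick tree; each event draws Exponential(total)
waiting time, picks a voxel by tree descent, then re-enumerates that
voxel's channels in a fixed order (reactions, then per-species hops,
then facilitated hops) — a next-subvolume-equivalent direct method.
Tie-breaking is by that fixed order, and a single seeded xoshiro256++
generator drives everything, so trajectories are bit-reproducible.

Checkpointing stores counts, time, event count, RNG state, the pending
(overshooting) event time, and the sampler's float bookkeeping; resume
therefore continues event-for-event identically to an uninterrupted
run, and an altered configuration is rejected by config-hash mismatch.
The drift-correcting tree rebuild happens at absolute event-count
multiples (2²²) so interrupted and uninterrupted runs rebuild at the
same events.

Throughput on one CPU is ≈5M events/s for the 2D HB disc at radius 30,
which sets the desk scale of everything below.

## Default kinetics (and why)

The published supplementary parameter tables are not part of the
package's sources, so preset constants are the package's own,
calibrated once to the *regimes* the model family is defined by and
then frozen:

| parameter | default | meaning |
|---|---|---|
| k1 | 1/40² | autocatalysis; 1/COUNT_SCALE² keeps the dimensionless dynamics invariant |
| k2, k4 | 52, 8 | Schnakenberg b=1.3, a=0.2 × COUNT_SCALE |
| k3, k5 | 0.02, 1 | substrate/activator decay (k5 sets the time unit) |
| D_H | 0.05 | activator hop rate (per direction, unit lattice) |
| D_B | 50 | ratio D_B/D_H = 1000, inside the Turing band |
| k6, k7, α | 0.02, 0.1, 0.1 | carrier production/decay/affinity; α·P* ≫ 6D_H at spots |
| k9, k10, k11, D_M | 100, 0.2, 0.5, 5 | inhibitor source/decay/annihilation/diffusion |
| k13, k14, D_A, k_AH, k_HA | 20, 0.05, 0.05, 0.05, 0.01 | apical hormone kinetics |

COUNT_SCALE = 40 puts the homogeneous activator level at ≈60
molecules/voxel; Turing spot peaks then exceed 1000 while demographic
noise tops out near 120, so the absolute spot criterion of 400
molecules/voxel separates pattern from noise with a wide margin. With
a=0.2, b=1.3 the critical diffusion ratio is ≈22, so ratio 10 has no
Turing band (no persistent spots, only noise) and ratios ≥100 pattern
robustly — the contrast the diffusion sweep measures.

M's parameters realize the stem-size mechanism: decay length
√(D_M/k10) = 5 voxels, comparable to the narrow stem radius (7) and
small against the wide stem radius (20), and k11 ≫ k5 so the inhibitor
front can extinguish established spots it reaches. Time is in units of
1/k5; patterns are stationary by t ≈ 15–20 and runs use t = 25–60.

## Desk-scale choices and lattice guards

* The cortical shell is the outer 4% radial fraction by default but
  never thinner than one voxel (inner radius capped at R−1): at R = 7 a
  literal 4% shell catches only the four voxels at exactly r = R, a
  discretization artifact without a continuum counterpart.
* Zone B width is measured from the shell's inner edge to the outer
  edge (r + ½) of the outermost spot voxel, so wall-to-wall spots give
  width zero on a discrete lattice.
* The stem-size experiment runs on 2D cross-sections (the carrier's
  longitudinal transport is inert in 2D); this mirrors the original
  study's own use of 2D runs for parameter exploration, and keeps the
  replicated contrast within a single-CPU test budget.

## The deterministic oracle

`pde` integrates the same pair with explicit Euler on the identical
lattice (5-/7-point Laplacian from the neighbor lists, so zero-flux is
inherited and total mass is conserved under pure diffusion), guarded by
`dt < 1/(2d·max D)` and aborting on negative concentrations instead of
clipping (a negative value means the step/parameter regime is invalid;
clipping would silently distort dynamics). `homogeneous_steady_state`
solves the eliminated cubic in [H]; `dispersion_relation` reports the
growth rate of mode q from the linearization, and its Turing band
predicts whether the matched stochastic run forms spots. Deterministic
runs are seeded from the steady state plus a small (default 1%)
perturbation, since the PDE has no intrinsic noise to break symmetry.

## What the generator's green tests do and do not establish

Synthetic runs live at ~10²–10³ molecules/voxel on radii 7–30, orders
of magnitude below the published 3D simulations (~10¹¹ events over
days). Green tests establish: exactness of the sampler (Poisson
stationary law, mean-field tracking, the transport law's empirical hop
statistics), conservation and region-mask discipline, determinism and
resume identity, and the direction of the published qualitative trends
(spot density vs diffusion ratio, spot presence vs stem size). They do
not establish the published absolute spot counts or diameters — those
depend on the unpublished full-scale parameters and lattice sizes — and
3D vessel connectivity/tortuosity is out of scope.

## Numerical details

* Mass-action propensities use combinatorial counts (`n(n−1)` for the
  dimer); region-restricted channels evaluate to zero outside their
  region bitmask.
* Waiting times use `−log(1−u)/a₀` with u ∈ [0,1) from 53-bit doubles.
* Event selection tolerates last-bit drift in the tree by falling back
  to the last positive channel in the fixed order; drift is bounded by
  periodic rebuilds.
* Spot detection is 4-connected by default (matching the diffusion
  topology); 8-connectivity is available for sensitivity checks.
  Equivalent diameter is `2√(area/π)`.
* Stationarity is operationalized as constant spot count plus Jaccard
  similarity ≥ 0.9 of consecutive supra-threshold masks, since the
  published criterion ("did not change substantially") is qualitative.

## Known limitations

* No growing domains, cell division, or tapered stems; voxel spacing is
  fixed at 1 and diffusion coefficients are per-direction hop rates.
* The HBPMA feedback form is a documented guess among the two shapes
  the configuration exposes.
* Stele presets (eustele, siphonostele, atactostele, haplostele,
  plectostele via the PDE) are qualitative starting points, not
  parameter-exact reproductions.
* Tau-leaping or hybrid solvers are not provided; everything is exact
  SSA or explicit-Euler PDE.
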