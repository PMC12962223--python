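# Methods

This note documents the models, conventions, numerical choices and known
limitations of `ptxmux`, in the order the pipeline uses them.

## Excitation model and conventions

The simulator implements the small-tip-angle (STA) approximation for trains
of hard sub-pulses with an arbitrary channel→coil schedule. Conventions that
are genuinely open choices and therefore fixed here explicitly:

- **Units.** Sensitivities are stored in rad/(V·s) with the gyromagnetic
  ratio folded in, and the equilibrium magnetization is taken as 1, so
  `|A·p|` is directly the flip angle in radians. This removes any ambiguity
  between B1 field units (T/V) and flip angle.
- **Off-resonance.** ΔB0 maps are stored in Hz (the convention of measured
  field maps) and enter the system matrix as the phase
  `2π·ΔB0·(t_j − T)`, i.e. the Hz value is multiplied by 2π rather than γ.
- **k-space.** k-locations are in m⁻¹ and the spatial phase is
  `2π·k·r` (gradient-area convention). Voxel indices are 0-based, physical
  positions are voxel centers, axes right-handed; `±14 m⁻¹` serves both as
  the random-initialization range and as a box bound during optimization
  (whether it is a hard bound is an open choice; we enforce it).
- **Timeline.** `t_j` is the temporal center of sub-pulse `j` on the
  physical timeline. RF-free intervals advance the clock: between two
  sub-pulses the gap is the gradient-blip duration (default 100 μs) if the
  k-location changes, else the switch gap (default 10 μs) if the
  channel→coil routing changes, else zero. Gaps are placed only *between*
  sub-pulses, never before the first. Center placement minimizes the phase
  discretization error of the hard-pulse approximation.
- **Masked evaluation.** The system matrix is built over mask voxels only;
  full-grid maps are reconstructed by scatter. This matches the
  mask-restricted NRMSE definition and bounds memory.

A rotation-matrix hard-pulse Bloch integrator (relaxation off) provides an
independent oracle: each sub-pulse is a Rodrigues rotation about the
effective field, blips are z-rotations realizing the k-space phase change,
and off-resonance precession runs through all gaps. At 5° targets the two
simulators agree to well under 1% of the target; the package reports STA
NRMSE by default and the Bloch map is available for cross-checking.

## Multiplexing rearrangement and power accounting

The simultaneous→multiplexed index maps are implemented for G ≥ 2 coil
groups (default: the two rows). In keep-duration mode sub-pulse durations
are divided by G and amplitudes multiplied by G; in double-duration mode
both are kept. Switch gaps carry no RF: the switch is absorptive, so gaps
are excluded from the average-power sum but included in the total duration.
Average power is `(1/TR)·Σ |p|²/Z·Δt` with Z = 50 Ω; peak instantaneous
per-channel power is `max |p|²/Z`. The exact factors (×2 average, ×4 peak
for G = 2 keep-duration) are asserted as identities in the tests. The
inverse map (merge) recovers the original pulse bit-exactly; the multiplex
mode needed to undo the amplitude scaling travels in the pulse's metadata.

## SAR operators and VOP compression

Q-matrices are per-voxel Hermitian PSD operators in (W/kg)/V² at 100% duty;
pulse SAR is `(1/TR)·Σ_j Δt·p_j^H Q p_j`. Row-switched pulses are evaluated
against row-wise Q-sets by routing each sub-pulse to the set of the row it
physically drives.

VOP compression is greedy: voxels are visited in order of decreasing largest
eigenvalue; a voxel is covered if an already-selected core matrix plus the
overestimation term `U = fraction × (global max eigenvalue) × I` dominates
it (smallest eigenvalue of `V + U − Q` above `−10⁻⁹`·‖V+U‖). The stored
prediction matrices are core + U, which makes the safety property — VOP
pSAR never below the source-set pSAR, for any drive — hold by construction,
not just empirically. The scaled identity is the simplest matrix fulfilling
U's role; it is recorded in the container so predictions are reproducible.
The worst-case overestimation is probed empirically as
`max(VOP pSAR / exact pSAR) − 1` over 4096 seeded complex-Gaussian
unit-power modes (the reference algorithm's closed-form factor is not
reproduced here; the empirical probe is a stand-in, not claimed equivalent).
Random modes are complex Gaussian, normalized to 1 W into 50 Ω.

For multiplexing, the two rows' Q-sets are concatenated along the voxel axis
and jointly compressed — the rows act as two virtual voxel models that the
single static VOP set must represent simultaneously. The guarantee this
yields is that every VOP-monitored drive bounds each virtual model's SAR
(and hence each row's physical contribution). The per-physical-voxel
switched SAR (top-row matrices for odd, bottom-row for even sub-pulses) is
the quantity reported by the survey's amplification statistics; its mean
relation to simultaneous SAR (voxel-wise inverse ratio between 0 and 1,
expectation 0.5 for decorrelated rows) is asserted statistically. Individual
modes may show multiplexed pSAR *below* simultaneous pSAR (spatially
migrating hot spots); the survey makes no amplification ≥ 1 assumption.

## Pulse design

Magnitude least squares with per-VOP quadratic constraints, all VOPs
constrained individually. Numerical choices:

- The non-smooth magnitude is smoothed as `sqrt(|z|² + ε²)` with
  `ε = 10⁻⁸·b`, keeping the objective differentiable at nulls (reported
  NRMSE is always computed from the exact magnitude).
- Variables are stacked real/imag pulse amplitudes plus free k-locations;
  for multiplexed pulses consecutive sub-pulse pairs share one k variable
  (this realizes the pairing constraint exactly rather than via penalty).
  The last (pair of) k-location(s) is pinned to the origin; a static shim
  (`n_kt = 1`) fixes k = 0 and optimizes amplitudes only.
- Analytic gradients for the objective (w.r.t. amplitudes and k) and the
  constraints are supplied and can be certified against central finite
  differences (`gradient_check`, tolerance 10⁻⁵).
- Unconstrained joint (P, K) solves use L-BFGS-B with k box bounds,
  followed by an RF-only block-coordinate polish at frozen K (the joint
  problem converges slowly in its tail; the polish is cheap and removes
  most of the residual suboptimality). Constrained RF-only solves use SLSQP
  with the analytic Jacobians. If a terminal SLSQP point violates a
  constraint by more than 10⁻⁶ relative, amplitudes are rescaled to exact
  feasibility (SAR is quadratic in amplitude) and the solution flagged.
- L-curve: one unconstrained joint solve defines the top of the sweep; then
  warm-started RF-only solves at SAR limits decreasing linearly (64 levels
  by default) to a floor of 0.1 W/kg, K frozen. A backward warm-start pass
  follows: a tighter-limit solution is feasible at every looser limit, so
  any looser level it beats is re-solved from it and the better result
  kept. This makes the fidelity-vs-limit monotonicity structural while
  every point remains a genuinely computed feasible solution; it also means
  the first curve point can be marginally better than the raw unconstrained
  solve. Solver failures are recorded per level and the curve is returned
  regardless.
- The Pareto front over restarts is the non-dominated subset of all
  (pSAR, NRMSE) points, returned with pSAR decreasing. A ~1000-restart
  budget is a cluster workload; the default here is 16 and the bundled
  analyses use 8, which saturates the minimum NRMSE on the synthetic
  fixtures.

Driving scenarios: `top`/`bottom` (one row, 8 channels, Δt = 0.2 ms),
`full16` (all coils, 0.2 ms), `multi8_conv` (the full16 solution rearranged
without re-optimization, 0.1 ms, evaluated under the joint VOPs),
`multi8_opt` (dedicated switched design, 0.1 ms), `multi8_2T_opt` (same at
0.2 ms, twice the pulse duration), and `passive_split` (8 channels feeding
top/bottom element pairs through a fixed splitter with −22.5° intra-pair
phase; effective sensitivities `C·β` and SAR operators `C*·Q·Cᵀ`). Global
power and global-SAR limits are not part of the optimization (peak local
SAR is the binding constraint in this regime); a power report is always
available post hoc.

## Synthetic data generator

The generator emulates a two-row 16-element head array around an ellipsoidal
head mask (semi-axes 7.5/9/8.5 cm) on a default 24³ grid at 8 mm spacing.
Per element, sensitivity magnitude decays exponentially with distance from
the element and the phase advances with azimuth (so the circularly-polarized
mode is constructive at the array center) and with distance (traveling-wave
term); a seeded smooth complex perturbation (10%) decorrelates elements.
E-field surrogates with three complex components feed a pooled Gram
construction for the Q-matrices (Hermitian PSD by construction; pooling over
a 1.5-voxel ball stands in for mass-based averaging). The off-resonance map
is filtered noise with its second-order polynomial component removed
(emulating shimming) and scaled to a 71 Hz in-mask standard deviation. All
randomness fans out from one top-level seed through counter-based
sub-streams, so any subset regenerates independently and bit-identically.

Parameter defaults and why: field decay length 3.5 cm (effective RF
penetration of a 400 MHz dipole into tissue, combining skin depth and
near-field falloff); row planes at ±4.5 cm (whole-head coverage splits
head–foot responsibility between rows — one row alone cannot homogenize the
far half, which is what makes the single-row scenarios genuinely inferior);
element radius 13 cm; rows azimuthally staggered by half an element spacing
(22.5°), which is the geometry that motivates the −22.5° passive-splitter
phase; SAR scale κ = 0.01 (W/kg)/V², calibrated so random 1 W drives
produce peak local SAR of order 1 W/kg at 100% duty on the default grid,
the scale head arrays operate at.

These are analytic surrogates, not electromagnetic solutions: no tissue
heterogeneity, no coil coupling, no mass-based 10 g averaging, no realistic
dipole physics. The identities the toolkit asserts on them (rearrangement
equivalence, power factors, VOP dominance, interference bounds, Jacobian
correctness) are algebraic and hold for any fields; the scenario-comparison
results are qualitative analogs — passing them shows the machinery
reproduces the *structure* of the real-array trade-offs, not the measured
numbers.

## Problem sizes used by the bundled analyses

The test-suite and acceptance analyses run the design sweeps on a 14³ grid
at 14 mm spacing (≈ 900 mask voxels, 22–110 VOPs depending on the set, at a
0.2 compression fraction), 3-kT-points pulses, 8 restarts, 16-level sweeps;
statistical SAR checks use 500–2800 voxels and 4096–10000 random modes. The
generator's 24³ default remains the reference fixture for simulation-scale
work.

## Known limitations

- No relaxation or large-tip simulation beyond the Bloch test oracle; no
  slice/slab-selective pulses; no gradient slew/amplitude constraints.
- Switch insertion loss and finite transition time are not modeled (the
  gaps are ideal RF-free intervals).
- The SAR-constrained solver is a local method; the multi-start heuristic
  approximates but does not certify global trade-offs.
- Joint VOP monitoring bounds each row's SAR contribution; the exact
  per-voxel switched SAR can in adversarial rank-1 constructions exceed the
  static-VOP prediction, which no static set can bound — in the survey this
  is a statistical comparison, not a safety claim.
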