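# Methods

## Forward models

**Bloch.** The magnetization of each masked voxel evolves under
`dM/dt = γ M × B` in the rotating frame.  The simulator uses the hard-pulse
approximation: within each raster interval (default 10 µs) the effective
field is constant and the state is advanced by the exact axis-angle
(Rodrigues) rotation through `γ|B|Δt`.  This is unconditionally
norm-preserving — the tests require `| |m| − 1 | < 1e−9` after arbitrary
pulses — unlike forward-Euler integration of the differential equation.
Relaxation, when enabled, is interleaved per step as a separable
transverse decay `exp(−Δt/T2)` and longitudinal regrowth toward `M0`
with `exp(−Δt/T1)`; designs ignore relaxation by default (pulse durations
are ≪ T2).

The transverse field at a voxel is `Σ_c b1_c · p_c(t)` with the
sensitivities in nT/V and RF in volts; the longitudinal component is
`g(t)·r + 2π·Δf/γ` with the off-resonance Δf in Hz.

*Sign convention.* Positive `B_z` (positive off-resonance) precesses `M_xy`
clockwise: the accrued phase is negative.  This follows directly from
`dM/dt = γ M × B` and is the only choice consistent with the STA system
matrix below.  Formulations with the opposite handedness exist in the
literature; only |mxy|-derived quantities (FA, NRMSE) are convention-free.

**Small-tip-angle.** Linearizing around `M_z ≈ M0` gives
`m_xy = A b` with

    A[(r),(c,t)] = i γ b1_c(r) Δt · exp( i [ k(t)·r + 2π Δf(r) (t − T) ] ),
    k(t) = −γ ∫_t^T g(s) ds   (rad/m),

i.e. phase referenced to the pulse end, `k(T) = 0`.  The discrete `k` uses a
right-aligned cumulative sum exclusive of the sample's own interval, so the
final sample sees exactly zero gradient phase.  `sta_system_matrix` builds
`A` explicitly (used by the kT-points module and for cross-checks);
`sta_simulate` evaluates the same sum in factored form without
materializing `A`, which is what the optimizer differentiates through.
The two paths agree to machine precision and this identity is a standing
test.

γ = 267.522×10⁶ rad/s/T throughout.

## Differentiation and optimization

All forward kernels (Bloch step loop, STA sum, SAR quadratic forms, the
eight cost terms) are written against a small reverse-mode
autodifferentiation engine over NumPy arrays (`fastptx.autodiff`): a
tape-based `Tensor` with the ~20 primitives these models need (arithmetic
with broadcasting, trig/exp/sqrt, atan2, hinge, matmul, cumulative and plain
reductions, slicing/concatenation).  The same kernel code runs on plain
arrays for fast evaluation.  Gradient correctness is enforced by
central-finite-difference tests at 1e−3 relative tolerance on 2-channel 3³
problems, for each model and for the full cost chain.

Optimization uses AdamW (β₁ = 0.9, β₂ = 0.999, decoupled weight decay
defaulting to 0) at learning rate 4·10⁻⁴, with the optimizer state
reinitialized every 1000 iterations restarting from the best pulse seen;
that running-best pulse is returned.  Parameters are the real and imaginary
parts of every RF sample and every gradient sample, *normalized by the
corresponding hardware limit* (RF by `u_limit`, gradients by `g_limit`).
Adam steps are scale-free (≈ learning rate per iteration per parameter), so
this normalization makes the effective per-iteration motion ≈ 0.07 V and
≈ 26 µT/m — commensurate progress on both waveform types at the same
learning rate, and convergence of a tailored design within a few thousand
iterations.  With volt-scale parameters the same learning rate could move a
waveform by at most a few volts in those budgets, which is why the
normalization (or an equivalent learning-rate split) is load-bearing.

**Initialization.** `design_small_fa` starts from the CP-mode rectangular
pulse scaled (via the linear STA) to the target mean FA — the scanner's own
default excitation and the non-selective analogue of the slab recipe's sinc
seed.  This puts the search at the correct overall power level from
iteration one; a small random complex Gaussian initialization (1 V scale,
zero gradients) remains available via `initial_pulse="random"`.

**Multi-subject (universal) designs** average the full cost breakdown over
the subjects' map sets with equal weights; a standing test checks the
universal objective equals the mean of single-subject objectives.

**Cost terms.** The hinge terms reduce by *sum* over violating samples so
every violator receives gradient (a `hinge_reduction="mean"` switch exists).
`pen_rmse` is computed in degrees on the FA map of whichever model the
current phase uses; at the default weights it then balances `pen_power`
(order 0.2–0.6 for working pulses) as intended.  The slew rate is the
forward difference divided by the raster *including* the ramps from/to the
implicit zero before the first and after the last sample; together with
`err_edge` (which penalizes the squared *sum* of first and last gradient
samples, kept verbatim even though equal-and-opposite edges would cancel)
this keeps the waveform start/end scanner-feasible.  `err_edge` is a squared
sum rather than a hinge, so converged designs drive it to ~1e−9 rather than
exactly zero; the other four limit terms are exactly zero on any accepted
design.

**SAR.** Local SAR is `max_v (Δt/TR) Σ_t p(t)ᴴ V_v p(t)` over the VOP
stack — pulse samples contribute, TR dead time contributes zero.  The
differentiable path routes the gradient through the maximizing VOP.

## Design recipes

- **Small FA**: STA phase (default 7500 iterations for universal pulses,
  2500 STA-only for tailored pulses) optionally followed by Bloch
  refinement (default 2500 iterations) continuing from the STA result; the
  refinement updates RF and gradients by default (`bloch_optimize_grad`
  covers the RF-only reading).  Designs at 10° can be scaled down linearly
  to smaller flip angles without re-running.
- **Large FA (90°)**: STA design at FA/10 under `u_limit`/10 (3500
  iterations), RF ×10 (feasible by construction), then Bloch refinement of
  the RF only (1000 iterations), without a SAR constraint by default since
  preparation pulses are played sparsely.  Note the voltage-scaled
  intermediate must be *reachable*: at this package's synthetic B1 scale a
  9° design needs ms-scale durations to fit under `u_limit`/10, so tests
  exercise the recipe at 1.5–2 ms.
- **Slab-selective**: seed = CP-mode sinc (time-bandwidth product 8 over the
  RF window) on a trapezoidal selection gradient along the slab normal with
  slew-compliant ramps and a refocusing lobe canceling the post-center
  area, scaled to the in-slab target FA; then free joint optimization
  against the pattern (target FA inside the slab, 0 outside).
- **kT-points benchmark**: three 130 µs rectangular sub-pulses with 60 µs
  gaps (510 µs total).  Channel weights per point solve the unregularized
  magnitude-least-squares problem by 20 variable-exchange iterations
  (`b ← A⁺(t·e^{i·arg(Ab)})`, phase initialized to zero; the magnitude
  residual is provably non-increasing).  The first two k-space locations are
  the best of `n_candidates` uniform draws from the ±14 m⁻¹ cube; the third
  sits at the origin.  k-space is measured in rad/m (`Δk = γ∫g dt`),
  matching the `k·r` phase of the system matrix — with this convention the
  worst-case corner-to-corner blip fits the 60 µs gap exactly at the 185
  T/m/s slew limit, which a cycles/m reading would violate by ~2×.  Blips
  are symmetric triangles, widened to trapezoids only if the amplitude limit
  requires; the kT search matrix works at sub-pulse granularity (one
  effective sample per point) and full-raster STA reproduces its prediction
  within 2%.

## Synthetic phantom

The generator stands in for measured head data; everything is deterministic
under a seed.

- **Mask**: ellipsoid with semi-axes 45% of the grid extent (~38% of voxels).
- **B1+ maps**: `n_channels` loop elements on an xy-ring just outside the
  mask (5% per-element radius jitter).  Magnitude: Gaussian falloff, sharp
  transversely (σ_t = 0.5·half-extent) and mild longitudinally
  (σ_z = 1.5·half-extent), since real arrays cover the head in z.  Phase:
  ring azimuth + a propagation-like term linear in the 3-D distance to the
  element (rate 6 rad per half-extent, i.e. wavelength-in-tissue scale at
  ultra-high field) + an independent smooth low-order polynomial ripple per
  channel (0.8 rad scale, zero-referenced at the grid center).  Each
  channel's phase is referenced so the CP mode combines coherently at the
  center.  The overall scale puts the CP-mode |B1+| at the center at
  30 nT/V (head-coil order; configurable).
- The parameters were chosen to reproduce two study-defining properties of
  real ultra-high-field heads: the CP mode excites with ~35–40% FA NRMSE
  against a uniform target (severe center brightening), *and* the
  inhomogeneity is compensable by pTx (static MLS shim ≈ 20–25%, 3 kT-points
  ≈ 7%, free joint optimization ≈ 3–5% on 16 channels).  Per-channel field
  diversity is essential for the second property; a generator whose channels
  share one radial envelope produces maps no pulse can homogenize.
- **B0 map**: random low-order polynomial normalized to a ±300 Hz peak
  (configurable) over the mask.
- **VOPs**: random Hermitian PSD matrices `G Gᴴ` rescaled to a top
  eigenvalue of 2·10⁻³ W/kg/V², set so that a CP-mode pulse scaled to a 10°
  mean FA deposits ≈ 1 W/kg at a 520 µs / 19.7 ms duty cycle — the measured
  order for real head arrays.

What the phantom does *not* emulate: electromagnetic field physics (no
Maxwell consistency between magnitude and phase), tissue-dependent B0
structure (air/tissue interfaces), coil coupling, and any relation between
the synthetic VOPs and the synthetic B1 maps (in reality both derive from
the same fields).  Passing tests therefore demonstrate correctness of the
models and optimizer and *plausible* design behavior, not performance
figures transferable to a specific coil.

## Numerical choices

- Rotation-axis normalization guards `sqrt(· + 1e−60)`; hinge and magnitude
  guards use `1e−30`–`1e−300` epsilons inside square roots so subgradients at
  zero are finite; all are far below physical scales.
- STA FA is `|m_xy|` in radians (M0-normalized); Bloch FA is
  `atan2(|m_xy|, m_z)`.  Near 90° these definitions differ; both are exposed.
- `scale_pulse_to_mean_fa` is closed-form under STA and a bracketing
  bisection (1e−4 deg tolerance) under Bloch.
- Degenerate inputs fail loudly: non-finite cost aborts naming the term;
  infeasible blips, duty cycles > 1, geometry mismatches and malformed
  containers raise structured errors.

## Problem sizes used in the checked experiments

The test suite and `scripts/acceptance.py` run desk-scale versions of the
full-size experiments: the headline non-selective design uses 16-channel
32³ maps (7 mm voxels, ~12.6k masked voxels) with 500 STA iterations — about
45 s on one CPU — where it satisfies all hardware limits exactly and reaches
≈ 3× lower Bloch NRMSE than the CP-mode pulse at the same mean FA.  The
kT-versus-free comparison uses 16-channel 16³ maps, 200 kT candidates and
1500 free iterations (free ≈ 5.0% vs kT ≈ 6.8%).  Unit fixtures are 8
channels at 12³.  Larger grids and the full iteration budgets (7500 + 2500)
change runtimes, not code paths.

## Known limitations

- The optimizer is first-order; no line search or quasi-Newton options.
- Single isotropic-resolution grids; no multi-resolution design.
- The ini pulse dialect is this package's own documented format; vendor
  formats need a converter.
- No GPU path: the autodiff engine is NumPy-bound, adequate for the
  desk-scale problems above (tailored designs in seconds to minutes) but
  slower than GPU tensor frameworks for 64³ multi-subject runs.
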