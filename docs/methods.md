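# Methods

## Model and assumptions

The package implements a deterministic, well-mixed (non-spatial) ODE
model of one gut epithelial cell's inflammatory state coupled to
butyrate. The inflammatory core (N, R, T, L) is a coarse-grained NF-κB
signalling loop: cytokines activate nuclear NF-κB import through a
cubic Hill term with threshold `k_s`; NF-κB drives both its own
repressors (linearly) and cytokine production (quadratic Hill,
threshold `k_n`); within-cell LPS activates cytokines linearly. The
`(1−N)` recruitment factor and the `N/(N+k_r)` saturation bound N to
[0, 1] dynamically, so no projection or clamping is applied during
integration — state validation only rejects inadmissible initial
conditions. Butyrate enters by a transporter (repressed by cytokines,
quadratic Hill with threshold `k_bt`) and by passive diffusion
`k_d·k_Bo`, decays linearly at rate `k_B`, blocks nuclear NF-κB import
linearly (`k_bn`), and throttles LPS influx (quadratic Hill, threshold
`k_lb`). Second-order Hill exponents encode plausible cooperativity;
the exact exponents are modelling choices, not fitted quantities.

Interpretation of the two drives: `k_Bo` is the lumen butyrate level
(set by microbial fibre fermentation), `k_bl` the lumen LPS supply (set
by the abundance of LPS-carrying bacteria). Both are treated as
constant parameters, or piecewise-constant in pulse experiments.

The `extended` variant multiplies the transporter term by
`B²/(B²+k_2B²)`, a cooperative gain representing butyrate → mucin →
SCFA-producer feedback. `k_2B` has no published value; the default 5.0
places the half-saturation just below the inflamed-state butyrate level
so the feedback differentiates the two states visibly. The effect of
any `k_2B > 0` is to weaken butyrate inflow at low B much more than at
high B, which (a) widens the bistable `k_Bo` interval — the property
the extended model exists to show — and (b) shifts both folds to
slightly larger `k_Bo`. A strict nesting of the core interval inside
the extended one is *not* attainable: the extra factor is < 1
everywhere, so the upper layer is always weakened and its terminal fold
can only move up. The package therefore asserts widening, not nesting.

## Parameters

The `fig2a` preset carries the published constants
(k_a=12, k_s=1.0, k_ai=5, k_r=0.5, k_bn=4.7, k_b=5, k_br=0.5, k_n=0.2,
k_p=7, k_t=0.2, k_tl=2.8, k_bl=1.02, k_lb=3.4, k_l=0.7, k_bt=2.1,
k_d=0.125, k_B=2.9) with `k_Bo=130` as the reference operating point.
All constants are nonnegative; those appearing in denominators or as
decay rates (`k_s, k_r, k_n, k_br, k_t, k_l, k_B, k_bt, k_lb, k_2B`)
must be strictly positive. Parameter objects are immutable; every
analysis takes an explicit parameter set.

## Equilibria

`find_fixed_points` runs damped Newton (backtracking line search on the
residual norm, analytic Jacobian) from a deterministic multistart grid:
N ∈ {0.001, 0.01, 0.1, 0.5, 0.9}, the other components log-spaced over
[1e−4, 1e4] with 4 points per axis. Duplicates merge at relative 1e−6;
results sort by B. Residuals are scaled per component by
max(1, |x_i|) because the two stable states span four orders of
magnitude (non-inflamed N ≈ 2·10⁻⁵ vs. T ≈ 20 inflamed); a reported
equilibrium must have scaled residual ≤ 1e−9. Stability is read from
the eigenvalues of the analytic Jacobian with a dead band of 1e−8 on
real parts; anything inside the band is "marginal" (as at a fold).

The trapping-box checks mirror the analytical existence argument: on
the box 0 ≤ N ≤ 1, 0 ≤ L ≤ k_bl/k_l + δ, 0 ≤ R, T, B ≤ K (defaults
δ=1, K=10⁴, chosen comfortably above every equilibrium value; ε=10⁻⁴
for the origin ball) the flow is verified to point inward at sampled
face points, and the LPS/butyrate inflows are verified strictly
positive throughout the origin ball, so no equilibrium sits there and
at least one must exist inside the box.

## Continuation and folds

`trace_branch` is a pseudo-arclength predictor–corrector in the
extended space (state, parameter): tangents come from a bordered linear
solve against the previous tangent, the corrector is Newton constrained
orthogonal to the predictor, and the step adapts between 1e−3 and 5
(initial 0.5, growth 1.3 on fast convergence, halving on failure).
Sweeps start from every equilibrium found at each end of the requested
range and run inward; sweeps whose start already lies on a traced piece
are skipped, which covers disconnected layers (the inflamed branch of
the lumen-LPS continuation never connects to the healthy one for
`k_bl ≥ 0`). A sweep leaving the range is clamped back onto the range
boundary by a fixed-parameter Newton solve; the same clamp handles
branches terminating against the `k_bl ≥ 0` constraint.

Folds are flagged by a sign change of the parameter component of the
unit tangent and refined by Newton on the bordered system
{f = 0, Jq = 0, ⟨q,q⟩ = 1} in (x, α, q), with analytic J and
finite-difference second-order blocks, to residual 1e−10. The left
null vector p is normalized by ⟨p,q⟩ = 1 and the quadratic coefficient
`a = ½⟨p, B₂(q,q)⟩` is evaluated with a central second difference along
q (step 1e−3·(1+‖x‖), giving ~6 significant digits here).

Sign convention: `a` flips with q → −q, so a convention is required.
q is oriented from the fold toward the adjoining *stable* branch
segment; under the one-dimensional reduction ẏ = bβ + ay² the
attracting equilibrium then lies at a·y < 0, so `a < 0` states exactly
that the colliding branch pair forms the stable/unstable edge of an
attracting hysteresis layer — both folds of the drive hysteresis carry
`a < 0`. (Orienting q by a fixed coordinate sign instead, e.g. positive
B component, flips the sign at the right fold while leaving the
magnitude unchanged.) Eigenvalues are monitored along the branch for
complex pairs crossing the imaginary axis; no such Hopf candidate
occurs for the default parameters.

For the published parameter set the folds land at k_Bo = 59.169 and
200.117 with a = −0.1079153 and −0.0111470. Note the narrative
thresholds "≈55" and "≈200" are coarser than the computed fold
locations; the normal-form coefficients, which are sensitive to every
constant, agree with the published ones to six digits, pinning the
implementation to the same vector field.

## Time integration and pulse experiments

`simulate` uses LSODA (stiff-capable, analytic Jacobian) at rtol 1e−8 /
atol 1e−10, restarted at every drive discontinuity so pulse edges stay
sharp, with dense output on a 1-time-unit reporting grid. Endpoint
classification against candidate attractors uses relative tolerance
1e−2 with absolute floor 1e−6 (the non-inflamed N is ~2·10⁻⁵).

A caveat discovered during verification: the nominal switching protocol
(baseline 130, high pulse 200 on t ∈ [50, 170], low pulse 50 on
t ∈ [200, 270]) has its high amplitude 0.06% *below* the computed fold
of the inflamed branch at k_Bo = 200.117. At drive 200.0 the inflamed
equilibrium still exists (B = 12.86) and attracts the pulsed
trajectory, so under tight tolerances this protocol does not switch;
amplitudes barely past the fold (≤ 201) escape too slowly for the
120-unit pulse because of the saddle-node ghost. The package therefore
ships two protocols: the nominal one, and an `above_fold` variant with
high amplitude 205 that completes the two-way switch comfortably. The
reproduce driver runs and reports both. The qualitative conclusion —
lumen butyrate pulses can switch the cell both ways, lumen LPS only one
way — is unaffected.

## Density transform

The hysteresis layers are interpolated per layer by monotone cubic
(PCHIP) splines B = h(k_Bo); monotonicity of each stable layer is
checked and violations raise. The transformed density is evaluated on
a common y-grid through the inverse spline,
q(y) = w·p(h⁻¹(y))/|h′(h⁻¹(y))|, with |h′| in the quotient (the
change-of-variables Jacobian). Around the fold that *terminates* a
layer — where h′ diverges and occupation is dynamically unstable — a
parameter window of ±1% of the fold location is excluded and its input
mass reported as excluded rather than redistributed; a layer passing
the other fold's parameter value smoothly keeps its mass there.
Layer weights default to ½/½ (no data exists to fit occupation
probabilities; they are configurable). The input is Gaussian with
default mean 130 and sd 40, centred on the operating point and wide
enough to straddle both folds so that both layers carry mass.

Verification is by construction oracles (identity and linear layer maps
transform exactly), mass bookkeeping (the y-integral of q matches the
retained input mass to < 1e−3), a 10⁵-draw Monte-Carlo push-through
histogram (total variation ≤ 0.03), and refinement convergence (halving
the continuation step changes q by < 1e−3 sup-norm).

## Problem sizes and determinism

Default analysis sizes: 1280-start Newton grids for equilibrium
searches, branch traces of ~150 accepted points over k_Bo ∈ [10, 300],
50-trajectory invariance sweeps, 200 samples per box face, 10⁵
Monte-Carlo draws, 2000-point density grids. Equilibria, branches,
folds and transforms are fully deterministic; only the sampling checks
(box faces, Monte Carlo) consume a seed.

## Known limitations

- No spatial structure, no stochastic kinetics, no unit calibration to
  physiological concentrations: conclusions are qualitative switch
  properties, not concentration predictions.
- The multistart grid is a heuristic global search; equilibria far
  outside [1e−4, 1e4] or at extremely small basins of Newton
  convergence could in principle be missed (none are known for this
  model over the scanned drive ranges).
- Continuation handles folds but not codimension-2 points, limit-cycle
  branches, or parameter ranges requiring more than the two-end restart
  strategy for coverage.
- The base (butyrate-free) variant with `k_bl > 0` has no equilibrium
  at the origin (its LPS equation forces L = k_bl/k_l > 0), so
  origin-fixedness claims inherited from the ancestor inflammation
  model are not asserted for it.
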