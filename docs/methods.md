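# Methods

## Models

All models are chemical reaction networks over a subset of the species
(Y1, Y2, X, U1, U2, X′, U1′, U2′), expressed as a list of typed rate terms
(Hill production, catalytic production, linear decay, pairwise sequestration,
additive control, saturated-degradation control). Mass-action/Hill kinetics
give the ODEs; the same term list maps one-to-one onto stochastic reaction
channels, and the identity Σ stoichiometry × propensity ≡ ODE right-hand side
is enforced by tests on random states. Units are μM and hours throughout.

Hill regulation is K^m/(K^m + y^m) (repression) or y^m/(K^m + y^m)
(activation) with a single Hill constant K shared by all regulatory edges of
a model. Nominal parameter sets: toggle switch and mutual activation
α = 2.2 μM/h, K = 1 μM, m = 3, δ = 1 /h; toggle with double self-activation
α = 1.2 μM/h, K = 0.5 μM, m = 4, δ = 1 /h; controller ξ = θ = 1 μM/h,
k = 1 /h, β = 1 /h, γ = 100 /μM/h. The Michaelis constant of the
saturated-degradation actuation −β·u·y/(y+K_deg) defaults to the Hill
constant K but is exposed as a separate field (`K_deg`), since nothing forces
the degradation operating point to coincide with the regulatory one.
Mirrored double controllers share (ξ, θ, k, γ, δ) and differ only in their
gains β, β′; scan drivers tie β′ = β unless overridden. Cooperativity m = 0
is rejected rather than reinterpreted.

Controller architecture is a small configuration object: which endogenous
species is sensed and through which Hill sign, which controller species
(U1 or U2) actuates, additive versus saturated-degradation actuation, and the
target. Sensing the target of a target-raising actuation closes a negative
feedback loop; sensing the opposing species closes a positive one. The
positive-feedback variant of the controlled mutual-activation motif is built
by mirror analogy with the negative one (activating sensing of Y2 instead of
Y1), as is the U2-input family.

## Deterministic and stochastic simulation

ODEs are integrated with scipy's LSODA at rtol 1e-8 / atol 1e-10 on a
2000-point output grid; basin boundaries of the bistable systems are
sensitive, which is why the defaults are tight. Small negative excursions
are clipped before term evaluation; forward invariance of the nonnegative
orthant holds because every removal term vanishes with its species.

Stochastic trajectories use the exact direct-method Gillespie algorithm,
compiled with numba. Concentration-scale rates are converted to count-scale
propensities at system size Ω (molecules per μM): a zeroth-order channel with
concentration rate f(c) has propensity Ω·f(n/Ω), first-order channels are
unchanged, the sequestration channel scales as γ·n₁·n₂/Ω, and the
Michaelis–Menten channel as β·n_u·n_y/(n_y + Ω·K). Identical seeds give
bit-identical event sequences; ensembles derive per-run seeds from a master
seed via numpy SeedSequence spawning, so any subset of runs is reproducible.
A zero total propensity is an absorbing state held to the horizon, not an
error.

## Equilibria and nullclines

Controlled systems are reduced to the endogenous (y1, y2) plane by
eliminating each controller at quasi-steady state: with sensing value
p ∈ [0, 1], x̄ = θp/δ, and with d = p(kθ − ξδ)/δ², ū₁ is the positive root
of γu² + (δ − γd)u − kθp/δ = 0, ū₂ = ū₁ − d (linear fallback at γ = 0).
At r = 1 this gives ū₁ = (−δ + √(δ² + 4γkθp/δ))/(2γ) ~ √(kθp/(δγ)), which is
the γ^(−1/2) residual actuation responsible for the equilibrium alteration
scaling verified in the tests.

Equilibria are found by seeding a 60×60 lattice over the search box
[0, 1.5·(max production + additive control bound)/δ]² and running a damped
Newton iteration on the reduced map (vectorised over all seeds; forward
finite differences keep evaluations inside the orthant; steps capped at 10%
of the box). Converged roots (residual < 1e-10) are deduplicated at 1e-4 μM,
lifted to the full state through the QSS expressions, polished by a full-state
root solve, and classified by the eigenvalues of the full-system Jacobian
(central differences, relative step 1e-6). Labels: stable (all real parts
< −1e-6), saddle (mixed), unstable (all > 1e-6), marginal otherwise
(excluded from stability counts). An independent brute-force oracle —
sign-change cells of both reduced nullclines on a 400×400 lattice polished by
scipy's hybr solver — must reproduce the census for every model variant; this
guards against both missed and spurious roots, including near saddle-node
folds. Nullclines are sampled per grid column by sign-scan bracketing and
bisection to 1e-10; columns without roots are omitted so disconnected
branches appear naturally.

Across parameter scans, stable branches are matched by nearest-neighbour
continuation from the previous grid point. The **equilibrium alteration** of
a controlled system against its uncontrolled baseline is the largest
coordinate shift of a matched stable equilibrium, normalised by the dominant
(largest) coordinate of the reference equilibrium. Normalising by the
dominant coordinate rather than per-species keeps the measure meaningful at
strongly asymmetric attractors, where the silenced gene's own value is near
zero: a shift of 0.17 μM on a (0.19, 2.18) μM equilibrium reads as ~8% of the
attractor's expression scale, not as an alarming 90% of the silenced gene's
level. The per-species percentage is also available (`alteration_percent`)
for single-coordinate questions such as the γ-scaling law. Bistable ratio
windows are reported on the 0.1-step ratio grid as the maximal contiguous
bistable interval containing ratio 1, which makes the printed endpoints
well-posed.

## Fast-sequestration approximation

The γ → ∞ output limit is realised in the time domain as a two-state filter
cascade (ż₁ = −δz₁ + y, ż₂ = −δz₂ + z₁) with output max{0, kθ·z₂ − ξ·z₁},
algebraically identical to the transfer function [kθ − ξ(s+δ)]/(s+δ)² with
the clip applied pointwise outside the inverse transform. No symbolic Laplace
inversion happens at runtime; equivalence with the convolution representation
(kernels t·e^(−δt) and e^(−δt)) is a test, not an implementation path. A
consequence worth stating explicitly: for a *rising* input at r = 1 the
direct (U2) path leads the delayed (X→U1) path, the pre-clip value is
negative, and the clipped output is zero; the controller fires on *falling*
inputs and adapts to zero for any input that settles. In the closed loop the
sensed signal is a repressing Hill function of a rising gene, i.e. a falling
input, which is exactly when the output is active.

## Fate assays and the system-size caveat

Fates are assigned at a fixed horizon (200 h) by nearest stable attractor in
the endogenous plane, with a 5% relative tie rule producing an explicit
"unresolved" bucket rather than silent misassignment; SSA counts are
converted back to concentrations (÷Ω) before classification. Distributions
report per-attractor fractions (summing to 1 including unresolved), an
8-bin histogram of a chosen species over [0, observed max], and a bias index
(target fraction minus the best competitor). Convergence *probabilities*
quoted in examples and the acceptance script are fractions of resolved
trajectories.

The count↔concentration conversion Ω is a genuine free parameter of the
stochastic layer: nothing in the deterministic model pins it. Its effect is
large. At Ω = 1 (concentrations read directly as counts) the high attractor
holds only ~2 molecules, trajectories hop basins up to the horizon, ~14% of
uncontrolled endpoints land on the integer diagonal and are unresolved, and
the controller's bias is mostly washed out (~55–60% instead of 80%).
At moderate sizes (Ω ≈ 20–100, copy numbers ~40–200) endpoints resolve
cleanly and the negative-feedback architecture produces its characteristic
strong bias with the positive-feedback one trailing. The package default is
Ω = 1 (the most literal reading of running the μM-parameterised equations as
a CRN), the stochastic property tests and examples use Ω = 50, and Ω is an
explicit argument everywhere; quantitative fate percentages should always be
read together with the Ω they were computed at. This is the main respect in
which passing tests here do not certify behaviour of a wet-lab system, whose
effective copy numbers are set by cell volume and are typically in the
hundreds or more.

## Synthetic data

There is no external data: every input is generated by the simulators at the
parameter sets above. What the generator emulates is intrinsic reaction noise
(exact SSA) on top of the literature-derived kinetic skeleton; what it does
not emulate are extrinsic noise, cell division/growth dilution, parameter
heterogeneity across cells, and transcription-translation delays — all of
which would broaden the fate distributions of a real population.

## Known limitations

- Near saddle-node folds the equilibrium census is exact but alteration
  measures blow up smoothly; robustness-window endpoints are grid-resolution
  statements (0.1 in ratio), not fold locations.
- The nullcline/QSS reduction assumes controller states equilibrate given
  frozen (y1, y2); at the default γ = 100 the full-system simulations land on
  the reduced equilibria to < 1e-3 μM (tested), but for very small γ the
  reduction degrades.
- No tau-leaping or hybrid acceleration: very large Ω ensembles are
  correspondingly slow.
- No pseudo-arclength continuation or formal bifurcation classification;
  count changes along grids are the bifurcation signal.
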