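# Methods

`mbam` implements manifold-boundary model reduction for deterministic ODE
models of biochemical kinetics.  This note records the model conventions,
the numerical choices, and the limits of what the bundled examples and
tests demonstrate.

## The model manifold and its metric

A model with log-parameters θ = log k predicts M quantities of interest
(QoIs): an observable at a set of times under an input protocol, each with
a tolerance σ_m.  The scaled prediction vector r_m(θ) = y_m(θ)/σ_m sweeps
out an N-dimensional surface in R^M — the model manifold.  Its Riemannian
metric is the Fisher Information Matrix

    g = Jᵀ J,     J_{mμ} = ∂r_m/∂θ_μ ,

computed by central finite differences with a single absolute step
h = 10⁻⁴ (Jacobians) in log-parameter units; the log transform is what
makes one absolute step meaningful across parameters of different units.
A forward-sensitivity ODE (state augmented with ∂x/∂θ) provides an
independent Jacobian for smooth models and is used as a cross-check, never
as the default.  Eigenvectors are oriented so that the largest-magnitude
component is positive, ties broken toward the lowest parameter index, which
makes repeated decompositions (including degenerate ones) deterministic.

## Geodesics and boundary detection

Reduction follows a geodesic launched along the eigenvector of the
smallest FIM eigenvalue,

    d²θ/dτ² = − g⁻¹ Jᵀ A(v),   A_m(v) = vᵀ (∇∇ r_m) v ,

with A(v) estimated by the symmetric stencil
(r(θ+hv̂) + r(θ−hv̂) − 2r(θ))/h² · |v|², h = 0.02.  The sign of the
acceleration term matters: with it, the Fisher-metric speed √(vᵀgv) is a
first integral, and the bundled boundary runs conserve it to better than
0.1% (a property test enforces this).  The metric inverse uses a
pseudo-inverse with relative cutoff 10⁻¹² so near-singular metrics at the
end of a path do not abort the run.

Two initial-speed normalizations are available.  With `fisher`
normalization the initial velocity has unit Fisher speed and τ measures
information distance; this requires a numerically nondegenerate metric
(smallest/largest eigenvalue above 10⁻¹⁰) and raises otherwise.  With
`parameter` normalization the initial velocity is a unit vector in
log-parameter space; this is the workhorse for deeply sloppy models whose
spectra span ten or more decades, where unit Fisher speed would demand
initial parameter velocities of 10⁴–10⁶.

A boundary is declared when the smallest eigenvalue collapses below
ε_λ = 10⁻³ times the next one.  When the starting ratio is *already* below
ε_λ (a common situation for sloppy models), the criterion becomes
relative: a further collapse by the same factor below the starting ratio.
Two additional terminations: parameter-velocity growth by 25× over its
initial norm, and a maximum τ (default 10).  A "gravitational slingshot"
guard flags paths whose smallest eigenvalue re-grows persistently after a
deep minimum — the geodesic has bent away from the boundary and should be
restarted from a nearby point or another sloppy direction.  The direction
sign is chosen by integrating a short trial segment both ways and keeping
the sign along which the velocity norm grows (an explicit override
exists).

The final unit velocity classifies the limit: components above 0.2 in
magnitude are read as log-parameters running to +∞ (positive) or to 0
(negative).

## Limit rules

Limits are evaluated by a curated, extensible registry rather than general
symbolic algebra.  Enzyme-kinetics rules: rapid equilibrium
(k_f, k_r → ∞ with K_d = k_r/k_f), irreversible binding (k_r → 0), and
quasi-steady state (k_f, k_c → ∞, E₀ → 0 with V_max = k_c E₀ and
K_M = k_c/k_f).  For the three-node regulatory motifs, models are held in
a structured term language (each term = sign · monomial coefficient ·
drivers · kinetic form), on which the rules are local rewrites:

* linearize a saturating term (its k and K → ∞ together, k/K finite);
* delete a vanishing reaction (a lumped rate → 0);
* harden a saturating activation into a Heaviside gate (K → 0);
* renormalize a buffer node whose absolute scale decouples (production
  and decay rates → 0 while the consumer's sensitivity → ∞; the product
  b̃ = s·b stays finite), in variants with Michaelis–Menten decay, linear
  decay, or no decay;
* rescale a buffer by a diverging Michaelis constant of its consumer;
* collapse an instantly saturating input node (its rate → ∞; downstream
  terms sense the stimulus directly).

Every new lumped parameter records its provenance as a monomial in the
original parameters, so a reduced model's parameters can always be read as
combinations of microscopic constants.

The iterated loop (spectrum → geodesic → limit → recalibration) accepts a
step only if the recalibrated reduced model reproduces its parent's QoIs
within the σ band (cost ≤ M, the operational meaning of "statistically
indistinguishable"); at a corner where several boundary faces meet, the
candidate faces are tried in order of their final-velocity components
until one passes.  The loop stops when all FIM eigenvalues exceed
λ* = 1 — in log-parameter space this is a standard relative parameter
error of a factor e — or on a target parameter count, or when no rule
matches.

Recalibration minimizes Σ_m ((y_m^parent − ỹ_m(φ))/σ_m)² by
Levenberg–Marquardt from the rule's analytic guess, with three seeded
jittered restarts as a fallback.

## Saturated (Heaviside-gated) states

Production terms rate·Θ(1−x) use the convention Θ(0) = 0.  Integration
uses event detection: when a gated state reaches its cap with positive net
production it slides along the cap (derivative pinned to zero) until the
ungated right-hand side turns negative — the Filippov solution of the
discontinuous system.  Between events the right-hand side is kept smooth
(free states never see the gate; the event stops integration exactly at
the crossing), which implicit solvers require.  On release the state
restarts a hair inside the cap so the solver never sits on the
discontinuity.  For finite-difference batches, if the reference trajectory
stays below 97% of every cap the gates are provably inert across the batch
and all parameter copies are integrated as one stacked smooth system; this
is what keeps Jacobians of gated models affordable.

## Bundled models and study conditions

The enzyme family (mass action E+S ⇌ C → E+P with E₀ = 0.25, S₀ = 1 and
reference log-rates (1, ½, 3/2)) uses QoIs [P]/S₀ at t = 5, 10, 15 with
σ = 1 for the spectrum demonstration.  At this reference point the
predictions (0.861, 0.987, 0.999) are nearly saturated, so the
three-point metric is numerically rank-one: the two sloppy eigenvalues
(2.3·10⁻⁵ and 2.9·10⁻¹²) are respectively 4×10³ and 3×10¹⁰ below the
stiffest.  Geodesic (boundary) runs therefore use the same observable on
the denser grid t = 1 … 15 (M = 15, σ = 1), on which the metric is
nondegenerate enough for unit-Fisher-speed integration.  Even so the
information distance from the reference point to either boundary face is
small: both the rapid-equilibrium and the irreversible-binding reduced
models pass within ~10⁻⁴ of the reference predictions, and the boundary
is detected at τ* ≈ 0.009 (equilibrium face, +direction; final velocity
→ (0.71, 0.70, −0.06), i.e. k_f, k_r → ∞ with log K_d finite) and
τ* ≈ 0.0015 (irreversibility face, −direction, k_r → 0).

For the promoted chain (E₀, S₀ as parameters) the fractional observable
[P]/S₀ has an exact scale invariance — E₀, S₀ → cE₀, cS₀ with
k_f → k_f/c leaves it unchanged — which makes the five-parameter FIM
exactly rank-deficient for any time grid.  The promoted chain therefore
observes the absolute product concentration [P] on t = 1 … 15.  Its
spectrum still spans ten decades, so these geodesics run with
parameter-unit normalization and the relative collapse criterion.  Under
these conventions the chain reproduces the classical sequence
mechanically: first boundary k_r → 0; after recalibration the second
geodesic terminates at τ* ≈ 1.56 with velocity (0.61, 0.53, −0.59, 0.0)
on (k_f, k_c, E₀, S₀) — the quasi-steady-state limit — and the final
model is d[P]/dt = V_max[S]/(K_M+[S]).

The adaptation motifs use external inhibitions F_A = F_B = 0.5, a step
input of magnitude 0.5 at t = 0 from all-zero initial conditions, and
log-uniform fixture sampling over [10⁻², 10²] for the twelve rate and
Michaelis constants, accepted when the step response shows a transient
peak of at least 0.1·I with a settled final offset of at most 20% of the
peak.  QoIs are the output node at 20 evenly spaced times spanning ten
times the time-to-peak, with σ = 0.1 × peak.

## What the bundled examples do and do not show

* The canonical 12→4→2 reduction sequences for both motifs are shipped as
  replayable rule chains.  Replaying them at the seed-0 adaptive fixture
  reproduces the reduced model structures exactly — with lumped parameters
  k_IA, k_CB k_BC/(K_CB K_BC), k_FB/K_FB, k_AC (feedback) and k_IA, k_AB,
  k_AC, k_BC/K_BC (feed-forward) — and every recalibration stays within
  the σ band.
* The geodesic-driven loop at the same fixture takes a different,
  regime-appropriate route: the sampled adaptive point has a
  non-saturating input node (A* ≈ 0.3), so the geodesics linearize the
  input activation instead of hardening it into a gate.  The feedback
  motif terminates fully identifiable at a three-parameter form
  {k_FA/K_FA, k_AC k_IA/K_IA, k_BC k_CB/(K_BC K_CB)}; the feed-forward
  run executes three valid limits and then halts at a buffer
  quasi-steady-state boundary outside the curated registry.  Which
  combinations are identifiable is a property of the regime, not only of
  the topology; user-supplied rules can extend the registry for such
  boundaries.
* The two-parameter adaptation models are characterized by the single
  dimensionless invariant τ (ratio of the initial-response rate to the
  square root of the feedback accumulation rate); the τ-collapse property
  (equal-τ parameter sets superimpose after time rescaling) is verified to
  10⁻⁴.  On the sweep grid the canonical response (k_AC = 1, I = 1) has a
  peak height that increases with τ and saturates at the output cap from
  τ ≈ 1; precision and sensitivity trade off between the mechanisms
  exactly as the steady-state formulas predict.
* Closed forms are re-derived rather than transcribed: dimensional
  analysis of the two-parameter dynamics fixes
  τ_NFBLB = k_AC I √(K_CB K_BC/(k_CB k_BC)),
  τ_IFFLP = k_AC √(I K_BC/(k_AB k_BC)), τ_EGF = θ₁/√θ₂ (stimulus
  normalized to 1, giving 1.576 ≈ 1.6 at the bundled reference values),
  and the feedback steady states C* = √(k_AC F_B (k_FB/K_FB) K_CB K_BC /
  (k_CB k_BC)), B̃* = k_AC/C* (valid while C* ≤ 1).

Synthetic-data caveats: the generator emulates deterministic step
responses of small, well-mixed motifs with fixed external inhibitions; it
does not emulate cell-to-cell variability, stochastic kinetics,
measurement drift, or non-step stimuli, so passing tests say nothing
about those features of real data.

## Known limitations

* Stochastic kinetics are out of scope throughout.
* The registry covers the bundled families; unfamiliar limits halt the
  loop with the classified descriptor so a user rule can be added.
* Forward sensitivities are restricted to smooth (ungated) models.
* The SBML importer reads the Level 2/3 core subset (species, parameters,
  reactions with content-MathML kinetic laws, assignment rules) and
  rejects events, rate/algebraic rules, function definitions and
  piecewise kinetics.
* Several printed reference numbers of the enzyme demonstration could not
  be verified from their stated setup under any convention tested (the
  smallest-eigenvalue eigenvector reported as (0.84, −0.23, 0.49) is, to
  two decimals, the *largest*-eigenvalue eigenvector of the verified FIM
  and is orthogonal to the entire sloppy subspace; the reported boundary
  distances τ ≈ 0.35/0.45 are two orders larger than the information
  distance from the stated reference point to the faces).  The package
  computes these quantities faithfully and the acceptance tests document
  the discrepancy.
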