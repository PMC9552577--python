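# Methods

## The model

A mental representation is a normalized state |Ψ⟩ = Σᵢ aᵢ|ϕᵢ⟩ in a
finite-dimensional complex Hilbert space whose basis vectors are *labeled*:
each label names an interpretation, instance or feature, and the geometry
is entirely carried by label identity (distinct labels are orthonormal).
This "complete orthonormal feature" assumption means features are treated
as mutually exclusive; context projection is exact under it and only
approximate where real features overlap. Amplitudes are stored complex
throughout; constructors accept real weights as a convenience.

Operations on representations:

* **Typicality** of instance |a⟩ in concept |A⟩ is |⟨A|a⟩| — the amplitude
  magnitude on that label.
* **Elaboration** (incorporating new information |A⟩):
  Û_A|Ψ⟩ = |Ψ⟩ + c·|A⟩⟨A|Ψ⟩. The operator is deliberately non-unitary; the
  right-hand side is renormalized by default, with the raw form available
  for display. The strength c defaults to 1 (a single application).
  Because (|A⟩⟨A|)² = |A⟩⟨A|, applying Û_A n times equals a single
  application with c = 2ⁿ − 1, so c > 1 models *sustained* elaboration —
  dwelling on one piece of information until it reshapes the
  representation. A single pass can shift at most a modest fraction of
  amplitude mass (the addition is bounded by the overlap ⟨A|Ψ⟩), which is
  why redescription-like steps in the case study use c > 1.
* **Unintegrated combination**: when |⟨A|Ψ⟩| is negligible (threshold
  ε = 0.05 by default — the formalism gives no cutoff, so one had to be
  chosen), the new fact cannot be elaborated in and is held as the tensor
  product |Ψ⟩⊗|A⟩. The product is separable by construction; callers may
  impose non-factorizing joint amplitudes to model entanglement.
  Separability is decided by the Schmidt criterion — the joint amplitude
  matrix is separable iff its second singular value is ≤ 10⁻⁶ of the first
  — which is the phase-robust operational form of aᵢⱼ = aᵢᴬaⱼᴮ.
* **Context / question application**: a projector Ĉ = Σᵢ wᵢ|i⟩⟨i| onto the
  goal-relevant labels (weights default to 1). Annihilation (a state with
  no support in the context) is an error, not a silent zero.
* **Compact vs expanded form**: the compact form keeps the smallest
  salience-ordered prefix of labels reaching a squared-mass threshold and
  renormalizes; ties in salience break lexicographically so compact forms
  are deterministic. The expanded form is the full superposition.
* **Cross-concept projection**: Σᵢⱼ pᵢeⱼ⟨j|i⟩|j⟩ projects one concept's
  superposition through another's. Cross-basis inner products ⟨j|i⟩ default
  to the Kronecker delta on literal label equality and can be overridden by
  an explicit correspondence table, since nothing in the formalism fixes
  the geometry between two different concept bases.
* **Measurement** is projective in the label basis with Born probabilities
  |aᵢ|², seeded explicitly per call (no hidden global RNG state).
  Arbitrary Hermitian-observable eigendecomposition is deliberately not
  exposed: questions are always modeled as projections onto labeled answer
  subspaces.
* **Two-part questions** on a joint state use Ô = Ô_s ⊗ Ô_d with both
  factors projectors. The answer distribution is the Born distribution over
  answer-label pairs conditioned on the answer subspaces. The caller
  declares which answer pairs are contradictory; if the two conditional
  marginals jointly place ≥ 0.5 of their mass on contradictory pairs
  (majority mass ≈ "cannot answer"), the question is flagged incompatible.

## The three measures

All three are expectation values on the *same* state under a fixed
description of the environment and are dimensionless, in [0, 1] except γ_D:

* **Abstractness** γ_A = 1 − ⟨ψ|α̂|ψ⟩, with α̂ the projector onto the
  observation labels {|Oₙ⟩}. The raw expectation ⟨α̂⟩ measures groundedness
  in direct observation; the *reported* value is its complement so that a
  shift away from observations registers as an increase in abstractness.
  Both are exposed (`abstractness`, `observation_groundedness`).
* **Divergence** γ_D = √(⟨B̂²⟩ − ⟨B̂⟩²), the standard deviation of thought
  over the salient-feature observable B̂. With B̂ a projector onto a salient
  subset this is √(p(1−p)) ≤ ½, p the salient mass — note a projector onto
  the *complete* basis is the identity and makes γ_D vanish identically, so
  a meaningful B̂ must project onto a proper subset. A weighted mode
  (diagonal B̂ with arbitrary real eigenvalues) supports richer spread
  measures. Degenerate negative variances beyond −10⁻¹² raise an error.
* **Context-specificity** γ_C = ⟨ψ|Ĉ|ψ⟩, the overlap with the context
  subspace, exactly as defined; the complement 1 − γ_C ("how much the
  context would change thought") is exposed separately rather than guessing
  which gloss was intended.

The three are mathematically independent: in a 4-label basis with
observations {w,x}, salient set {w,y} and context {w,z}, the four masses
(summing to 1) are in bijection with (γ_A, p, γ_C), so each measure can be
dialed while the other two stay fixed to machine precision. The test suite
and acceptance script construct exactly these families. All measures are
invariant under global phase and label permutation.

Profile changes are quantized to arrows (↑, ↓, −) with a per-dimension
tolerance of 0.05, chosen because the case-study tables are qualitative;
the numeric deltas are always available alongside.

## The Earth-shape case study

Two children's trajectories from no Earth model to a Spherical-Earth model
are replayed as ordered operator applications over one 13-label basis
(six observation labels: flat ground, flat horizon, a circle drawing, a toy
ball, a red balloon, redness; seven abstractions: flat, round, hollow,
sphere, planet, Mars, pretend play). The fixed environment takes the six
perceptual labels as the observation set, pretend play
{red balloon, Mars, pretend play} as the goal context, and a projector
B̂ onto the features salient in the children's surroundings and discourse
(ground, horizon, toy ball, the four shape ideas, and Mars).

Child i: observation bundle → elaboration binds it to "flat" → compact
form + roundness → Disk → the sphere idea has negligible overlap with the
compacted Disk (|⟨sphere-info|disk⟩| < 0.05), so it is held as a tensor
product (the Dual model) → a cross-factor shape question returns
contradictory answers (the incompatibility diagnostic is recorded) and the
child redescribes, elaborating the *expanded* Disk form with the sphere
idea → a final play elaboration. Child j: the same formation step → hollow
model by elaborating the expanded Flat form → three social-learning steps
building Mars/planet knowledge → projection of the PLANET concept through
the Earth state (the double-sum comparison) → two concretizing steps →
projection onto the pretend-play context.

The source narrative specifies no numeric amplitudes, only the qualitative
arrow pattern of each step. The fixture amplitudes are therefore a
**calibration, frozen once**: they were chosen so that every arrow cell of
both trajectories reproduces at the default tolerance, and they are
regression-tested at exactly those values. The claims carried by the case
study are the arrow patterns and the structural facts (the Dual state is a
tensor product that cannot answer the cross-factor shape question; both
children end in a Sphere model whose abstractness exceeds the initial Flat
model's; the two children's consolidated Sphere-model profiles agree within
0.05 per dimension), not the amplitude magnitudes.

Two conventions in the trajectories deserve note. First, profiles of a
joint (tensor-product) state are computed with each observable lifted as
M̂ ⊗ Î, i.e. on the reduced state of the primary factor: an unintegrated
appended fact does not participate in thought about the primary concept
until it is redescribed into it. Second, child j's final step is a
pretend-play *projection* of the consolidated Sphere model (γ_C = 1 by
construction), so cross-child end-state comparisons use the state just
before that projection (`CHILD_J_SPHERE_INDEX`); child i's play step is an
ordinary elaboration and leaves its profile essentially unchanged.

The accompanying frequency table (7 mental models × grades 1/3/5, 60
children) ships as a CSV with declared row/column totals; the loader
recomputes all marginals and refuses internally inconsistent tables,
naming the offending row or column. Zero counts are explicit cells.

## Synthetic generator

`synthetic.GeneratorConfig` draws concept spaces for property testing:
squared amplitudes are symmetric-Dirichlet distributed (concentration → 0
gives peaked, convergent-like states; large concentration gives
near-uniform, divergent-like states), phases are zero by default with a
random-phase option to exercise the complex path, contexts are uniform
label subsets, and fuzzing trajectories alternate elaboration, context
application and compaction. Everything is reproducible from
(config, seed); a random context that annihilates the current state is
treated as irrelevant (identity) during fuzzing rather than an error.

What the generator does *not* emulate: human-plausible semantic feature
norms, correlated feature structure, or any learning dynamics for
amplitudes. Passing property tests therefore certify the algebra and the
measures, not psychological fidelity of any particular amplitude
assignment.

## Numerical choices

* Normalization and hermiticity tolerance 10⁻⁹ (double precision leaves
  ample headroom); projector idempotence checked at 10⁻⁸.
* Separability tolerance 10⁻⁶ on the ratio of the second to the first
  singular value.
* Born sampling uses `numpy.random.default_rng(seed)` with one explicit
  integer seed per call.
* Salience ties break lexicographically; compact-form selection stops as
  soon as the cumulative mass reaches the threshold (within 10⁻⁹).
* Expectation values clamp tiny negative round-off to zero; a variance
  below −10⁻¹² is reported as an operator error rather than clamped.

## Problem sizes

The test suite and acceptance script use dimensions 2–13, 500-state oracle
sweeps, 1,000-state separability sweeps, 10,000-draw measurement
simulations, and a few hundred fuzzed trajectories; the full suite runs in
a few seconds on one CPU. These sizes were chosen as comfortably past the
point where the checked identities either hold to machine precision or
fail visibly.

## Known limitations

* Fock-space composites, mixed states/density matrices, continuous
  spaces, and measurement in arbitrary eigenbases are out of scope.
* How entanglement would *arise* dynamically between unintegrated
  representations is not modeled; the package represents and tests such
  states but never generates non-separable joints itself.
* The three measures are not claimed exhaustive, and no fitting to
  human-subject data is provided or implied.
* Cross-basis geometry in concept comparison is user-supplied; the default
  label-identity map is a modeling convenience.
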