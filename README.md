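# mindmodes

A quantum-cognition toolkit for modeling **modes of thought** and
**conceptual change**.

Quantum-cognition models represent an ambiguous mental entity — a word, a
concept, a half-formed idea — as a superposition state |Ψ⟩ = Σᵢ aᵢ|ϕᵢ⟩ over
a labeled orthonormal basis of its possible interpretations, instances and
features. The squared amplitude |aᵢ|² is the Born-rule probability that
thought resolves to interpretation |ϕᵢ⟩ when a question is asked; questions
and goal contexts are Hermitian operators (projectors onto answer- or
goal-relevant subspaces); and two pieces of knowledge that a thinker holds
without integrating them live in a tensor-product space where they may be
entangled. No claim is made that the brain is a quantum system — only the
probabilistic formalism is borrowed.

On top of this algebra, the package computes three expectation-value
measures that characterize *how* someone is thinking, independently of
*what* they are thinking about:

| measure | operator | value |
|---|---|---|
| abstractness γ_A | α̂ = Σₙ\|Oₙ⟩⟨Oₙ\| over direct observations | 1 − ⟨ψ\|α̂\|ψ⟩ |
| divergence γ_D | salient-feature observable B̂ | √(⟨B̂²⟩ − ⟨B̂⟩²) |
| context-specificity γ_C | goal context Ĉ = Σᵢ\|i⟩⟨i\| | ⟨ψ\|Ĉ\|ψ⟩ |

Convergent thought uses a concept in its *compact* form (most typical
features only); divergent thought uses its *expanded* form, remote
associates included. A trajectory engine chains conceptual-change
operators — elaboration Û_A = Î + |A⟩⟨A|, unintegrated combination
|Ψ⟩⊗|A⟩, context projection, cross-concept projection Σᵢⱼ pᵢeⱼ⟨j|i⟩|j⟩ —
and renders each step's effect on (γ_A, γ_D, γ_C) as a qualitative arrow
table. The bundled case study replays two children's developmental paths
from "no model of the Earth's shape" to a Spherical-Earth model (one via a
Disk and an unintegrated Dual model, one via a Hollow model and reasoning
about planets), together with the classic frequency table of Earth-shape
mental models by school grade.

Audience: researchers in computational cognitive science, quantum
cognition, and conceptual-change / creativity modeling who want a small,
fully-tested reference implementation to build on.

## Worked example

The bundled DOG concept is a superposition over seven features. Applying
the hunting context Ĉ = |hunt⟩⟨hunt| + |smell⟩⟨smell| trims thought to the
goal-relevant features:

```python
from mindmodes.io import load_bundled_concepts, load_bundled_contexts
from mindmodes.concepts import apply_context, typicality
from mindmodes.dimensions import ObservationSet, DivergenceObservable, profile

concepts, contexts = load_bundled_concepts(), load_bundled_contexts()
dog, hunting = concepts["dog"], contexts["hunting"]

typicality(dog, "furry")                                  # 0.5292
apply_context(dog.state, hunting, renormalize=False)      # d_h|hunt⟩ + d_s|smell⟩
#   raw amplitudes:          {hunt: 0.2646, smell: 0.2236}
#   after renormalization:   {hunt: 0.7638, smell: 0.6455}

obs  = ObservationSet(dog.basis, dog.observation_labels)
bhat = DivergenceObservable(dog.basis, salient_labels=("hunt", "smell", "bark"))
profile(dog.state, obs, hunting, bhat)
# DimensionProfile(gamma_A=0.15, gamma_D=0.433, gamma_C=0.12)
```

γ_C = 0.12 is exactly the squared-amplitude mass the DOG state places on
the hunting features (d_h² + d_s² = 0.07 + 0.05); γ_A = 0.15 says the
concept is mostly grounded in observable features (only the mass on
"loyal" is not); γ_D is the spread of the state over the salient-feature
observable.

The case-study trajectories run from the command line:

```console
$ mindmodes trajectory child_j
step,description,source,equation,gamma_A,gamma_D,gamma_C
1,No earth model to flat earth,IL,15,↑,−,−
2,Flat earth to hollow earth,RR,2,−,↓,−
3,Mars is a planet,SL,2,−,−,−
4,Planet is a solid sphere,SL,2,↓,−,−
5,Earth is a planet,SL,2,↑,−,−
6,Earth is a sphere,RR,18,↑,↑,−
7,"Mars is red, spherical",SL,2,↓,−,−
8,"Balloon is red, spherical",IL,2,↓,−,−
9,Pretend red balloon is mars,RR,5,↓,↑,↑
```

Each row is one conceptual-change step, tagged with its source (IL =
individual learning, SL = social learning, RR = representational
redescription) and the arrows say whether the step raised (↑), lowered (↓)
or left unchanged (−) each of the three measures. For example, the final
pretend-play step projects the child's state onto the
{red balloon, Mars, pretend-play} context: the concrete balloon drags
abstractness down (0.494 → 0.415), the spread over salient features rises
(0.403 → 0.483), and context-specificity jumps to 1.0. `mindmodes validate`
prints the mental-model frequency table's marginals (7 models × 3 grades,
60 children), and `mindmodes generate` emits synthetic concept/context
bundles for experimentation.

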