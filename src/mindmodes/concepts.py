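"""Concept-level semantics on top of the Hilbert-space algebra.

A concept (BIRD, ISLAND, DOG, ...) is a superposition over its instances and
features; the amplitude on a label encodes how typical that instance or
feature is. Conceptual change is modeled by operators:

* elaboration  Û_A = Î + |A⟩⟨A|  folds new, related information into the
  representation;
* when the new fact barely overlaps the current representation
  (|⟨A|Ψ⟩| ≪ 1), elaboration cannot take hold and the two are held jointly
  as a tensor product — unintegrated, possibly entangled, knowledge;
* a context or question Ĉ = Σ|i⟩⟨i| projects the representation onto the
  goal-relevant feature subspace;
* a concept can be held in a compact form (most typical features only,
  conducive to convergent thought) or an expanded form (the full
  superposition including remote associates, conducive to divergent
  thought);
* two concepts can be compared by projecting one superposition through the
  other, Σ_ij p_i e_j ⟨j|i⟩ |j⟩.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .algebra import (
    ATOL,
    Basis,
    LinearOperator,
    ProductState,
    StateVector,
    apply,
    inner,
    normalize,
    projector,
    tensor,
)
from .errors import (
    AnnihilationError,
    HermitianityError,
    UnknownLabelError,
)

#: default overlap below which new information is treated as unintegrated
NEGLIGIBLE_OVERLAP = 0.05


@dataclass(frozen=True)
class Concept:
    """A named concept: a normalized state plus bookkeeping about which
    basis labels are direct observations."""

    name: str
    state: StateVector
    observation_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.state.is_normalized:
            object.__setattr__(self, "state", normalize(self.state))
        obs = tuple(self.observation_labels)
        for lab in obs:
            if lab not in self.state.basis:
                raise UnknownLabelError(lab)
        object.__setattr__(self, "observation_labels", obs)

    @property
    def basis(self) -> Basis:
        return self.state.basis

    @property
    def salience_order(self) -> tuple[str, ...]:
        """Basis labels ranked by squared amplitude, descending; ties broken
        lexicographically so compact forms are deterministic."""
        probs = self.state.probabilities()
        order = sorted(
            range(self.basis.dimension),
            key=lambda i: (-probs[i], self.basis.labels[i]),
        )
        return tuple(self.basis.labels[i] for i in order)


@dataclass(frozen=True)
class Context:
    """A goal-defined context: the subset of features relevant right now.

    Acts as the projector Σ_i w_i |i⟩⟨i|; weights default to 1 (the
    orthonormal-feature assumption under which the projection is exact).
    """

    name: str
    labels: tuple[str, ...]
    weights: Mapping[str, float] | None = None

    def __post_init__(self):
        labels = tuple(self.labels)
        if not labels:
            raise ValueError("a context needs at least one label")
        object.__setattr__(self, "labels", labels)
        if self.weights is not None:
            bad = set(self.weights) - set(labels)
            if bad:
                raise UnknownLabelError(sorted(bad)[0])
            if any(w <= 0 for w in self.weights.values()):
                raise ValueError("context weights must be positive")

    def operator(self, basis: Basis) -> LinearOperator:
        op = projector(basis, self.labels)
        if self.weights is None:
            return op
        mat = np.array(op.matrix)
        for lab, w in self.weights.items():
            i = basis.index(lab)
            mat[i, i] = w
        return LinearOperator(basis, mat)


def typicality(concept: Concept, instance_label: str) -> float:
    """|⟨A|a⟩|: how typical a basis instance is of the concept.

    A pure instance is fully typical of itself (value 1); an instance absent
    from the superposition has typicality 0.
    """
    return abs(concept.state.amplitude(instance_label))


def elaborate(state: StateVector, info: StateVector,
              renormalize: bool = True, strength: float = 1.0) -> StateVector:
    """Incorporate new information: Û_A|Ψ⟩ = |Ψ⟩ + |A⟩⟨A|Ψ⟩.

    The new information is added weighted by its relevance ⟨A|Ψ⟩ to the
    current representation, so orthogonal information leaves the state
    untouched. The raw (unnormalized) sum is available with
    ``renormalize=False``; by default the result is renormalized.

    ``strength`` scales the projection term, |Ψ⟩ + c·|A⟩⟨A|Ψ⟩. Iterating
    the elaboration operator n times equals a single application with
    c = 2ⁿ−1, so strength > 1 models sustained dwelling on the same piece
    of information; the default c = 1 is a single elaboration.
    """
    if strength < 0:
        raise ValueError("strength must be non-negative")
    ov = inner(info, state)
    raw = StateVector(
        state.basis, state.amplitudes + strength * ov * info.amplitudes
    )
    return normalize(raw) if renormalize else raw


def combine_unintegrated(state: StateVector, info: StateVector) -> ProductState:
    """Hold a new fact alongside the current representation, unintegrated.

    Used when the overlap ⟨A|Ψ⟩ is negligible — the fact has been learnt but
    not understood to bear on the representation. The result is the
    (separable) tensor product; callers may subsequently impose a
    non-factorizing joint-amplitude pattern to model entanglement.
    """
    return tensor(normalize(state), normalize(info))


def apply_context(state: StateVector, ctx: Context,
                  renormalize: bool = True) -> StateVector:
    """Project a representation onto a context's feature subspace.

    Under the orthonormal-feature assumption the surviving amplitudes are
    exactly the original amplitudes on the context labels (Ĉ|Ψ⟩ =
    Σ_{i∈ctx} a_i|i⟩). Raises :class:`AnnihilationError` when the state is
    orthogonal to the context subspace.
    """
    op = ctx.operator(state.basis)
    out = StateVector(state.basis, op.matrix @ state.amplitudes)
    if out.norm <= ATOL:
        raise AnnihilationError(
            f"state has no support in context {ctx.name!r}"
        )
    return normalize(out) if renormalize else out


def compact_form(concept: Concept, mass_threshold: float = 0.9) -> StateVector:
    """The concept truncated to its most typical features.

    Keeps the smallest salience-ordered prefix of labels whose cumulative
    squared-amplitude mass reaches ``mass_threshold``, then renormalizes.
    Threshold 1.0 returns the full expanded state.
    """
    if not (0.0 < mass_threshold <= 1.0):
        raise ValueError("mass_threshold must lie in (0, 1]")
    probs = concept.state.probabilities()
    keep: list[str] = []
    mass = 0.0
    for lab in concept.salience_order:
        if mass >= mass_threshold - ATOL:
            break
        keep.append(lab)
        mass += probs[concept.basis.index(lab)]
    idx = concept.basis.indices(keep)
    amps = np.zeros(concept.basis.dimension, dtype=complex)
    amps[idx] = concept.state.amplitudes[idx]
    return normalize(StateVector(concept.basis, amps))


def expanded_form(concept: Concept) -> StateVector:
    """The full superposition, remote associates included."""
    return concept.state


def project_compare(
    source: Concept,
    target: Concept,
    basis_map: Mapping[tuple[str, str], complex] | None = None,
) -> StateVector:
    """Compare two concepts by projecting one through the other.

    With |source⟩ = Σ_i p_i|i⟩ and |target⟩ = Σ_j e_j|j⟩, the result is the
    target-basis state with amplitudes Σ_i p_i e_j ⟨j|i⟩ on label j,
    renormalized. The cross-basis inner products ⟨j|i⟩ default to 1 where
    labels literally match and 0 otherwise; ``basis_map`` overrides entries
    by (source_label, target_label) pair.

    Raises :class:`AnnihilationError` when the concepts share no features
    under the map.
    """
    basis_map = dict(basis_map or {})
    p = source.state.amplitudes
    e = target.state.amplitudes
    src_labels = source.basis.labels
    tgt_labels = target.basis.labels
    out = np.zeros(target.basis.dimension, dtype=complex)
    for j, lab_j in enumerate(tgt_labels):
        acc = 0.0 + 0.0j
        for i, lab_i in enumerate(src_labels):
            ov = basis_map.get((lab_i, lab_j), 1.0 if lab_i == lab_j else 0.0)
            if ov:
                acc += p[i] * ov
        out[j] = acc * e[j]
    result = StateVector(target.basis, out)
    if result.norm <= ATOL:
        raise AnnihilationError(
            f"concepts {source.name!r} and {target.name!r} share no features "
            "under the given correspondence"
        )
    return normalize(result)


@dataclass(frozen=True)
class JointAnswer:
    """Outcome of putting a two-part question to a joint representation."""

    probabilities: dict[tuple[str, str], float] = field(repr=False)
    incompatible: bool = False
    contradiction_mass: float = 0.0

    def marginal(self, factor: str) -> dict[str, float]:
        out: dict[str, float] = {}
        k = 0 if factor == "a" else 1
        for pair, p in self.probabilities.items():
            out[pair[k]] = out.get(pair[k], 0.0) + p
        return out


def _projector_support(op: LinearOperator) -> tuple[str, ...]:
    diag = np.abs(np.diag(op.matrix))
    return tuple(
        lab for lab, d in zip(op.basis.labels, diag) if d > ATOL
    )


def joint_question(
    dual: ProductState,
    op_s: LinearOperator,
    op_d: LinearOperator,
    contradictory_pairs: Sequence[tuple[str, str]] = (),
    incompatibility_threshold: float = 0.5,
) -> JointAnswer:
    """Ask a question Ô = Ô_s ⊗ Ô_d of a joint (possibly unintegrated)
    representation.

    ``op_s`` acts on factor A and ``op_d`` on factor B; both must be
    projectors onto their answer subspaces (the identity means the question
    does not touch that factor). Returns the joint Born probabilities over
    (answer_s, answer_d) label pairs, conditioned on the answer subspaces.

    If the caller declares contradictory answer pairs — e.g. the Dual-Earth
    representation asked its shape, where "flat" from one factor contradicts
    "sphere" from the other — and the two conditional marginals jointly
    place mass of at least ``incompatibility_threshold`` on such pairs, the
    answer is flagged incompatible: the representation cannot answer the
    question coherently.
    """
    if not (op_s.is_projector and op_d.is_projector):
        raise HermitianityError("joint_question requires projector observables")
    supp_s = _projector_support(op_s)
    supp_d = _projector_support(op_d)
    idx_s = dual.basis_a.indices(supp_s)
    idx_d = dual.basis_b.indices(supp_d)
    block = np.abs(dual.joint_amplitudes[np.ix_(idx_s, idx_d)]) ** 2
    total = block.sum()
    if total <= ATOL:
        raise AnnihilationError("joint state has no support in the answer subspaces")
    block = block / total
    probs = {
        (la, lb): float(block[i, j])
        for i, la in enumerate(supp_s)
        for j, lb in enumerate(supp_d)
        if block[i, j] > 0.0
    }
    ans = JointAnswer(probabilities=probs)
    if contradictory_pairs:
        marg_a = ans.marginal("a")
        marg_b = ans.marginal("b")
        mass = sum(
            min(marg_a.get(la, 0.0), marg_b.get(lb, 0.0))
            for la, lb in contradictory_pairs
        )
        ans = JointAnswer(
            probabilities=probs,
            incompatible=mass >= incompatibility_threshold,
            contradiction_mass=mass,
        )
    return ans
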