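"""Labeled finite-dimensional Hilbert-space algebra.

A mental representation is a superposition |Ψ⟩ = Σ_i a_i |ϕ_i⟩ over a labeled
orthonormal basis, with complex amplitudes a_i whose squared magnitudes give
Born-rule probabilities. This module provides the bases, state vectors,
Hermitian operators, tensor products of two representations, a Schmidt-rank
separability test, and projective measurement (collapse).

Everything downstream — concept semantics, the three mode-of-thought
measures, and the conceptual-change trajectory engine — is built on these
primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AnnihilationError,
    BasisMismatchError,
    EmptySubspaceError,
    HermitianityError,
    NormalizationError,
    UnknownLabelError,
)

#: absolute tolerance for normalization and hermiticity checks
ATOL = 1e-9


@dataclass(frozen=True)
class Basis:
    """An ordered orthonormal basis identified by unique string labels.

    Labels are case-sensitive. Basis states are mutually orthogonal by
    construction: the geometry is entirely encoded in the label identity.
    """

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]):
        labels = tuple(labels)
        if len(labels) < 1:
            raise ValueError("a basis needs at least one label")
        if len(set(labels)) != len(labels):
            raise ValueError("basis labels must be unique")
        object.__setattr__(self, "labels", labels)

    @property
    def dimension(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise UnknownLabelError(label) from None

    def indices(self, labels: Iterable[str]) -> list[int]:
        return [self.index(lab) for lab in labels]

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __len__(self) -> int:
        return self.dimension


def _as_complex(values: Sequence | np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=complex)
    if not np.all(np.isfinite(arr.view(float))):
        raise ValueError("amplitudes must be finite")
    return arr


@dataclass(frozen=True)
class StateVector:
    """A superposition state over a labeled basis.

    Amplitudes are stored as complex numbers; real weights are accepted and
    promoted. The constructor does not normalize — use :func:`normalize` or
    the ``normalized()`` method.
    """

    basis: Basis
    amplitudes: np.ndarray = field(repr=False)

    def __init__(self, basis: Basis, amplitudes: Sequence | np.ndarray):
        arr = _as_complex(amplitudes)
        if arr.shape != (basis.dimension,):
            raise ValueError(
                f"expected {basis.dimension} amplitudes, got shape {arr.shape}"
            )
        object.__setattr__(self, "basis", basis)
        object.__setattr__(self, "amplitudes", arr)
        self.amplitudes.setflags(write=False)

    @classmethod
    def from_dict(cls, basis: Basis, weights: dict[str, complex]) -> "StateVector":
        """Build a state from a ``label -> amplitude`` mapping; absent labels
        get zero amplitude."""
        amps = np.zeros(basis.dimension, dtype=complex)
        for label, w in weights.items():
            amps[basis.index(label)] = w
        return cls(basis, amps)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    @property
    def is_normalized(self) -> bool:
        return abs(self.norm - 1.0) <= ATOL

    def amplitude(self, label: str) -> complex:
        return complex(self.amplitudes[self.basis.index(label)])

    def probabilities(self) -> np.ndarray:
        """Born-rule probabilities |a_i|² (of the state as stored)."""
        return np.abs(self.amplitudes) ** 2

    def support(self, tol: float = ATOL) -> tuple[str, ...]:
        """Labels carrying non-negligible amplitude."""
        mask = np.abs(self.amplitudes) > tol
        return tuple(lab for lab, m in zip(self.basis.labels, mask) if m)

    def normalized(self) -> "StateVector":
        return normalize(self)


@dataclass(frozen=True)
class LinearOperator:
    """A linear operator over a labeled basis, stored as a dense matrix."""

    basis: Basis
    matrix: np.ndarray = field(repr=False)

    def __init__(self, basis: Basis, matrix: Sequence | np.ndarray):
        arr = _as_complex(matrix)
        d = basis.dimension
        if arr.shape != (d, d):
            raise ValueError(f"expected a {d}x{d} matrix, got shape {arr.shape}")
        object.__setattr__(self, "basis", basis)
        object.__setattr__(self, "matrix", arr)
        self.matrix.setflags(write=False)

    @property
    def is_hermitian(self) -> bool:
        return bool(np.allclose(self.matrix, self.matrix.conj().T, atol=ATOL))

    @property
    def is_projector(self) -> bool:
        return self.is_hermitian and bool(
            np.allclose(self.matrix @ self.matrix, self.matrix, atol=1e-8)
        )

    @classmethod
    def identity(cls, basis: Basis) -> "LinearOperator":
        return cls(basis, np.eye(basis.dimension, dtype=complex))

    def __matmul__(self, other: "LinearOperator") -> "LinearOperator":
        _check_same_basis(self.basis, other.basis)
        return LinearOperator(self.basis, self.matrix @ other.matrix)


@dataclass(frozen=True)
class ProductState:
    """A joint state Σ_ij a_ij |i⟩_A ⊗ |j⟩_B of two representations.

    Separable states factor as a_ij = a_i^A · a_j^B; any state that does not
    so factor is entangled, which here models two pieces of knowledge held
    jointly but not integrated.
    """

    basis_a: Basis
    basis_b: Basis
    joint_amplitudes: np.ndarray = field(repr=False)

    def __init__(self, basis_a: Basis, basis_b: Basis,
                 joint_amplitudes: Sequence | np.ndarray):
        arr = _as_complex(joint_amplitudes)
        if arr.shape != (basis_a.dimension, basis_b.dimension):
            raise ValueError(
                "joint amplitude array must be "
                f"{basis_a.dimension}x{basis_b.dimension}, got {arr.shape}"
            )
        object.__setattr__(self, "basis_a", basis_a)
        object.__setattr__(self, "basis_b", basis_b)
        object.__setattr__(self, "joint_amplitudes", arr)
        self.joint_amplitudes.setflags(write=False)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.joint_amplitudes))

    @property
    def is_normalized(self) -> bool:
        return abs(self.norm - 1.0) <= ATOL

    def normalized(self) -> "ProductState":
        n = self.norm
        if n <= 0.0:
            raise NormalizationError("cannot normalize the zero joint state")
        return ProductState(self.basis_a, self.basis_b, self.joint_amplitudes / n)

    def marginal_probabilities(self, factor: str) -> np.ndarray:
        """Born marginals over one factor ('a' or 'b')."""
        p = np.abs(self.joint_amplitudes) ** 2
        if factor == "a":
            return p.sum(axis=1)
        if factor == "b":
            return p.sum(axis=0)
        raise ValueError("factor must be 'a' or 'b'")


def _check_same_basis(x: Basis, y: Basis) -> None:
    if x.labels != y.labels:
        raise BasisMismatchError(f"bases differ: {x.labels} vs {y.labels}")


def normalize(state: StateVector) -> StateVector:
    """Scale a state to unit norm, preserving its direction."""
    n = state.norm
    if n <= 0.0:
        raise NormalizationError("cannot normalize the zero vector")
    return StateVector(state.basis, state.amplitudes / n)


def inner(bra: StateVector, ket: StateVector) -> complex:
    """The inner product ⟨bra|ket⟩ = Σ_i conj(a_i)·b_i.

    For a normalized concept state |A⟩ and a basis instance |a⟩, the
    magnitude |⟨A|a⟩| is the typicality of the instance.
    """
    _check_same_basis(bra.basis, ket.basis)
    return complex(np.vdot(bra.amplitudes, ket.amplitudes))


def projector(basis: Basis, labels: Iterable[str]) -> LinearOperator:
    """The projector P = Σ_{i in labels} |i⟩⟨i| onto a label subspace.

    Projectors implement both contexts (a goal trims thought to relevant
    features) and multiple-choice questions (a projection onto the answer
    subspace).
    """
    labels = tuple(labels)
    if not labels:
        raise EmptySubspaceError("projector requires at least one label")
    idx = basis.indices(labels)
    mat = np.zeros((basis.dimension, basis.dimension), dtype=complex)
    for i in idx:
        mat[i, i] = 1.0
    return LinearOperator(basis, mat)


def apply(op: LinearOperator, state: StateVector,
          renormalize: bool = True) -> StateVector:
    """Apply an operator to a state, optionally renormalizing the result.

    Raises :class:`AnnihilationError` if renormalization is requested but the
    operator annihilates the state (no support in the operator's range).
    """
    _check_same_basis(op.basis, state.basis)
    out = StateVector(state.basis, op.matrix @ state.amplitudes)
    if renormalize:
        if out.norm <= ATOL:
            raise AnnihilationError(
                "operator annihilated the state; nothing to renormalize"
            )
        out = normalize(out)
    return out


def expectation(state: StateVector, op: LinearOperator) -> float:
    """The expectation value ⟨ψ|M̂|ψ⟩ of a Hermitian operator.

    For a projector this is the squared-amplitude mass the state places in
    the projected subspace, a number in [0, 1] for normalized states.
    """
    if not op.is_hermitian:
        raise HermitianityError("expectation requires a Hermitian operator")
    _check_same_basis(op.basis, state.basis)
    val = np.vdot(state.amplitudes, op.matrix @ state.amplitudes)
    return float(val.real)


def tensor(a: StateVector, b: StateVector) -> ProductState:
    """The tensor product |a⟩⊗|b⟩ with joint amplitudes a_i·b_j.

    Used when a newly acquired fact has negligible overlap with the current
    representation: the two are held jointly, unintegrated.
    """
    joint = np.outer(a.amplitudes, b.amplitudes)
    return ProductState(a.basis, b.basis, joint)


@dataclass(frozen=True)
class SeparabilityResult:
    """Verdict of the Schmidt-rank separability test, with the singular-value
    spectrum (Schmidt coefficients) as a diagnostic."""

    verdict: str  # "separable" | "entangled"
    schmidt_coefficients: np.ndarray

    @property
    def is_separable(self) -> bool:
        return self.verdict == "separable"


def separability_test(p: ProductState, tol: float = 1e-6) -> SeparabilityResult:
    """Decide whether a joint state factors as a_ij = a_i^A · a_j^B.

    Operationally: the joint amplitude matrix is separable iff it has Schmidt
    rank 1, i.e. its second singular value is at most ``tol`` relative to the
    first. This criterion is invariant to global phase, unlike elementwise
    comparison of a_ij with a_i^A·a_j^B.
    """
    sv = np.linalg.svd(p.joint_amplitudes, compute_uv=False)
    if sv[0] <= 0.0:
        raise NormalizationError("zero joint state has no Schmidt form")
    ratio = sv[1] / sv[0] if sv.size > 1 else 0.0
    verdict = "separable" if ratio <= tol else "entangled"
    return SeparabilityResult(verdict, sv)


def collapse(state: StateVector, observable_basis: Basis,
             seed: int) -> tuple[str, StateVector]:
    """Projective measurement in the label basis.

    Samples an outcome label with Born probability |a_i|² and returns the
    post-measurement state |i⟩. Measurement is restricted to the
    computational (label) basis: the interpretations a question can resolve
    to are the basis states themselves.

    The same seed always yields the same outcome.
    """
    if not state.is_normalized:
        raise NormalizationError("collapse requires a normalized state")
    _check_same_basis(state.basis, observable_basis)
    probs = state.probabilities()
    probs = probs / probs.sum()  # kill 1e-9-level round-off
    rng = np.random.default_rng(seed)
    i = int(rng.choice(state.basis.dimension, p=probs))
    post = np.zeros(state.basis.dimension, dtype=complex)
    post[i] = 1.0
    return state.basis.labels[i], StateVector(state.basis, post)
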