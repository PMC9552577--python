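"""The three mode-of-thought measures: abstractness, divergence,
context-specificity.

All three are expectation values of Hermitian operators on the current
mental state |ψ⟩, taken with respect to a fixed description of the
environment:

* an observation set {|O_n⟩} — the basis labels that are direct sensory
  observations; α̂ = Σ_n |O_n⟩⟨O_n| measures how grounded the state is in
  them, and **abstractness** is reported as γ_A = 1 − ⟨ψ|α̂|ψ⟩ (the raw
  groundedness is exposed separately);
* a goal context Ĉ; **context-specificity** is γ_C = ⟨ψ|Ĉ|ψ⟩ exactly as
  defined (the complement 1 − γ_C is exposed for readers who prefer
  "degree to which the context would change thought");
* a salient-feature observable B̂; **divergence** is the standard deviation
  γ_D = √(⟨B̂²⟩ − ⟨B̂⟩²) of the thought over that observable. With B̂ a
  projector onto a proper salient subset this reduces to √(p(1−p)) where p
  is the squared-amplitude mass on the salient labels; a weighted mode with
  arbitrary real eigenvalues supports richer spread measures. (A projector
  onto a *complete* basis is the identity and yields γ_D ≡ 0, which is why
  the default observable projects onto a proper subset.)

The sign convention for γ_A makes "shifting away from direct observations"
register as an increase in abstractness, matching the qualitative arrow
conventions used by the trajectory engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .algebra import (
    Basis,
    LinearOperator,
    StateVector,
    expectation,
    normalize,
    projector,
)
from .concepts import Context
from .errors import NormalizationError, NumericalError, UnknownLabelError

#: default per-dimension tolerance when quantizing profile changes to arrows
ARROW_TOL = 0.05


@dataclass(frozen=True)
class ObservationSet:
    """The basis labels flagged as direct observations {|O_n⟩}."""

    basis: Basis
    labels: tuple[str, ...]

    def __post_init__(self):
        labels = tuple(self.labels)
        if not labels:
            raise ValueError("an observation set needs at least one label")
        for lab in labels:
            if lab not in self.basis:
                raise UnknownLabelError(lab)
        object.__setattr__(self, "labels", labels)

    def operator(self) -> LinearOperator:
        """α̂ = Σ_n |O_n⟩⟨O_n|."""
        return projector(self.basis, self.labels)


@dataclass(frozen=True)
class DivergenceObservable:
    """The salient-feature observable B̂ whose variance measures divergence.

    ``projector`` mode: B̂ projects onto ``salient_labels`` (a proper subset
    of the basis, or the variance degenerates to zero everywhere).
    ``weighted`` mode: B̂ is diagonal with one real eigenvalue per label.
    """

    basis: Basis
    mode: str = "projector"
    salient_labels: tuple[str, ...] = ()
    eigenvalues: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.mode not in ("projector", "weighted"):
            raise ValueError("mode must be 'projector' or 'weighted'")
        if self.mode == "projector":
            labels = tuple(self.salient_labels)
            if not labels:
                raise ValueError("projector mode needs salient labels")
            for lab in labels:
                if lab not in self.basis:
                    raise UnknownLabelError(lab)
            object.__setattr__(self, "salient_labels", labels)
        else:
            if self.eigenvalues is None:
                raise ValueError("weighted mode needs eigenvalues")
            vals = {lab: float(v) for lab, v in self.eigenvalues.items()}
            for lab in vals:
                if lab not in self.basis:
                    raise UnknownLabelError(lab)
            if not all(np.isfinite(v) for v in vals.values()):
                raise ValueError("eigenvalues must be finite")
            object.__setattr__(self, "eigenvalues", vals)

    def operator(self) -> LinearOperator:
        if self.mode == "projector":
            return projector(self.basis, self.salient_labels)
        diag = np.zeros(self.basis.dimension)
        for lab, v in self.eigenvalues.items():
            diag[self.basis.index(lab)] = v
        return LinearOperator(self.basis, np.diag(diag).astype(complex))


@dataclass(frozen=True)
class DimensionProfile:
    """The triple (γ_A, γ_D, γ_C) of one mental state under one environment."""

    gamma_A: float
    gamma_D: float
    gamma_C: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.gamma_A, self.gamma_D, self.gamma_C)


def observation_groundedness(state: StateVector, obs: ObservationSet) -> float:
    """The raw expectation ⟨ψ|α̂|ψ⟩: squared-amplitude mass on observations."""
    return expectation(state, obs.operator())


def abstractness(state: StateVector, obs: ObservationSet) -> float:
    """Reported abstractness γ_A = 1 − ⟨ψ|α̂|ψ⟩, in [0, 1].

    A state supported entirely on observation labels is fully concrete
    (γ_A = 0); a state orthogonal to all observations is purely abstract
    (γ_A = 1).
    """
    val = 1.0 - observation_groundedness(state, obs)
    return float(min(max(val, 0.0), 1.0))


def context_specificity(state: StateVector, ctx: Context) -> float:
    """γ_C = ⟨ψ|Ĉ|ψ⟩: overlap of the state with the context subspace."""
    op = ctx.operator(state.basis)
    return expectation(state, op)


def context_sensitivity_complement(state: StateVector, ctx: Context) -> float:
    """1 − γ_C: how much the context projection would change the state."""
    return 1.0 - context_specificity(state, ctx)


def divergence(state: StateVector, obsv: DivergenceObservable) -> float:
    """γ_D = √(⟨B̂²⟩ − ⟨B̂⟩²): standard deviation of thought over B̂."""
    op = obsv.operator()
    op2 = LinearOperator(op.basis, op.matrix @ op.matrix)
    var = expectation(state, op2) - expectation(state, op) ** 2
    if var < -1e-12:
        raise NumericalError(f"negative variance {var} from a broken operator")
    return float(np.sqrt(max(var, 0.0)))


def build_abstraction(obs: ObservationSet,
                      weights: Mapping[str, float]) -> StateVector:
    """Form a concept one step removed from observations:
    |A₀⟩ = Σ_n a_n |O_n⟩, normalized.

    ``weights`` assigns amplitudes to a subset of the observation labels.
    """
    for lab in weights:
        if lab not in obs.labels:
            raise UnknownLabelError(lab)
    amps = np.zeros(obs.basis.dimension, dtype=complex)
    for lab, w in weights.items():
        amps[obs.basis.index(lab)] = w
    state = StateVector(obs.basis, amps)
    if state.norm <= 0.0:
        raise NormalizationError("all-zero abstraction weights")
    return normalize(state)


def profile(state: StateVector, obs: ObservationSet, ctx: Context,
            obsv: DivergenceObservable) -> DimensionProfile:
    """Compute all three measures of one state under one environment."""
    return DimensionProfile(
        gamma_A=abstractness(state, obs),
        gamma_D=divergence(state, obsv),
        gamma_C=context_specificity(state, ctx),
    )


#: arrow glyphs used in change tables
UP, DOWN, FLAT = "↑", "↓", "−"


def delta_profile(before: DimensionProfile, after: DimensionProfile,
                  tol: float = ARROW_TOL) -> tuple[str, str, str]:
    """Quantize a profile change into the qualitative arrows (↑, ↓, −).

    Each dimension gets ↑ if it rose by more than ``tol``, ↓ if it fell by
    more than ``tol``, and − otherwise.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")

    def arrow(b: float, a: float) -> str:
        d = a - b
        if d > tol:
            return UP
        if d < -tol:
            return DOWN
        return FLAT

    return (
        arrow(before.gamma_A, after.gamma_A),
        arrow(before.gamma_D, after.gamma_D),
        arrow(before.gamma_C, after.gamma_C),
    )
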