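"""JSON serialization of bases, states, operators, concepts and contexts.

Complex numbers are serialized as ``[re, im]`` pairs throughout; all files
are UTF-8 and label strings are case-sensitive. A bundled fixture file
ships the worked-example concepts (blanket, island, dog, bird, planet).
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any, Mapping

import numpy as np

from .algebra import Basis, LinearOperator, StateVector
from .concepts import Concept, Context
from .dimensions import DivergenceObservable, ObservationSet
from .errors import FixtureError


class SchemaError(ValueError):
    """A JSON document does not match the expected schema; ``field`` names
    the offending entry."""

    def __init__(self, field: str, message: str):
        super().__init__(f"{field}: {message}")
        self.field = field


def _require(doc: Mapping, field: str, kind=None):
    if field not in doc:
        raise SchemaError(field, "missing required field")
    value = doc[field]
    if kind is not None and not isinstance(value, kind):
        raise SchemaError(field, f"expected {kind.__name__}")
    return value


def _complex_pairs(values, field: str) -> np.ndarray:
    out = []
    for i, v in enumerate(values):
        if isinstance(v, (int, float)):
            out.append(complex(v))
        elif isinstance(v, (list, tuple)) and len(v) == 2:
            out.append(complex(v[0], v[1]))
        else:
            raise SchemaError(f"{field}[{i}]", "expected a number or [re, im] pair")
    return np.asarray(out, dtype=complex)


def _pairs(arr: np.ndarray) -> list[list[float]]:
    return [[float(z.real), float(z.imag)] for z in np.asarray(arr, dtype=complex)]


# -- basis ------------------------------------------------------------------

def basis_to_json(basis: Basis) -> dict:
    return {"labels": list(basis.labels)}


def basis_from_json(doc: Mapping) -> Basis:
    labels = _require(doc, "labels", list)
    if not all(isinstance(lab, str) for lab in labels):
        raise SchemaError("labels", "labels must be strings")
    try:
        return Basis(labels)
    except ValueError as exc:
        raise SchemaError("labels", str(exc)) from exc


# -- state ------------------------------------------------------------------

def state_to_json(state: StateVector) -> dict:
    return {
        "basis": basis_to_json(state.basis),
        "amplitudes": _pairs(state.amplitudes),
    }


def state_from_json(doc: Mapping) -> StateVector:
    basis = basis_from_json(_require(doc, "basis", dict))
    amps = _complex_pairs(_require(doc, "amplitudes", list), "amplitudes")
    if amps.shape != (basis.dimension,):
        raise SchemaError("amplitudes", "amplitude count must equal basis dimension")
    return StateVector(basis, amps)


# -- operator ---------------------------------------------------------------

def operator_to_json(op: LinearOperator) -> dict:
    return {
        "basis": basis_to_json(op.basis),
        "matrix": [_pairs(row) for row in op.matrix],
    }


def operator_from_json(doc: Mapping) -> LinearOperator:
    basis = basis_from_json(_require(doc, "basis", dict))
    rows = _require(doc, "matrix", list)
    if len(rows) != basis.dimension:
        raise SchemaError("matrix", "row count must equal basis dimension")
    mat = np.stack(
        [_complex_pairs(row, f"matrix[{i}]") for i, row in enumerate(rows)]
    )
    if mat.shape != (basis.dimension, basis.dimension):
        raise SchemaError("matrix", "matrix must be square")
    return LinearOperator(basis, mat)


# -- concept / context ------------------------------------------------------

def concept_to_json(concept: Concept) -> dict:
    doc = state_to_json(concept.state)
    doc["name"] = concept.name
    doc["observations"] = list(concept.observation_labels)
    return doc


def concept_from_json(doc: Mapping) -> Concept:
    name = _require(doc, "name", str)
    state = state_from_json(doc)
    obs = doc.get("observations", [])
    if not isinstance(obs, list):
        raise SchemaError("observations", "expected a list of labels")
    for lab in obs:
        if lab not in state.basis:
            raise SchemaError("observations", f"unknown label {lab!r}")
    return Concept(name, state, tuple(obs))


def context_to_json(ctx: Context) -> dict:
    doc: dict[str, Any] = {"name": ctx.name, "labels": list(ctx.labels)}
    if ctx.weights is not None:
        doc["weights"] = dict(ctx.weights)
    return doc


def context_from_json(doc: Mapping) -> Context:
    name = _require(doc, "name", str)
    labels = _require(doc, "labels", list)
    weights = doc.get("weights")
    try:
        return Context(name, tuple(labels), weights)
    except (ValueError, KeyError) as exc:
        raise SchemaError("labels", str(exc)) from exc


def divergence_from_json(doc: Mapping, basis: Basis) -> DivergenceObservable:
    mode = doc.get("mode", "projector")
    if mode == "projector":
        labels = _require(doc, "salient_labels", list)
        try:
            return DivergenceObservable(
                basis, mode="projector", salient_labels=tuple(labels)
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError("salient_labels", str(exc)) from exc
    if mode == "weighted":
        eig = _require(doc, "eigenvalues", dict)
        try:
            return DivergenceObservable(basis, mode="weighted", eigenvalues=eig)
        except (ValueError, KeyError) as exc:
            raise SchemaError("eigenvalues", str(exc)) from exc
    raise SchemaError("mode", "must be 'projector' or 'weighted'")


def observation_set_from_json(doc: Mapping, basis: Basis) -> ObservationSet:
    labels = _require(doc, "labels", list)
    try:
        return ObservationSet(basis, tuple(labels))
    except (ValueError, KeyError) as exc:
        raise SchemaError("labels", str(exc)) from exc


# -- bundled worked-example concepts ---------------------------------------

def load_bundled_concepts() -> dict[str, Concept]:
    """The packaged worked-example concepts, keyed by name."""
    ref = resources.files("mindmodes.data").joinpath("concepts.json")
    try:
        with resources.as_file(ref) as f:
            docs = json.loads(f.read_text(encoding="utf-8"))
    except OSError as exc:
        raise FixtureError(f"cannot read bundled concepts: {exc}") from exc
    return {doc["name"]: concept_from_json(doc) for doc in docs}


def load_bundled_contexts() -> dict[str, Context]:
    """The packaged worked-example contexts, keyed by name."""
    ref = resources.files("mindmodes.data").joinpath("contexts.json")
    try:
        with resources.as_file(ref) as f:
            docs = json.loads(f.read_text(encoding="utf-8"))
    except OSError as exc:
        raise FixtureError(f"cannot read bundled contexts: {exc}") from exc
    return {doc["name"]: context_from_json(doc) for doc in docs}
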