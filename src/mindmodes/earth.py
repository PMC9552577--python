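"""The Earth-shape case study: two children's conceptual-change trajectories.

Two children start from the same unstructured perceptual state (no mental
model of the Earth's shape) and end holding a Spherical-Earth model, but by
different routes:

* child i: Flat → Disk → Dual (an unintegrated flat-plus-sphere tensor
  state) → Sphere, finishing with a play step;
* child j: Flat → Hollow, then a chain of social-learning steps about Mars
  and planets, a redescription that projects the planet concept through the
  Earth concept, and finally a pretend-play step that projects the state
  onto the play context.

All states live in one labeled basis mixing direct observations (flat
ground, the horizon, a drawn circle, a toy ball, a red balloon, redness)
with abstractions (flat, round, hollow, sphere, planet, Mars, pretend play).
The environment against which the three measures are computed is fixed for
the whole case study: the observation set is the six perceptual labels, the
goal context is pretend play, and the salient-feature observable projects
onto the features most salient in the children's surroundings and
discourse.

The numeric amplitudes below are a frozen calibration: they were chosen
once so that the qualitative arrow patterns of the two trajectories are
reproduced at the default tolerance, and are regression-tested. The claims
of the case study are the arrow patterns, not the magnitudes.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .algebra import Basis, StateVector, normalize, projector
from .concepts import (
    NEGLIGIBLE_OVERLAP,
    Concept,
    Context,
    apply_context,
    combine_unintegrated,
    compact_form,
    elaborate,
    inner,
    joint_question,
    project_compare,
)
from .dimensions import DivergenceObservable, ObservationSet
from .trajectory import ChangeStep, Environment, Trajectory, run_trajectory

# ---------------------------------------------------------------------------
# The shared basis and environment

OBSERVATION_LABELS = (
    "flat_ground",     # the ground underfoot looks flat
    "flat_horizon",    # the horizon looks flat
    "circle_drawing",  # a circle drawn on paper / blackboard
    "toy_ball",        # the child's ball
    "red_balloon",     # a red balloon in the room
    "red",             # redness itself
)

ABSTRACT_LABELS = (
    "flat", "round", "hollow", "sphere", "planet", "mars", "pretend_play",
)

EARTH_BASIS = Basis(OBSERVATION_LABELS + ABSTRACT_LABELS)

#: features salient in the children's environment and discourse: what they
#: see and handle, plus the Earth-shape ideas under discussion and Mars
SALIENT_LABELS = (
    "flat_ground", "flat_horizon", "toy_ball",
    "flat", "round", "hollow", "sphere", "mars",
)

#: the pretend-play goal context (includes the concrete balloon, so play
#: re-grounds thought in an observation)
PLAY_CONTEXT_LABELS = ("red_balloon", "mars", "pretend_play")


def _state(masses: Mapping[str, float]) -> StateVector:
    """Build a normalized state from squared-amplitude weights."""
    amps = {lab: math.sqrt(m) for lab, m in masses.items()}
    return normalize(StateVector.from_dict(EARTH_BASIS, amps))


def environment() -> Environment:
    """The fixed environment of the case study."""
    return Environment(
        observations=ObservationSet(EARTH_BASIS, OBSERVATION_LABELS),
        context=Context("pretend_play", PLAY_CONTEXT_LABELS),
        divergence=DivergenceObservable(
            EARTH_BASIS, mode="projector", salient_labels=SALIENT_LABELS
        ),
    )


# ---------------------------------------------------------------------------
# Frozen calibration (squared-amplitude weights of every fixture state)

#: the shared start state: raw percepts, no earth model
INITIAL_MASSES = {
    "flat_ground": 0.52, "flat_horizon": 0.26, "toy_ball": 0.08,
    "circle_drawing": 0.06, "red_balloon": 0.04, "red": 0.03,
    "pretend_play": 0.01,
}

#: step 1 (both children): the experiences bound to the new "flat" label
FLAT_ABSTRACTION_MASS = 0.30   # weight of the flat label inside the info state
FLAT_STRENGTH = 2.0

# --- child i ---
DISK_INFO_MASSES = {
    "flat_ground": 0.38, "flat_horizon": 0.17, "circle_drawing": 0.07,
    "round": 0.23, "flat": 0.09,
}
DISK_STRENGTH = 0.8
DISK_COMPACT_THRESHOLD = 0.90

DUAL_COMPACT_THRESHOLD = 0.82
SPHERE_INFO_MASSES = {"sphere": 0.85, "toy_ball": 0.15}

SPHERE_I_INFO_MASSES = {
    "sphere": 0.38, "planet": 0.08, "flat_ground": 0.12, "flat_horizon": 0.06,
    "toy_ball": 0.09, "circle_drawing": 0.09, "round": 0.05,
    "red_balloon": 0.035, "red": 0.03, "pretend_play": 0.005,
}
SPHERE_I_STRENGTH = 7.0

BALLOON_I_INFO_MASSES = {
    "sphere": 0.50, "red_balloon": 0.20, "mars": 0.22, "pretend_play": 0.08,
}
BALLOON_I_STRENGTH = 0.20

# --- child j ---
HOLLOW_INFO_MASSES = {
    "flat_ground": 0.44, "flat_horizon": 0.27, "flat": 0.09, "hollow": 0.14,
    "circle_drawing": 0.02,
}
HOLLOW_STRENGTH = 1.4

MARS_PLANET_INFO_MASSES = {"toy_ball": 0.50, "mars": 0.30, "planet": 0.20}
MARS_PLANET_STRENGTH = 1.0

PLANET_SPHERE_INFO_MASSES = {
    "toy_ball": 0.70, "flat_ground": 0.15, "red": 0.05,
    "sphere": 0.07, "planet": 0.03,
}
PLANET_SPHERE_STRENGTH = 2.5

EARTH_PLANET_INFO_MASSES = {
    "planet": 0.09, "flat": 0.17, "hollow": 0.15,
    "flat_ground": 0.26, "flat_horizon": 0.10, "sphere": 0.15,
    "mars": 0.04,
}
EARTH_PLANET_STRENGTH = 1.2

#: child j's concept of PLANET at step 6 (built up over steps 3-5)
PLANET_CONCEPT_MASSES = {
    "planet": 0.36, "sphere": 0.30, "toy_ball": 0.14,
    "mars": 0.10, "red": 0.06, "circle_drawing": 0.04,
}

MARS_RED_INFO_MASSES = {
    "mars": 0.12, "sphere": 0.20, "toy_ball": 0.31,
    "red": 0.13, "flat_ground": 0.12, "red_balloon": 0.06,
    "pretend_play": 0.01,
}
MARS_RED_STRENGTH = 0.50

BALLOON_J_INFO_MASSES = {
    "red_balloon": 0.28, "red": 0.10, "toy_ball": 0.31,
    "flat_ground": 0.10, "sphere": 0.19, "pretend_play": 0.015,
}
BALLOON_J_STRENGTH = 0.50


# ---------------------------------------------------------------------------
# Fixture assembly


def initial_state() -> StateVector:
    return _state(INITIAL_MASSES)


def _flat_info() -> StateVector:
    """The step-1 information: the percept bundle bound to 'flat'."""
    base = initial_state()
    w = FLAT_ABSTRACTION_MASS
    amps = np.array(base.amplitudes) * math.sqrt(1.0 - w)
    amps[EARTH_BASIS.index("flat")] = math.sqrt(w)
    return normalize(StateVector(EARTH_BASIS, amps))


def _as_concept(state: StateVector, name: str = "earth") -> Concept:
    return Concept(name, state, OBSERVATION_LABELS)


def child_i_fixture() -> tuple[StateVector, list[ChangeStep], Environment]:
    """Child i: Flat → Disk → Dual → Sphere → play (5 steps)."""
    memo: dict[str, object] = {}
    sphere_info = _state(SPHERE_INFO_MASSES)

    def form_flat(s):
        return elaborate(s, _flat_info(), strength=FLAT_STRENGTH)

    def to_disk(s):
        compacted = compact_form(_as_concept(s, "flat"), DISK_COMPACT_THRESHOLD)
        out = elaborate(compacted, _state(DISK_INFO_MASSES),
                        strength=DISK_STRENGTH)
        memo["disk_expanded"] = out
        return out

    def to_dual(s):
        compacted = compact_form(_as_concept(s, "disk"), DUAL_COMPACT_THRESHOLD)
        # the sphere idea barely overlaps the disk representation, so it
        # cannot be elaborated in; it is held unintegrated instead
        overlap = abs(inner(sphere_info, compacted))
        if overlap >= NEGLIGIBLE_OVERLAP:
            raise AssertionError(
                f"sphere info unexpectedly integrable (overlap {overlap:.3f})"
            )
        return combine_unintegrated(compacted, sphere_info)

    def to_sphere(dual):
        # the shape question touches both factors and the answers contradict
        ans = joint_question(
            dual,
            projector(EARTH_BASIS, ("flat", "round")),
            projector(EARTH_BASIS, ("sphere",)),
            contradictory_pairs=[("flat", "sphere")],
        )
        memo["dual_question"] = ans
        if not ans.incompatible:
            raise AssertionError("Dual-Earth shape question should be unanswerable")
        # redescription: elaborate the *expanded* disk form with the sphere idea
        return elaborate(memo["disk_expanded"], _state(SPHERE_I_INFO_MASSES),
                         strength=SPHERE_I_STRENGTH)

    def play(s):
        return elaborate(s, _state(BALLOON_I_INFO_MASSES),
                         strength=BALLOON_I_STRENGTH)

    steps = [
        ChangeStep("No earth model to flat earth", "IL", form_flat, "15", "Flat"),
        ChangeStep("Flat earth to disk earth", "SL", to_disk, "2", "Disk"),
        ChangeStep("Disk earth to dual earth", "SL", to_dual, "2, 4", "Dual"),
        ChangeStep("Dual earth to spherical earth", "RR", to_sphere, "6", "Sphere"),
        ChangeStep("Pretend red balloon is mars", "SL", play, "2", "Sphere"),
    ]
    return initial_state(), steps, environment()


def child_j_fixture() -> tuple[StateVector, list[ChangeStep], Environment]:
    """Child j: Flat → Hollow → Mars/planet chain → Sphere → play (9 steps)."""

    def form_flat(s):
        return elaborate(s, _flat_info(), strength=FLAT_STRENGTH)

    def to_hollow(s):
        return elaborate(s, _state(HOLLOW_INFO_MASSES), strength=HOLLOW_STRENGTH)

    def mars_is_planet(s):
        return elaborate(s, _state(MARS_PLANET_INFO_MASSES),
                         strength=MARS_PLANET_STRENGTH)

    def planet_is_sphere(s):
        return elaborate(s, _state(PLANET_SPHERE_INFO_MASSES),
                         strength=PLANET_SPHERE_STRENGTH)

    def earth_is_planet(s):
        return elaborate(s, _state(EARTH_PLANET_INFO_MASSES),
                         strength=EARTH_PLANET_STRENGTH)

    def earth_is_sphere(s):
        planet = Concept("planet", _state(PLANET_CONCEPT_MASSES),
                         OBSERVATION_LABELS)
        return project_compare(planet, _as_concept(s, "earth"))

    def mars_red_sphere(s):
        return elaborate(s, _state(MARS_RED_INFO_MASSES),
                         strength=MARS_RED_STRENGTH)

    def balloon_red_sphere(s):
        return elaborate(s, _state(BALLOON_J_INFO_MASSES),
                         strength=BALLOON_J_STRENGTH)

    def pretend_play(s):
        return apply_context(s, Context("pretend_play", PLAY_CONTEXT_LABELS))

    steps = [
        ChangeStep("No earth model to flat earth", "IL", form_flat, "15", "Flat"),
        ChangeStep("Flat earth to hollow earth", "RR", to_hollow, "2", "Hollow"),
        ChangeStep("Mars is a planet", "SL", mars_is_planet, "2", "Hollow"),
        ChangeStep("Planet is a solid sphere", "SL", planet_is_sphere, "2", "Hollow"),
        ChangeStep("Earth is a planet", "SL", earth_is_planet, "2", "Hollow"),
        ChangeStep("Earth is a sphere", "RR", earth_is_sphere, "18", "Sphere"),
        ChangeStep("Mars is red, spherical", "SL", mars_red_sphere, "2", "Sphere"),
        ChangeStep("Balloon is red, spherical", "IL", balloon_red_sphere, "2", "Sphere"),
        ChangeStep("Pretend red balloon is mars", "RR", pretend_play, "5", "Sphere"),
    ]
    return initial_state(), steps, environment()


#: the printed arrow patterns the calibration reproduces
CHILD_I_ARROWS = (
    ("↑", "−", "−"),
    ("−", "↓", "−"),
    ("−", "↓", "−"),
    ("↑", "↑", "−"),
    ("−", "−", "−"),
)

CHILD_J_ARROWS = (
    ("↑", "−", "−"),
    ("−", "↓", "−"),
    ("−", "−", "−"),
    ("↓", "−", "−"),
    ("↑", "−", "−"),
    ("↑", "↑", "−"),
    ("↓", "−", "−"),
    ("↓", "−", "−"),
    ("↓", "↑", "↑"),
)

#: index of the state representing each child's consolidated Sphere model
#: (child j's final step is a pretend-play projection of that model)
CHILD_I_SPHERE_INDEX = 5
CHILD_J_SPHERE_INDEX = 8


def run_child_i() -> Trajectory:
    init, steps, env = child_i_fixture()
    return run_trajectory(init, steps, env)


def run_child_j() -> Trajectory:
    init, steps, env = child_j_fixture()
    return run_trajectory(init, steps, env)


def earth_model_states() -> dict[str, object]:
    """The distinct mental-model representations visited in the case study,
    keyed as ``<child>_<tag>``. Dual is a joint (tensor-product) state; all
    others are plain superpositions."""
    out: dict[str, object] = {}
    for child, traj in (("child_i", run_child_i()), ("child_j", run_child_j())):
        for step, state in zip(traj.steps, traj.states[1:]):
            key = f"{child}_{step.model_tag}"
            if step.model_tag and key not in out:
                out[key] = state
    return out


def export_model_concepts(directory) -> list[str]:
    """Write each single-state Earth model as a concept JSON file; returns
    the filenames written. The Dual model, being a joint state, has no
    single-concept serialization and is skipped."""
    import json
    from pathlib import Path

    from . import io as _io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, state in earth_model_states().items():
        if not isinstance(state, StateVector):
            continue
        doc = _io.concept_to_json(
            Concept(name, state, OBSERVATION_LABELS)
        )
        fname = f"{name}.json"
        (directory / fname).write_text(
            json.dumps(doc, indent=2), encoding="utf-8"
        )
        written.append(fname)
    return written
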