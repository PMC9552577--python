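"""Conceptual-change trajectories.

A trajectory is an ordered sequence of change steps applied to a mental
state. Each step records its source — individual learning (IL), social
learning (SL), or representational redescription (RR) — and the profile
(γ_A, γ_D, γ_C) of the state before and after, so the qualitative pattern
of change can be rendered as an arrow table.

States along a trajectory may be plain superpositions or joint
(tensor-product) representations of unintegrated knowledge. For a joint
state the three measures are evaluated with each observable lifted to act
on the primary factor (M̂ → M̂ ⊗ Î), i.e. on the reduced state of the
representation under change; the unintegrated appended fact does not enter
the measures until it is redescribed into the representation itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd

from .algebra import ProductState, StateVector
from .concepts import Context
from .dimensions import (
    ARROW_TOL,
    DimensionProfile,
    DivergenceObservable,
    ObservationSet,
    delta_profile,
)
from .errors import FixtureError, NumericalError

#: allowed change-step sources
SOURCES = ("IL", "SL", "RR")

#: allowed mental-model tags for the Earth case study
MODEL_TAGS = ("Flat", "Disk", "Dual", "Hollow", "FlattenedSphere", "Sphere", "Mixed")

Representation = Union[StateVector, ProductState]


@dataclass(frozen=True)
class Environment:
    """The fixed backdrop against which profiles are computed: what counts
    as a direct observation, the current goal context, and the salient-
    feature observable."""

    observations: ObservationSet
    context: Context
    divergence: DivergenceObservable

    def profile_of(self, rep: Representation) -> DimensionProfile:
        if isinstance(rep, StateVector):
            from .dimensions import profile

            return profile(rep, self.observations, self.context, self.divergence)
        return self._profile_product(rep)

    def _profile_product(self, p: ProductState) -> DimensionProfile:
        # expectations of M ⊗ I reduce to tr(M ρ_A) with ρ_A = A A†
        m = p.joint_amplitudes
        rho = m @ m.conj().T
        _check_env_basis(self.observations.basis, p.basis_a)
        alpha = self.observations.operator().matrix
        ctx_op = self.context.operator(p.basis_a).matrix
        b = self.divergence.operator().matrix
        g_obs = float(np.trace(alpha @ rho).real)
        g_c = float(np.trace(ctx_op @ rho).real)
        eb = float(np.trace(b @ rho).real)
        eb2 = float(np.trace(b @ b @ rho).real)
        var = eb2 - eb**2
        if var < -1e-12:
            raise NumericalError(f"negative variance {var}")
        return DimensionProfile(
            gamma_A=float(min(max(1.0 - g_obs, 0.0), 1.0)),
            gamma_D=float(np.sqrt(max(var, 0.0))),
            gamma_C=g_c,
        )


def _check_env_basis(env_basis, state_basis):
    """The environment's operators must live on the state's basis."""
    if env_basis.labels != state_basis.labels:
        raise FixtureError("environment basis does not match state basis")


@dataclass(frozen=True)
class MentalModel:
    """A tagged mental model of the Earth's shape.

    The Dual model is intrinsically a joint (tensor-product) representation;
    all other models are plain superpositions.
    """

    tag: str
    representation: Representation

    def __post_init__(self):
        if self.tag not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {self.tag!r}")
        if self.tag == "Dual" and not isinstance(self.representation, ProductState):
            raise ValueError("a Dual model must be a ProductState")
        if self.tag != "Dual" and not isinstance(self.representation, StateVector):
            raise ValueError(f"a {self.tag} model must be a StateVector")


@dataclass(frozen=True)
class ChangeStep:
    """One conceptual-change transition.

    ``operation`` maps the current representation to the next one;
    ``equation`` is a short tag naming the mechanism the step uses (for the
    arrow table); ``model_tag`` optionally names the mental model the child
    holds after the step.
    """

    description: str
    source: str
    operation: Callable[[Representation], Representation]
    equation: str = ""
    model_tag: str | None = None
    expected_arrows: tuple[str, str, str] | None = None

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")


@dataclass(frozen=True)
class Trajectory:
    """An executed trajectory: the visited states and their profiles."""

    steps: tuple[ChangeStep, ...]
    states: tuple[Representation, ...]
    profiles: tuple[DimensionProfile, ...]
    environments: tuple[Environment, ...]

    def __post_init__(self):
        if len(self.states) != len(self.steps) + 1:
            raise ValueError("need exactly one state per step plus the initial state")
        if len(self.profiles) != len(self.states):
            raise ValueError("need one profile per state")

    @property
    def initial_state(self) -> Representation:
        return self.states[0]

    @property
    def final_state(self) -> Representation:
        return self.states[-1]

    def models(self) -> list[MentalModel | None]:
        """The tagged mental model after each step (None where untagged)."""
        out: list[MentalModel | None] = []
        for step, state in zip(self.steps, self.states[1:]):
            out.append(
                MentalModel(step.model_tag, state) if step.model_tag else None
            )
        return out

    @property
    def final_model(self) -> MentalModel | None:
        for step, state in zip(reversed(self.steps), reversed(self.states[1:])):
            if step.model_tag:
                return MentalModel(step.model_tag, state)
        return None


class StepError(RuntimeError):
    """A step's operation failed; carries the step index."""

    def __init__(self, index: int, step: ChangeStep, cause: Exception):
        super().__init__(f"step {index + 1} ({step.description!r}) failed: {cause}")
        self.index = index
        self.step = step
        self.__cause__ = cause


def run_trajectory(
    initial: Representation,
    steps: Sequence[ChangeStep],
    environment: Environment | Sequence[Environment],
) -> Trajectory:
    """Apply the steps in order, recording each state's profile.

    ``environment`` may be one Environment (used throughout) or one per
    state. Deterministic: no sampling is involved.
    """
    steps = tuple(steps)
    if isinstance(environment, Environment):
        envs = tuple([environment] * (len(steps) + 1))
    else:
        envs = tuple(environment)
        if len(envs) != len(steps) + 1:
            raise ValueError("need one environment per state")
    states: list[Representation] = [initial]
    for i, step in enumerate(steps):
        try:
            states.append(step.operation(states[-1]))
        except Exception as exc:  # attach the step index for diagnosis
            raise StepError(i, step, exc) from exc
    profiles = tuple(env.profile_of(s) for env, s in zip(envs, states))
    return Trajectory(steps, tuple(states), profiles, envs)


def arrow_table(traj: Trajectory, tol: float = ARROW_TOL) -> pd.DataFrame:
    """Render a trajectory as an arrow table (one row per step).

    Columns: step, description, source, equation, and the three arrow
    columns gamma_A / gamma_D / gamma_C with values in {↑, ↓, −}.
    """
    rows = []
    for i, step in enumerate(traj.steps):
        arrows = delta_profile(traj.profiles[i], traj.profiles[i + 1], tol)
        rows.append(
            {
                "step": i + 1,
                "description": step.description,
                "source": step.source,
                "equation": step.equation,
                "gamma_A": arrows[0],
                "gamma_D": arrows[1],
                "gamma_C": arrows[2],
            }
        )
    return pd.DataFrame(rows)


def profile_table(traj: Trajectory, tol: float = ARROW_TOL) -> pd.DataFrame:
    """Numeric companion to :func:`arrow_table`: per-step profiles and
    deltas (columns step, source, gamma_A, gamma_D, gamma_C, d_gamma_A,
    d_gamma_D, d_gamma_C)."""
    rows = []
    for i, step in enumerate(traj.steps):
        before, after = traj.profiles[i], traj.profiles[i + 1]
        rows.append(
            {
                "step": i + 1,
                "source": step.source,
                "gamma_A": after.gamma_A,
                "gamma_D": after.gamma_D,
                "gamma_C": after.gamma_C,
                "d_gamma_A": after.gamma_A - before.gamma_A,
                "d_gamma_D": after.gamma_D - before.gamma_D,
                "d_gamma_C": after.gamma_C - before.gamma_C,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mental-model frequency table (the developmental cross-section)


@dataclass(frozen=True)
class FrequencyTable:
    """Counts of children holding each Earth-shape mental model, by grade."""

    counts: pd.DataFrame = field(repr=False)  # index: model, columns: grades

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise FixtureError("frequency counts must be non-negative")

    @property
    def row_marginals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def column_marginals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())


def load_frequency_fixture(path=None) -> FrequencyTable:
    """Load the packaged mental-model frequency table (or one from ``path``).

    The CSV has columns model, grade1, grade3, grade5 and, optionally, a
    declared ``total`` column and a declared ``Total`` row; grades/models
    with zero counts are explicit zero cells. Declared marginals are
    verified against recomputed sums on load, and any inconsistency is
    reported with the offending row or column named.
    """
    try:
        if path is None:
            ref = resources.files("mindmodes.data").joinpath(
                "earth_model_frequencies.csv"
            )
            with resources.as_file(ref) as f:
                df = pd.read_csv(f)
        else:
            df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise FixtureError(f"cannot read frequency fixture: {exc}") from exc
    grade_cols = ["grade1", "grade3", "grade5"]
    if list(df.columns) not in (
        ["model"] + grade_cols,
        ["model"] + grade_cols + ["total"],
    ):
        raise FixtureError(
            "frequency fixture must have columns model, grade1, grade3, "
            f"grade5[, total]; got {list(df.columns)}"
        )
    if df["model"].duplicated().any():
        raise FixtureError("duplicate model rows in frequency fixture")
    df = df.set_index("model")
    declared_col_totals = None
    if "Total" in df.index:
        declared_col_totals = df.loc["Total"]
        df = df.drop(index="Total")
    declared_row_totals = df["total"] if "total" in df.columns else None
    counts = df[grade_cols]
    if not np.issubdtype(counts.values.dtype, np.integer):
        raise FixtureError("frequency counts must be integers")
    table = FrequencyTable(counts)
    if declared_row_totals is not None:
        for model, declared in declared_row_totals.items():
            got = int(table.row_marginals[model])
            if got != int(declared):
                raise FixtureError(
                    f"row marginal for model {model!r} is {got}, "
                    f"but the fixture declares {int(declared)}"
                )
    if declared_col_totals is not None:
        for col in grade_cols:
            got = int(table.column_marginals[col])
            if got != int(declared_col_totals[col]):
                raise FixtureError(
                    f"column marginal for {col!r} is {got}, "
                    f"but the fixture declares {int(declared_col_totals[col])}"
                )
        if "total" in declared_col_totals.index and declared_row_totals is not None:
            if table.total != int(declared_col_totals["total"]):
                raise FixtureError(
                    f"grand total is {table.total}, but the fixture declares "
                    f"{int(declared_col_totals['total'])}"
                )
    return table
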