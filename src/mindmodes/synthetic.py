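"""Seeded random generation of concept spaces, contexts and trajectories.

Used to property-test every operation without external data. Squared
amplitudes are drawn from a symmetric Dirichlet distribution whose
concentration parameter controls the weight spread: a low concentration
yields peaked, convergent-like states, a high one near-uniform,
divergent-like states. Phases are zero by default, with an option for
uniform random phases to exercise the complex path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .algebra import Basis, StateVector, normalize
from .concepts import Concept, Context, apply_context, compact_form, elaborate
from .errors import AnnihilationError
from .dimensions import DivergenceObservable, ObservationSet
from .trajectory import ChangeStep, Environment, Trajectory, run_trajectory


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic concept-space generator."""

    n_features: int = 8
    n_observations: int = 3
    concentration: float = 1.0
    context_size: int = 2
    n_steps: int = 4
    seed: int = 0
    random_phases: bool = False

    def __post_init__(self):
        if self.n_features < 2:
            raise ValueError("n_features must be at least 2")
        if not (1 <= self.n_observations <= self.n_features):
            raise ValueError("n_observations must lie in [1, n_features]")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.context_size < 1:
            raise ValueError("context_size must be at least 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")

    def basis(self) -> Basis:
        return Basis(f"f{i}" for i in range(self.n_features))

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def random_concept(config: GeneratorConfig, salt: int = 0) -> Concept:
    """A random concept: Dirichlet-distributed squared amplitudes; the first
    ``n_observations`` labels are flagged as observations."""
    rng = config.rng(salt)
    basis = config.basis()
    probs = rng.dirichlet([config.concentration] * config.n_features)
    amps = np.sqrt(probs).astype(complex)
    if config.random_phases:
        amps = amps * np.exp(2j * np.pi * rng.random(config.n_features))
    state = normalize(StateVector(basis, amps))
    obs = basis.labels[: config.n_observations]
    return Concept(f"synthetic-{config.seed}-{salt}", state, obs)


def random_context(config: GeneratorConfig, salt: int = 0) -> Context:
    """A uniformly sampled label subset of size ``context_size``."""
    if config.context_size > config.n_features:
        raise ValueError("context_size cannot exceed n_features")
    rng = config.rng(1000 + salt)
    basis = config.basis()
    labels = rng.choice(
        basis.labels, size=config.context_size, replace=False
    )
    return Context(f"ctx-{config.seed}-{salt}", tuple(sorted(labels)))


def random_environment(config: GeneratorConfig) -> Environment:
    basis = config.basis()
    obs = ObservationSet(basis, basis.labels[: config.n_observations])
    ctx = random_context(config)
    # a proper salient subset keeps the divergence spectrum non-trivial
    n_sal = max(1, config.n_features - 1)
    obsv = DivergenceObservable(
        basis, mode="projector", salient_labels=basis.labels[:n_sal]
    )
    return Environment(observations=obs, context=ctx, divergence=obsv)


def random_trajectory(config: GeneratorConfig) -> Trajectory:
    """A fuzzing trajectory alternating elaboration, context application
    and compaction, with randomly drawn arguments."""
    env = random_environment(config)
    init = random_concept(config, salt=900_000).state
    steps: list[ChangeStep] = []
    for k in range(config.n_steps):
        kind = k % 3
        if kind == 0:
            info = random_concept(config, salt=k + 1).state

            def op(s, info=info):
                return elaborate(s, info)

            steps.append(ChangeStep(f"elaborate-{k}", "IL", op, "2"))
        elif kind == 1:
            ctx = random_context(config, salt=k + 1)

            def op(s, ctx=ctx):
                try:
                    return apply_context(s, ctx)
                except AnnihilationError:
                    return s  # context irrelevant to this thought; no change

            steps.append(ChangeStep(f"context-{k}", "RR", op, "5"))
        else:
            thr = 0.5 + 0.5 * float(config.rng(2000 + k).random())

            def op(s, thr=thr):
                return compact_form(
                    Concept("tmp", s, s.basis.labels[: config.n_observations]),
                    thr,
                )

            steps.append(ChangeStep(f"compact-{k}", "SL", op, "8"))
    return run_trajectory(init, steps, env)
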