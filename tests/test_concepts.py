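"""Concept semantics: typicality, elaboration, contexts, compact/expanded
forms, cross-concept projection and two-part questions."""

import numpy as np
import pytest

from mindmodes.algebra import (
    Basis,
    LinearOperator,
    StateVector,
    expectation,
    inner,
    normalize,
    projector,
)
from mindmodes.concepts import (
    Concept,
    Context,
    apply_context,
    combine_unintegrated,
    compact_form,
    elaborate,
    expanded_form,
    joint_question,
    project_compare,
    typicality,
)
from mindmodes.algebra import separability_test
from mindmodes.errors import (
    AnnihilationError,
    HermitianityError,
    UnknownLabelError,
)
from mindmodes.io import load_bundled_concepts, load_bundled_contexts
from .conftest import random_state


@pytest.fixture(scope="module")
def concepts():
    return load_bundled_concepts()


@pytest.fixture(scope="module")
def contexts():
    return load_bundled_contexts()


class TestTypicality:
    def test_pure_instance_fully_typical_of_itself(self):
        b = Basis(["sparrow", "penguin"])
        c = Concept("sparrow", StateVector.from_dict(b, {"sparrow": 1}))
        assert typicality(c, "sparrow") == pytest.approx(1.0)

    def test_absent_label_zero(self):
        b = Basis(["sparrow", "penguin"])
        c = Concept("sparrow", StateVector.from_dict(b, {"sparrow": 1}))
        assert typicality(c, "penguin") == 0.0

    def test_reads_off_amplitude_magnitude(self):
        b = Basis(["sparrow", "penguin"])
        c = Concept("bird", StateVector(b, [0.6, 0.8]))
        assert typicality(c, "sparrow") == pytest.approx(0.6)
        with pytest.raises(UnknownLabelError):
            typicality(c, "ostrich")

    def test_salience_order_ties_break_lexicographically(self):
        b = Basis(["b", "a", "c"])
        c = Concept("t", normalize(StateVector(b, [1, 1, 2])))
        assert c.salience_order == ("c", "a", "b")


class TestElaborate:
    def test_orthogonal_information_is_identity(self, basis4, rng):
        for _ in range(25):
            s = random_state(basis4, rng)
            # random state orthogonalized against s
            raw = random_state(basis4, rng)
            ortho = normalize(
                StateVector(
                    basis4, raw.amplitudes - inner(s, raw) * s.amplitudes
                )
            )
            out = elaborate(s, ortho)
            np.testing.assert_allclose(out.amplitudes, s.amplitudes, atol=1e-9)

    def test_information_equal_to_state_is_fixed_direction(self, basis4, rng):
        s = random_state(basis4, rng)
        raw = elaborate(s, s, renormalize=False)
        np.testing.assert_allclose(raw.amplitudes, 2 * s.amplitudes, atol=1e-12)
        out = elaborate(s, s)
        np.testing.assert_allclose(out.amplitudes, s.amplitudes, atol=1e-12)

    def test_equal_superposition_pulled_toward_information(self):
        # |Ψ⟩=(|x⟩+|y⟩)/√2 elaborated with |x⟩ → (2/√5, 1/√5)
        b = Basis(["x", "y"])
        s = normalize(StateVector(b, [1, 1]))
        out = elaborate(s, StateVector.from_dict(b, {"x": 1}))
        np.testing.assert_allclose(
            out.amplitudes, [2 / np.sqrt(5), 1 / np.sqrt(5)], atol=1e-12
        )

    def test_mass_on_information_direction_never_decreases(self, basis4, rng):
        for _ in range(25):
            s = random_state(basis4, rng)
            a = random_state(basis4, rng)
            before = abs(inner(a, s)) ** 2
            after = abs(inner(a, elaborate(s, a))) ** 2
            assert after >= before - 1e-12

    def test_strength_equals_iterated_operator(self, basis4, rng):
        # applying U_A twice equals a single application with strength 3
        s = random_state(basis4, rng)
        a = random_state(basis4, rng)
        twice = elaborate(elaborate(s, a), a)
        once = elaborate(s, a, strength=3.0)
        np.testing.assert_allclose(twice.amplitudes, once.amplitudes, atol=1e-9)


class TestCombineUnintegrated:
    def test_disk_sphere_tensor_is_dual_model(self):
        b = Basis(["flat", "round", "sphere"])
        disk = normalize(StateVector(b, [0.8, 0.6, 0]))
        sphere = StateVector.from_dict(b, {"sphere": 1})
        assert abs(inner(sphere, disk)) == pytest.approx(0.0)
        dual = combine_unintegrated(disk, sphere)
        assert dual.is_normalized
        assert separability_test(dual).is_separable

    def test_norm_of_combined_state_is_one(self, basis4, rng):
        dual = combine_unintegrated(
            random_state(basis4, rng), random_state(basis4, rng)
        )
        assert dual.norm == pytest.approx(1.0)


class TestApplyContext:
    def test_blanket_bedtime_reads_off_amplitudes(self, concepts, contexts):
        # Ĉ_s|blanket⟩ = b1|warm⟩ + b2|soft⟩ without renormalization
        blanket = concepts["blanket"].state
        out = apply_context(blanket, contexts["bedtime"], renormalize=False)
        assert out.support() == ("warm", "soft")
        assert out.amplitude("warm") == pytest.approx(blanket.amplitude("warm"))
        assert out.amplitude("soft") == pytest.approx(blanket.amplitude("soft"))

    def test_dog_hunting_context_restricts_support(self, concepts, contexts):
        out = apply_context(concepts["dog"].state, contexts["hunting"])
        assert out.support() == ("hunt", "smell")
        # renormalized output lies entirely in the context subspace
        p = projector(out.basis, ("hunt", "smell"))
        assert expectation(out, p) == pytest.approx(1.0)

    def test_leaky_context_keeps_extra_feature(self, concepts, contexts):
        out = apply_context(concepts["dog"].state, contexts["hunting_leaky"])
        assert out.support() == ("rollover", "hunt", "smell")

    def test_full_basis_context_is_identity(self, concepts):
        dog = concepts["dog"].state
        ctx = Context("everything", dog.basis.labels)
        out = apply_context(dog, ctx)
        np.testing.assert_allclose(out.amplitudes, dog.amplitudes, atol=1e-12)

    def test_orthogonal_context_annihilates(self, concepts, contexts):
        b = load_bundled_concepts()["dog"].basis
        s = StateVector.from_dict(b, {"furry": 1})
        with pytest.raises(AnnihilationError):
            apply_context(s, contexts["hunting"])

    def test_output_always_in_context_subspace(self, basis4, rng):
        ctx = Context("wx", ("w", "x"))
        p = projector(basis4, ("w", "x"))
        for _ in range(25):
            s = random_state(basis4, rng)
            try:
                out = apply_context(s, ctx)
            except AnnihilationError:
                continue
            assert expectation(out, p) == pytest.approx(1.0, abs=1e-9)


class TestCompactAndExpandedForms:
    def test_island_compact_keeps_land_and_water(self, concepts):
        out = compact_form(concepts["island"], 0.95)
        assert out.support() == ("land", "water")

    def test_threshold_one_returns_expanded_state(self, concepts):
        island = concepts["island"]
        out = compact_form(island, 1.0)
        np.testing.assert_allclose(
            out.amplitudes, expanded_form(island).amplitudes, atol=1e-12
        )

    def test_uniform_state_half_mass_keeps_half_labels(self):
        b = Basis([f"f{i}" for i in range(10)])
        c = Concept("u", normalize(StateVector(b, np.ones(10))))
        assert len(compact_form(c, 0.5).support()) == 5

    def test_mass_coverage_and_minimality(self, basis4, rng):
        for _ in range(50):
            c = Concept("r", random_state(basis4, rng))
            thr = float(rng.uniform(0.3, 0.99))
            kept = compact_form(c, thr).support()
            probs = {lab: p for lab, p in zip(basis4.labels, c.state.probabilities())}
            mass = sum(probs[lab] for lab in kept)
            assert mass >= thr - 1e-9
            # dropping the least salient kept label breaks the bound
            least = min(kept, key=lambda lab: (probs[lab], lab))
            assert mass - probs[least] < thr

    def test_expanded_support_contains_compact_support(self, concepts):
        for c in concepts.values():
            full = set(expanded_form(c).support())
            for thr in (0.5, 0.8, 0.95):
                assert set(compact_form(c, thr).support()) <= full


class TestProjectCompare:
    def test_identical_concepts_identity_map_preserve_direction(self, concepts):
        dog = concepts["dog"]
        out = project_compare(dog, dog)
        # amplitudes get squared elementwise then renormalized
        expected = normalize(
            StateVector(dog.basis, dog.state.amplitudes**2)
        )
        np.testing.assert_allclose(out.amplitudes, expected.amplitudes, atol=1e-12)

    def test_disjoint_label_sets_annihilate(self):
        a = Concept("a", StateVector(Basis(["p", "q"]), [0.6, 0.8]))
        b = Concept("b", StateVector(Basis(["r", "s"]), [0.6, 0.8]))
        with pytest.raises(AnnihilationError):
            project_compare(a, b)

    def test_single_shared_feature_concentrates_there(self):
        planet = Concept(
            "planet", normalize(StateVector(Basis(["sphere", "orbits"]), [0.8, 0.6]))
        )
        earth = Concept(
            "earth", normalize(StateVector(Basis(["sphere", "ground"]), [0.3, 0.954]))
        )
        out = project_compare(planet, earth)
        # hand-computed double sum: only the sphere term survives
        assert out.support() == ("sphere",)
        assert out.amplitude("sphere") == pytest.approx(1.0)

    def test_matches_bruteforce_double_sum(self, concepts):
        # independent oracle: overlap matrix evaluation of Σ_ij p_i e_j ⟨j|i⟩|j⟩
        small = {k: c for k, c in concepts.items() if c.basis.dimension <= 8}
        compared = 0
        for src in small.values():
            for tgt in small.values():
                m = np.array(
                    [
                        [1.0 if i == j else 0.0 for i in src.basis.labels]
                        for j in tgt.basis.labels
                    ]
                )
                raw = tgt.state.amplitudes * (m @ src.state.amplitudes)
                if np.linalg.norm(raw) < 1e-9:
                    with pytest.raises(AnnihilationError):
                        project_compare(src, tgt)
                    continue
                expected = raw / np.linalg.norm(raw)
                out = project_compare(src, tgt)
                np.testing.assert_allclose(out.amplitudes, expected, atol=1e-12)
                compared += 1
        assert compared >= 10

    def test_explicit_correspondence_overrides_default(self):
        a = Concept("a", StateVector(Basis(["p"]), [1.0]))
        b = Concept("b", StateVector(Basis(["r"]), [1.0]))
        out = project_compare(a, b, basis_map={("p", "r"): 0.5})
        assert out.amplitude("r") == pytest.approx(1.0)


class TestJointQuestion:
    @pytest.fixture
    def dual(self):
        b = Basis(["flat", "round", "sphere"])
        disk = normalize(StateVector(b, [0.8, 0.6, 0]))
        sphere = StateVector.from_dict(b, {"sphere": 1})
        return combine_unintegrated(disk, sphere)

    def test_single_factor_question_gives_marginal(self, dual):
        b = dual.basis_a
        ans = joint_question(
            dual, projector(b, ("flat", "round")), LinearOperator.identity(b)
        )
        marg = ans.marginal("a")
        assert marg["flat"] == pytest.approx(0.64)
        assert marg["round"] == pytest.approx(0.36)
        assert not ans.incompatible

    def test_contradictory_shape_question_unanswerable(self, dual):
        b = dual.basis_a
        ans = joint_question(
            dual,
            projector(b, ("flat", "round")),
            projector(b, ("sphere",)),
            contradictory_pairs=[("flat", "sphere")],
        )
        assert ans.incompatible
        assert ans.contradiction_mass >= 0.5

    def test_certain_compatible_factors_single_outcome(self):
        b = Basis(["yes", "no"])
        sure = StateVector.from_dict(b, {"yes": 1})
        joint = combine_unintegrated(sure, sure)
        ans = joint_question(
            joint, projector(b, ("yes",)), projector(b, ("yes",)),
            contradictory_pairs=[("yes", "no")],
        )
        assert ans.probabilities == {("yes", "yes"): pytest.approx(1.0)}
        assert not ans.incompatible

    def test_non_projector_observable_rejected(self, dual):
        b = dual.basis_a
        m = np.eye(3, dtype=complex) * 2.0
        with pytest.raises(HermitianityError):
            joint_question(dual, LinearOperator(b, m), LinearOperator.identity(b))
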