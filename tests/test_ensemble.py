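"""Amino-acid aggregation, backbone weighting, enrichment, full pipeline."""

import math

import numpy as np
import pytest

from scmfpep import (
    AA_INDEX,
    EnsembleAggregate,
    MFParameters,
    MFState,
    ProbabilityMatrix,
    SpecificityProfile,
    ValidationError,
    aa_probabilities,
    backbone_aa_energies,
    backbone_weights,
    combine_backbones,
    enrich_over_background,
    predict_specificity,
)
from scmfpep.interaction_model import N_AA
from scmfpep.synthetic import ToyEnergyModel, generate_ensemble, generate_toy_graph

from conftest import make_graph, random_profile


def state_with(P_rows, E_rows):
    """Fabricate a final MFState with prescribed probabilities/energies."""
    return MFState(
        P=ProbabilityMatrix([np.asarray(r, dtype=float) for r in P_rows]),
        E=[np.asarray(e, dtype=float) for e in E_rows],
        iterations=1,
        converged=True,
        residual=0.0,
    )


@pytest.fixture
def multiplicity_graph():
    """One position: A with 1 rotamer, C with 5 rotamers."""
    return make_graph([[0.0] * 6], ["ACCCCC"])


@pytest.fixture
def multiplicity_state():
    """Rotamer probabilities 0.5 for A's rotamer, 0.1 for each of C's."""
    return state_with([[0.5] + [0.1] * 5], [[0.0] * 6])


class TestAaProbabilities:
    def test_gamma_zero_sums_rotamer_probabilities(
        self, multiplicity_graph, multiplicity_state
    ):
        table = aa_probabilities(multiplicity_state, multiplicity_graph, gamma=0.0)
        assert table[0, AA_INDEX["A"]] == pytest.approx(0.5)
        assert table[0, AA_INDEX["C"]] == pytest.approx(0.5)

    def test_gamma_one_averages_rotamer_probabilities(
        self, multiplicity_graph, multiplicity_state
    ):
        table = aa_probabilities(multiplicity_state, multiplicity_graph, gamma=1.0)
        assert table[0, AA_INDEX["A"]] == pytest.approx(5 / 6)
        assert table[0, AA_INDEX["C"]] == pytest.approx(1 / 6)

    def test_gamma_0_8_hand_value(self, multiplicity_graph, multiplicity_state):
        table = aa_probabilities(multiplicity_state, multiplicity_graph, gamma=0.8)
        expected_a = 0.5 / (0.5 + 0.5 / 5**0.8)
        assert table[0, AA_INDEX["A"]] == pytest.approx(expected_a, abs=1e-12)
        assert expected_a == pytest.approx(0.7838, abs=1e-4)

    @pytest.mark.parametrize("gamma", [0.0, 0.37, 1.0])
    def test_single_rotamer_amino_acids_make_gamma_inert(self, gamma):
        g = make_graph([[0.0, 0.0, 0.0]], ["ACD"])
        state = state_with([[0.2, 0.3, 0.5]], [[0.0] * 3])
        table = aa_probabilities(state, g, gamma)
        assert table[0, AA_INDEX["A"]] == pytest.approx(0.2)
        assert table[0, AA_INDEX["C"]] == pytest.approx(0.3)
        assert table[0, AA_INDEX["D"]] == pytest.approx(0.5)

    def test_absent_amino_acids_are_exactly_zero(
        self, multiplicity_graph, multiplicity_state
    ):
        table = aa_probabilities(multiplicity_state, multiplicity_graph, gamma=0.5)
        present = np.zeros(N_AA, dtype=bool)
        present[[AA_INDEX["A"], AA_INDEX["C"]]] = True
        assert np.all(table[0, ~present] == 0.0)
        assert table[0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_gamma_out_of_range_rejected(self, multiplicity_graph, multiplicity_state):
        with pytest.raises(ValidationError):
            aa_probabilities(multiplicity_state, multiplicity_graph, gamma=1.5)

    def test_multiplicity_inflation_made_exact(self):
        # X (here S) has twice the rotamers of Y (here A), all converged to
        # the same probability: gamma=0 doubles X, gamma=1 equalises.
        g = make_graph([[0.0, 0.0, 0.0]], ["SSA"])
        state = state_with([[1 / 3, 1 / 3, 1 / 3]], [[0.0] * 3])
        g0 = aa_probabilities(state, g, 0.0)
        assert g0[0, AA_INDEX["S"]] == pytest.approx(2 * g0[0, AA_INDEX["A"]])
        g1 = aa_probabilities(state, g, 1.0)
        assert g1[0, AA_INDEX["S"]] == pytest.approx(g1[0, AA_INDEX["A"]])


class TestBackboneAaEnergies:
    def test_single_rotamer_amino_acid(self):
        g = make_graph([[0.0]], ["A"])
        state = state_with([[1.0]], [[2.0]])
        for gamma in (0.0, 0.8, 1.0):
            table = backbone_aa_energies(state, g, gamma)
            assert table[0, AA_INDEX["A"]] == pytest.approx(2.0)

    def test_probability_weighted_sum(self):
        g = make_graph([[0.0, 0.0]], ["CC"])
        state = state_with([[0.75, 0.25]], [[0.0, 4.0]])
        table = backbone_aa_energies(state, g, gamma=0.0)
        assert table[0, AA_INDEX["C"]] == pytest.approx(1.0)

    def test_zero_energies_give_zero_table(self, multiplicity_graph, multiplicity_state):
        table = backbone_aa_energies(multiplicity_state, multiplicity_graph, 0.8)
        np.testing.assert_array_equal(table, 0.0)


class TestBackboneWeights:
    def test_single_backbone_weight_is_one(self):
        w = backbone_weights([np.zeros((3, N_AA))], kT=0.6)
        np.testing.assert_array_equal(w, 1.0)

    def test_equal_energy_sums_split_evenly(self):
        t = np.ones((2, N_AA))
        w = backbone_weights([t, t], kT=0.6)
        np.testing.assert_allclose(w, 0.5)

    def test_two_state_closed_form(self):
        kT = 0.45
        t0 = np.zeros((1, N_AA))
        t1 = np.zeros((1, N_AA))
        t1[0, 0] = math.log(3) * kT
        w = backbone_weights([t0, t1], kT)
        np.testing.assert_allclose(w[:, 0], [0.75, 0.25], atol=1e-12)

    def test_infinite_temperature_is_exactly_uniform(self):
        rng = np.random.default_rng(5)
        tables = [rng.normal(size=(4, N_AA)) for _ in range(5)]
        w = backbone_weights(tables, kT=np.inf)
        np.testing.assert_array_equal(w, 0.2)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(1)
        tables = [rng.normal(size=(6, N_AA)) for _ in range(3)]
        w = backbone_weights(tables, kT=0.6)
        np.testing.assert_allclose(w.sum(axis=0), 1.0, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="shape"):
            backbone_weights([np.zeros((2, N_AA)), np.zeros((3, N_AA))], 0.6)


class TestCombineBackbones:
    def test_single_backbone_identity(self):
        prof = random_profile(3, seed=2)
        agg = EnsembleAggregate(
            aa_probs=prof.freq[None, :, :],
            aa_energies=np.zeros((1, 3, N_AA)),
            weights=np.ones((1, 3)),
        )
        np.testing.assert_allclose(combine_backbones(agg).freq, prof.freq)

    def test_identical_tables_any_weights(self):
        prof = random_profile(2, seed=3)
        rng = np.random.default_rng(0)
        w = rng.dirichlet(np.ones(3), size=2).T  # (3 backbones, 2 positions)
        agg = EnsembleAggregate(
            aa_probs=np.repeat(prof.freq[None], 3, axis=0),
            aa_energies=np.zeros((3, 2, N_AA)),
            weights=w,
        )
        np.testing.assert_allclose(combine_backbones(agg).freq, prof.freq, atol=1e-12)

    def test_hand_convex_combination(self):
        a = random_profile(1, seed=4).freq
        b = random_profile(1, seed=5).freq
        agg = EnsembleAggregate(
            aa_probs=np.stack([a, b]),
            aa_energies=np.zeros((2, 1, N_AA)),
            weights=np.array([[0.75], [0.25]]),
        )
        np.testing.assert_allclose(
            combine_backbones(agg).freq, 0.75 * a + 0.25 * b, atol=1e-12
        )
        combine_backbones(agg).validate()

    def test_backbone_permutation_invariance(self):
        rng = np.random.default_rng(9)
        aa_probs = rng.dirichlet(np.ones(N_AA), size=(3, 2))
        energies = rng.normal(size=(3, 2, N_AA))
        w = backbone_weights(list(energies), kT=0.6)
        base = combine_backbones(EnsembleAggregate(aa_probs, energies, w))
        perm = [2, 0, 1]
        w_p = backbone_weights(list(energies[perm]), kT=0.6)
        permuted = combine_backbones(
            EnsembleAggregate(aa_probs[perm], energies[perm], w_p)
        )
        np.testing.assert_allclose(permuted.freq, base.freq, atol=1e-12)


class TestEnrichment:
    def test_uniform_background_is_identity(self):
        prof = random_profile(3, seed=1)
        out = enrich_over_background(prof, SpecificityProfile.uniform(1))
        np.testing.assert_allclose(out.freq, prof.freq, atol=1e-12)

    def test_hand_division(self):
        freq = np.zeros((1, N_AA))
        freq[0, 0] = 0.5
        freq[0, 1] = 0.5
        bg = np.full((1, N_AA), 0.05)
        bg[0, 0] = 0.25
        bg /= bg.sum()
        # Renormalising the background keeps the ratios 0.25 : 0.05 intact,
        # so the enriched row is still proportional to (2, 10, 0, ...).
        out = enrich_over_background(
            SpecificityProfile(freq), SpecificityProfile(bg)
        )
        assert out.freq[0, 0] == pytest.approx(1 / 6)
        assert out.freq[0, 1] == pytest.approx(5 / 6)
        assert np.all(out.freq[0, 2:] == 0.0)

    def test_self_division_gives_uniform(self):
        prof = random_profile(2, seed=8)  # Dirichlet rows: strictly positive
        out = enrich_over_background(prof, prof)
        np.testing.assert_allclose(out.freq, 1 / N_AA, atol=1e-12)

    def test_zero_background_refused_with_advice(self):
        prof = random_profile(1, seed=0)
        bg = np.zeros((1, N_AA))
        bg[0, 0] = 1.0
        with pytest.raises(ValidationError, match="smooth"):
            enrich_over_background(prof, SpecificityProfile(bg))


class TestPredictSpecificity:
    def test_decoupled_closed_form_with_gamma_zero(self):
        g = make_graph([[0.0, 0.5, 1.0]], ["ACD"])
        params = MFParameters(gamma=0.0, tol=1e-13)
        result = predict_specificity([g], params)
        e = g.one_body[0]
        w = np.exp(-e / params.kT)
        expected = w / w.sum()
        for k, aa in enumerate("ACD"):
            assert result.profile.freq[0, AA_INDEX[aa]] == pytest.approx(
                expected[k], abs=1e-10
            )

    def test_duplicated_backbones_reproduce_single_backbone_result(self):
        model = ToyEnergyModel(alphabet="ACDE", coupling_density=1.0, seed=6)
        g = generate_toy_graph(3, model)
        single = predict_specificity([g])
        multi = predict_specificity([g.copy() for _ in range(4)])
        np.testing.assert_allclose(
            multi.profile.freq, single.profile.freq, atol=1e-12
        )
        np.testing.assert_allclose(multi.aggregate.weights, 0.25, atol=1e-12)

    def test_uniform_background_equals_no_background(self):
        ensemble = generate_ensemble(
            ToyEnergyModel(alphabet="ACD", seed=2), 2, 0.2, 2
        )
        plain = predict_specificity(ensemble)
        enriched = predict_specificity(
            ensemble, background=SpecificityProfile.uniform(1)
        )
        np.testing.assert_allclose(
            plain.profile.freq, enriched.profile.freq, atol=1e-12
        )

    def test_position_mismatch_rejected(self):
        g1 = make_graph([[0.0]], ["A"])
        g2 = make_graph([[0.0], [0.0]], ["A", "C"])
        with pytest.raises(ValidationError, match="positions"):
            predict_specificity([g1, g2])

    def test_diagnostics_cover_each_backbone(self):
        ensemble = generate_ensemble(
            ToyEnergyModel(alphabet="AC", seed=4), 3, 0.1, 2
        )
        result = predict_specificity(ensemble)
        assert result.diagnostics["n_backbones"] == 3
        assert len(result.diagnostics["backbones"]) == 3
        assert all(b["converged"] for b in result.diagnostics["backbones"])

    def test_scmf_profile_matches_oracle_on_decoupled_graphs(self):
        from scmfpep.synthetic import brute_force_marginals

        model = ToyEnergyModel(
            alphabet="ACDE",
            rotamer_multiplicity={"A": 1, "C": 2, "D": 3, "E": 2},
            coupling_density=0.0,
            rotamer_strain=1.0,
            seed=11,
        )
        g = generate_toy_graph(3, model)
        params = MFParameters(gamma=0.0, tol=1e-13)
        result = predict_specificity([g], params)
        oracle = brute_force_marginals(g, params.kT)
        np.testing.assert_allclose(
            result.profile.freq, oracle.aa_marginals, atol=1e-9, rtol=0
        )
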