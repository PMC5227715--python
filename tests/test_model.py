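from itertools import product

import numpy as np
import pytest

from m6avote.exceptions import ConfigError, TrainingError
from m6avote.model import (
    KINDS,
    TrainingRecipe,
    VotingScenario,
    load_model,
    predict,
    save_model,
    simulate_voting,
    train_base,
    train_ensemble,
    vote,
    voting_accuracy_closed_form,
)
from m6avote.seqio import NEGATIVE_LABEL as NEG
from m6avote.seqio import POSITIVE_LABEL as POS
from m6avote.synthetic import SyntheticConfig, generate_dataset


def enumeration_oracle(p1, p2, p3):
    """Sum majority-correct probabilities over all 8 correctness outcomes."""
    total = 0.0
    for c1, c2, c3 in product([0, 1], repeat=3):
        if c1 + c2 + c3 >= 2:
            total += (
                (p1 if c1 else 1 - p1)
                * (p2 if c2 else 1 - p2)
                * (p3 if c3 else 1 - p3)
            )
    return total


class TestVote:
    def test_uniform_weights_equal_simple_majority(self):
        w = (1 / 3, 1 / 3, 1 / 3)
        for labels in product([POS, NEG], repeat=3):
            final, v_pos, v_neg = vote(labels, w)
            majority = POS if labels.count(POS) >= 2 else NEG
            assert final == majority
            assert v_pos + v_neg == pytest.approx(1.0)

    def test_majority_example(self):
        final, v_pos, v_neg = vote((POS, POS, NEG), (1 / 3, 1 / 3, 1 / 3))
        assert final == POS
        assert v_pos == pytest.approx(2 / 3)
        assert v_neg == pytest.approx(1 / 3)

    def test_tie_falls_to_largest_weight_classifier(self):
        final, v_pos, v_neg = vote((NEG, POS, POS), (0.5, 0.25, 0.25))
        assert v_pos == pytest.approx(0.5)
        assert v_neg == pytest.approx(0.5)
        assert final == NEG

    def test_unanimity_ignores_weights(self):
        for labels in ((POS,) * 3, (NEG,) * 3):
            assert vote(labels, (0.7, 0.2, 0.1))[0] == labels[0]

    def test_flipping_all_base_labels_flips_result(self):
        flip = {POS: NEG, NEG: POS}
        for labels in product([POS, NEG], repeat=3):
            final, *_ = vote(labels, (1 / 3, 1 / 3, 1 / 3))
            flipped, *_ = vote(tuple(flip[l] for l in labels), (1 / 3, 1 / 3, 1 / 3))
            assert flipped == flip[final]

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigError):
            vote((POS, POS, NEG), (0.5, 0.5, 0.5))


class TestVotingTheory:
    def test_closed_form_equals_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p1, p2, p3 = rng.uniform(0.501, 0.999, size=3)
            s = VotingScenario(p1, p2, p3)
            assert voting_accuracy_closed_form(s) == pytest.approx(
                enumeration_oracle(p1, p2, p3), abs=1e-12
            )

    def test_equal_accuracy_case_is_3q2_minus_2q3(self):
        for q in (0.55, 0.7, 0.9):
            assert voting_accuracy_closed_form(VotingScenario(q, q, q)) == pytest.approx(
                3 * q**2 - 2 * q**3, abs=1e-12
            )

    def test_q07_value(self):
        assert voting_accuracy_closed_form(VotingScenario(0.7, 0.7, 0.7)) == pytest.approx(0.784)

    def test_boundary_limit_is_one(self):
        assert voting_accuracy_closed_form(VotingScenario(1.0, 1.0, 1.0)) == 1.0

    def test_majority_beats_single_on_dense_grid(self):
        for q in np.linspace(0.501, 0.999, 200):
            assert 3 * q**2 - 2 * q**3 > q

    def test_monotone_in_each_accuracy(self):
        grid = np.linspace(0.55, 0.95, 9)
        for p2, p3 in product(grid[::3], grid[::3]):
            vals = [voting_accuracy_closed_form(VotingScenario(p1, p2, p3)) for p1 in grid]
            assert np.all(np.diff(vals) >= -1e-12)

    def test_domain_error(self):
        with pytest.raises(ConfigError):
            VotingScenario(0.4, 0.7, 0.7)

    def test_simulation_converges_to_closed_form(self):
        s = VotingScenario(0.7, 0.7, 0.7)
        closed = voting_accuracy_closed_form(s)
        emp = simulate_voting(s, 20_000, seed=5)
        assert abs(emp - closed) < 3 * np.sqrt(closed * (1 - closed) / 20_000)

    def test_simulation_perfect_voters(self):
        assert simulate_voting(VotingScenario(1.0, 1.0, 1.0), 100, seed=0) == 1.0

    def test_simulation_rejects_zero_trials(self):
        with pytest.raises(ConfigError):
            simulate_voting(VotingScenario(0.7, 0.7, 0.7), 0)

    def test_agreement_for_random_scenarios(self):
        rng = np.random.default_rng(17)
        for i in range(10):
            ps = rng.uniform(0.55, 0.95, size=3)
            s = VotingScenario(*ps)
            closed = voting_accuracy_closed_form(s)
            emp = simulate_voting(s, 10_000, seed=100 + i)
            assert abs(emp - closed) < 3 * np.sqrt(closed * (1 - closed) / 10_000)


class TestTraining:
    def test_base_classifiers_separate_separable_data(
        self, separable_dataset, light_recipe
    ):
        residues = [w.residues for w in separable_dataset]
        truth = np.array([1 if w.label == POS else -1 for w in separable_dataset])
        for kind in KINDS:
            clf = train_base(separable_dataset, kind, light_recipe, seed=0)
            assert 0.0 <= clf.cv_accuracy <= 1.0
            got = clf.predict_residues(residues)
            assert np.array_equal(got, truth), kind

    def test_same_seed_identical_predictions(self, separable_dataset, light_recipe):
        query = generate_dataset(SyntheticConfig(n_pos=5, n_neg=5, seed=99))
        runs = []
        for _ in range(2):
            ens = train_ensemble(separable_dataset, light_recipe, seed=3)
            runs.append([r.label for r in predict(ens, query)])
        assert runs[0] == runs[1]

    def test_uniform_weights(self, separable_dataset, light_recipe):
        ens = train_ensemble(separable_dataset, light_recipe, seed=0)
        assert ens.weights == (1 / 3, 1 / 3, 1 / 3)

    def test_cv_accuracy_weights_normalized_and_proportional(
        self, separable_dataset, light_recipe
    ):
        from dataclasses import replace

        recipe = replace(light_recipe, weighting="cv_accuracy")
        ens = train_ensemble(separable_dataset, recipe, seed=0)
        acc = np.array([c.cv_accuracy for c in ens.classifiers])
        assert np.allclose(ens.weights, acc / acc.sum())
        assert sum(ens.weights) == pytest.approx(1.0)

    def test_training_set_predicted_perfectly(self, separable_dataset, light_recipe):
        ens = train_ensemble(separable_dataset, light_recipe, seed=0)
        records = predict(ens, separable_dataset)
        assert all(r.label == r.window.label for r in records)
        assert all(len(r.base_labels) == 3 for r in records)

    def test_persistence_roundtrip(self, separable_dataset, light_recipe, tmp_path):
        ens = train_ensemble(separable_dataset, light_recipe, seed=0)
        path = tmp_path / "model.joblib"
        save_model(ens, path)
        back = load_model(path)
        assert back.training_fingerprint == ens.training_fingerprint
        query = generate_dataset(SyntheticConfig(n_pos=4, n_neg=4, seed=123))
        assert [r.label for r in predict(back, query)] == [
            r.label for r in predict(ens, query)
        ]

    def test_single_class_input_rejected(self, separable_dataset, light_recipe):
        only_pos = [w for w in separable_dataset if w.label == POS]
        with pytest.raises(TrainingError):
            train_base(only_pos, "psednc", light_recipe, seed=0)

    def test_unknown_kind_rejected(self, separable_dataset, light_recipe):
        with pytest.raises(ConfigError):
            train_base(separable_dataset, "spectral", light_recipe, seed=0)
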