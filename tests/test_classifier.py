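"""Gaussian kernel, one-against-one training and the interval decision rule."""

import numpy as np
import pytest

from eogkit import (STATES, TrainedModel, classify, decision_score,
                    gaussian_kernel, interval_decision, predict,
                    score_from_outcomes, train, vote_counts)
from eogkit.classifier import INTERVAL_MIDPOINTS, UntrainedModelError, pair_outcomes


def pure_outcomes(winner, fill="straight"):
    """All four contests of ``winner`` won; remaining pairs to ``fill``."""
    outcomes = {}
    for i, a in enumerate(STATES):
        for b in STATES[i + 1:]:
            if winner in (a, b):
                outcomes[(a, b)] = winner
            else:
                outcomes[(a, b)] = fill if fill in (a, b) else a
    return outcomes


class TestKernel:
    def test_identical_inputs_give_one(self):
        x = np.arange(8.0)
        assert gaussian_kernel(x, x, sigma=2.0) == 1.0

    def test_closed_form_at_sigma_sqrt2(self):
        x = np.zeros(8)
        y = np.zeros(8)
        y[0] = 2.0 * np.sqrt(2.0)  # distance = sigma*sqrt(2) for sigma=2
        assert gaussian_kernel(x, y, sigma=2.0) == pytest.approx(np.exp(-1))

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rng.normal(size=8), rng.normal(size=8)
            assert gaussian_kernel(a, b, 1.3) == pytest.approx(
                gaussian_kernel(b, a, 1.3))

    def test_non_positive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.zeros(8), np.zeros(8), sigma=0.0)


class TestTrain:
    def test_training_accuracy_on_separable_features(self, clean_feature_set,
                                                     clean_model):
        feats, labels = clean_feature_set
        pred = predict(clean_model, feats)
        assert np.mean([p == l for p, l in zip(pred, labels)]) == 1.0

    def test_ten_binaries_for_five_classes(self, clean_model):
        assert len(clean_model.binaries) == 10

    def test_two_class_subset_trains_one_binary(self, clean_feature_set):
        feats, labels = clean_feature_set
        mask = [l in ("left", "right") for l in labels]
        model = train(np.asarray(feats)[mask],
                      [l for l in labels if l in ("left", "right")])
        assert len(model.binaries) == 1

    def test_duplication_invariance(self, clean_feature_set):
        """With no dual weight at the box bound (separable data, high C),
        duplicating every sample leaves the decision functions unchanged."""
        feats, labels = clean_feature_set
        m1 = train(feats, labels, sigma=3.0, penalty=1000.0)
        m2 = train(np.vstack([feats, feats]), list(labels) * 2, sigma=3.0,
                   penalty=1000.0)
        rng = np.random.default_rng(7)
        for _ in range(20):
            probe = feats[rng.integers(len(feats))] * rng.uniform(0.9, 1.1)
            for b1, b2 in zip(m1.binaries, m2.binaries):
                z1 = m1.normalizer.transform(probe)
                z2 = m2.normalizer.transform(probe)
                assert b1.decision_value(z1, m1.sigma) == pytest.approx(
                    b2.decision_value(z2, m2.sigma), abs=1e-6)

    def test_missing_class_named_in_error(self, clean_feature_set):
        feats, labels = clean_feature_set
        bad = ["up" if l == "down" else l for l in labels]
        with pytest.raises(ValueError, match="down"):
            train(feats, bad, classes=STATES)

    def test_deterministic_for_fixed_seed(self, clean_feature_set):
        feats, labels = clean_feature_set
        m1, m2 = train(feats, labels, seed=1), train(feats, labels, seed=1)
        assert m1.to_json() == m2.to_json()


class TestDecisionScore:
    @pytest.mark.parametrize("winner,expected", [
        ("left", 1.5), ("right", -1.5), ("up", 0.5), ("down", -0.5),
        ("straight", 0.0),
    ])
    def test_pure_sweep_lands_on_midpoint(self, winner, expected):
        assert score_from_outcomes(pure_outcomes(winner)) == pytest.approx(expected)

    def test_pure_sweep_robust_to_unrelated_pairs(self):
        """Cross-pair votes cannot perturb a clean sweep."""
        for fill in ("up", "down", "right"):
            assert score_from_outcomes(pure_outcomes("left", fill=fill)) \
                == pytest.approx(1.5)

    def test_mirror_antisymmetry(self):
        """Swapping up<->down and left<->right in every outcome negates V."""
        mirror = {"up": "down", "down": "up", "left": "right",
                  "right": "left", "straight": "straight"}
        rng = np.random.default_rng(4)
        for _ in range(50):
            outcomes = {}
            for i, a in enumerate(STATES):
                for b in STATES[i + 1:]:
                    outcomes[(a, b)] = a if rng.random() < 0.5 else b
            mirrored = {tuple(sorted((mirror[a], mirror[b]),
                                     key=STATES.index)): mirror[w]
                        for (a, b), w in outcomes.items()}
            assert score_from_outcomes(mirrored) == pytest.approx(
                -score_from_outcomes(outcomes))

    def test_order_invariance(self, clean_model, clean_feature_set):
        feats, _ = clean_feature_set
        outcomes = pair_outcomes(clean_model, feats[7])
        shuffled = dict(reversed(list(outcomes.items())))
        assert score_from_outcomes(outcomes) == score_from_outcomes(shuffled)

    def test_score_within_interval_bounds(self, clean_model, clean_feature_set):
        feats, _ = clean_feature_set
        for row in feats[::5]:
            assert -2.0 <= decision_score(clean_model, row) <= 2.0


class TestClassify:
    @pytest.mark.parametrize("v,state", [
        (0.5, "up"), (-0.5, "down"), (1.5, "left"), (-1.5, "right"),
        (0.0, "straight"), (1.0, "straight"), (-2.0, "straight"),
    ])
    def test_interval_rule(self, v, state):
        assert interval_decision(v, epsilon=0.05) == state

    def test_event_free_short_circuit(self, clean_model):
        assert classify(clean_model, np.zeros(8)) == "straight"

    def test_untrained_model_rejected(self):
        with pytest.raises(UntrainedModelError):
            classify(TrainedModel(), np.ones(8))

    def test_label_permutation_consistency(self, clean_feature_set):
        """Relabelling classes + permuting the midpoint map permutes
        predictions accordingly."""
        feats, labels = clean_feature_set
        swap = {"left": "right", "right": "left"}
        swapped_labels = [swap.get(l, l) for l in labels]
        m_orig = train(feats, labels, sigma=3.0)
        m_swap = train(feats, swapped_labels, sigma=3.0)
        for row in feats[:25]:
            a = classify(m_orig, row)
            b = classify(m_swap, row)
            assert b == swap.get(a, a)

    def test_noise_free_end_to_end_recovery(self, clean_model, noise_free_config,
                                            pipeline_config):
        """>= 99% state recovery on 200 fresh noise-free trials."""
        from eogkit import generate_trial, process_trace
        hits = 0
        for i in range(200):
            state = STATES[i % 5]
            tr = generate_trial(state, noise_free_config, seed=77_000 + i)
            feats = process_trace(tr, pipeline_config).features
            hits += classify(clean_model, feats) == state
        assert hits >= 198


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, clean_model,
                                                  clean_feature_set, tmp_path):
        feats, _ = clean_feature_set
        path = tmp_path / "model.json"
        clean_model.save(path)
        clone = TrainedModel.load(path)
        assert predict(clone, feats[:25]) == predict(clean_model, feats[:25])

    def test_version_check(self):
        with pytest.raises(ValueError, match="format version"):
            TrainedModel.from_json('{"format_version": 99}')

    def test_vote_counts_sum_to_pair_count(self, clean_model, clean_feature_set):
        feats, _ = clean_feature_set
        assert sum(vote_counts(clean_model, feats[0]).values()) == 10
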