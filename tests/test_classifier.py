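"""Age classifiers: class weighting, the surrogate MLP head, the logistic
baseline, the P(old) contract, ROC-AUC and serialization."""

import numpy as np
import pandas as pd
import pytest

import agescreen as ag
from agescreen.classifier import (MLPHeadClassifier, _init_params,
                                  class_weights, evaluate_auc, load_model,
                                  save_model)
from agescreen.preprocess import BinnedMatrix


def _binned(tokens, n_bins=51, ages=None):
    tokens = np.asarray(tokens, dtype=np.int16)
    n = tokens.shape[0]
    ages = ages if ages is not None else ["mid" if i % 2 == 0 else "old" for i in range(n)]
    obs = pd.DataFrame({"donor_id": "d", "age_group": ages, "tissue": "t"},
                       index=[f"c{i}" for i in range(n)])
    return BinnedMatrix(tokens=tokens, n_bins=n_bins,
                        gene_symbols=pd.Index([f"g{j}" for j in range(tokens.shape[1])]),
                        cell_ids=pd.Index(obs.index), obs=obs)


class TestClassWeights:
    def test_inverse_frequency_formula(self):
        assert class_weights(["old", "old", "old", "mid"]) == (2.0, pytest.approx(2 / 3))

    def test_balanced_labels_give_unit_weights(self):
        assert class_weights(["mid", "old", "mid", "old"]) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights(["old", "old"])

    def test_weighted_loss_invariant_to_class_duplication(self):
        # with w_c = n/(2 n_c), the weighted mean loss equals the average of
        # per-class mean losses, so duplicating one class k times changes
        # nothing
        rng = np.random.default_rng(0)
        losses = rng.random(10)
        labels = np.array(["mid"] * 4 + ["old"] * 6)

        def weighted_mean(lab, los):
            w_mid, w_old = class_weights(lab)
            w = np.where(lab == "old", w_old, w_mid)
            return float((w * los).mean())

        dup_labels = np.concatenate([labels, labels[labels == "old"]] + [labels[labels == "old"]])
        dup_losses = np.concatenate([losses, losses[labels == "old"]] + [losses[labels == "old"]])
        assert weighted_mean(labels, losses) == pytest.approx(weighted_mean(dup_labels, dup_losses))


class TestMLPHead:
    def test_parameter_count_matches_architecture(self, tiny_train_config):
        cfg = tiny_train_config
        g, b, d, h = 9, 11, cfg.embed_dim, cfg.hidden_units
        params = _init_params(g, cfg, b, np.random.default_rng(0))
        model = MLPHeadClassifier(pd.Index([f"g{i}" for i in range(g)]), b, cfg, params)
        expected = (
            2 * g * d + 2 * b * d          # gene/bin tables + modulation tables
            + 2 * d                         # layer norm
            + (d * h + h)                   # first hidden layer
            + (cfg.n_hidden_layers - 1) * (h * h + h)
            + h + 1                         # output logit map
        )
        assert model.n_parameters == expected

    def test_training_is_deterministic(self, small_binned, tiny_train_config):
        labels = small_binned.obs["age_group"].to_numpy()
        m1 = ag.fit_mlp_head(small_binned, labels, tiny_train_config)
        m2 = ag.fit_mlp_head(small_binned, labels, tiny_train_config)
        np.testing.assert_array_equal(m1.predict_old_prob(small_binned),
                                      m2.predict_old_prob(small_binned))

    def test_single_class_labels_rejected(self, small_binned, tiny_train_config):
        with pytest.raises(ValueError):
            ag.fit_mlp_head(small_binned, ["old"] * small_binned.n_cells, tiny_train_config)

    def test_shuffled_labels_give_chance_auc(self, tiny_train_config):
        rng = np.random.default_rng(12)
        train = _binned(rng.integers(0, 51, (600, 30)))
        test = _binned(rng.integers(0, 51, (600, 30)))
        labels = rng.permutation(["mid", "old"] * 300)
        model = ag.fit_mlp_head(train, labels, tiny_train_config)
        auc = evaluate_auc(model, test, rng.permutation(["mid", "old"] * 300))
        assert 0.4 <= auc <= 0.6

    def test_fast_perturbation_path_matches_gene_by_gene(self, small_binned, tiny_train_config):
        labels = small_binned.obs["age_group"].to_numpy()
        model = ag.fit_mlp_head(small_binned, labels, tiny_train_config)
        tokens = small_binned.tokens[:40]
        idx = np.array([0, 3, 7])
        fast = model.perturbation_probs(tokens, idx, 0)
        slow = ag.AgeClassifier.perturbation_probs(model, tokens, idx, 0)
        np.testing.assert_allclose(fast, slow, rtol=1e-5, atol=1e-8)


class TestLogisticBaseline:
    def test_separable_single_gene_is_learned_perfectly(self):
        tokens = np.array([[0], [0], [0], [50], [50], [50]] * 4)
        ages = (["mid"] * 3 + ["old"] * 3) * 4
        b = _binned(tokens, ages=ages)
        model = ag.fit_logistic_baseline(b, ages, seed=0)
        p = model.predict_old_prob(b)
        assert ((p > 0.5) == (np.array(ages) == "old")).all()

    def test_constant_features_predict_class_prior(self):
        tokens = np.full((40, 3), 7)
        ages = ["mid"] * 10 + ["old"] * 30
        model = ag.fit_logistic_baseline(_binned(tokens, ages=ages), ages, seed=0)
        p = model.predict_old_prob(_binned(tokens, ages=ages))
        assert np.allclose(p, p[0])
        assert p[0] == pytest.approx(0.75, abs=0.05)

    def test_fast_perturbation_path_matches_gene_by_gene(self, small_binned):
        labels = small_binned.obs["age_group"].to_numpy()
        model = ag.fit_logistic_baseline(small_binned, labels, seed=1)
        tokens = small_binned.tokens[:30]
        idx = np.array([1, 4])
        fast = model.perturbation_probs(tokens, idx, model.n_bins - 1)
        slow = ag.AgeClassifier.perturbation_probs(model, tokens, idx, model.n_bins - 1)
        np.testing.assert_allclose(fast, slow, rtol=1e-9)


class TestPredictContract:
    @pytest.fixture()
    def fitted(self, small_binned):
        labels = small_binned.obs["age_group"].to_numpy()
        return ag.fit_logistic_baseline(small_binned, labels, seed=0)

    def test_outputs_strictly_inside_unit_interval(self, fitted, small_binned):
        p = fitted.predict_old_prob(small_binned)
        assert p.shape == (small_binned.n_cells,)
        assert (p > 0).all() and (p < 1).all()

    def test_row_permutation_permutes_probabilities(self, fitted, small_binned):
        perm = np.random.default_rng(0).permutation(small_binned.n_cells)
        p = fitted.predict_old_prob(small_binned)
        p_perm = fitted.predict_old_prob(small_binned.subset_cells(perm))
        np.testing.assert_array_equal(p_perm, p[perm])

    def test_gene_order_mismatch_rejected(self, fitted, small_binned):
        swapped = BinnedMatrix(tokens=small_binned.tokens[:, ::-1].copy(),
                               n_bins=small_binned.n_bins,
                               gene_symbols=small_binned.gene_symbols[::-1],
                               cell_ids=small_binned.cell_ids, obs=small_binned.obs)
        with pytest.raises(ValueError, match="order"):
            fitted.predict_old_prob(swapped)

    def test_gene_set_mismatch_lists_difference(self, fitted, small_binned):
        renamed = BinnedMatrix(tokens=small_binned.tokens, n_bins=small_binned.n_bins,
                               gene_symbols=pd.Index(["WEIRD"] + list(small_binned.gene_symbols[1:])),
                               cell_ids=small_binned.cell_ids, obs=small_binned.obs)
        with pytest.raises(ValueError, match="WEIRD"):
            fitted.predict_old_prob(renamed)

    def test_save_load_restores_identical_predictions(self, fitted, small_binned, tmp_path):
        p = fitted.predict_old_prob(small_binned)
        save_model(fitted, tmp_path / "m.pkl")
        back = load_model(tmp_path / "m.pkl")
        np.testing.assert_array_equal(back.predict_old_prob(small_binned), p)


class TestEvaluateAuc:
    def _model_with_scores(self, scores):
        class Fixed(ag.AgeClassifier):
            backend = "fixed"

            def _predict_tokens(self, tokens):
                return np.asarray(scores, dtype=float)

        return Fixed(pd.Index(["g0"]), 51)

    def _run(self, scores, ages):
        model = self._model_with_scores(scores)
        b = _binned(np.zeros((len(scores), 1)), ages=ages)
        return evaluate_auc(model, b, ages)

    def test_perfect_separation(self):
        assert self._run([0.9, 0.8, 0.1, 0.2], ["old", "old", "mid", "mid"]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert self._run([0.5] * 4, ["old", "old", "mid", "mid"]) == 0.5

    def test_pair_enumeration_example(self):
        # old {0.7, 0.2} vs mid {0.5}: one win + one loss out of 2 pairs
        assert self._run([0.7, 0.2, 0.5], ["old", "old", "mid"]) == 0.5

    def test_matches_bruteforce_pair_count(self, small_binned):
        ages = small_binned.obs["age_group"].to_numpy()
        idx = np.concatenate([np.flatnonzero(ages == "mid")[:25],
                              np.flatnonzero(ages == "old")[:25]])
        labels = ages[idx]
        sub = small_binned.subset_cells(idx)
        model = ag.fit_logistic_baseline(sub, labels, seed=0)
        scores = model.predict_old_prob(sub)
        old, mid = scores[labels == "old"], scores[labels == "mid"]
        wins = sum((o > m) + 0.5 * (o == m) for o in old for m in mid)
        assert evaluate_auc(model, sub, labels) == pytest.approx(wins / (len(old) * len(mid)))

    def test_single_class_rejected(self, small_binned):
        labels = small_binned.obs["age_group"].to_numpy()
        model = ag.fit_logistic_baseline(small_binned, labels, seed=0)
        with pytest.raises(ValueError):
            evaluate_auc(model, small_binned, ["old"] * small_binned.n_cells)
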