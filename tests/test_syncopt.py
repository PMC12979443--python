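"""Synchronous optimization tests: encoding, CV fitness, split, end-to-end search."""

import numpy as np
import pytest

from cafrisk.cohort import GenerationConfig, default_schema, generate, planted_signal_dataset
from cafrisk.learners import make_space
from cafrisk.optimizer import OptimizerConfig
from cafrisk.syncopt import (
    CandidateSolution,
    EncodingSchema,
    cv_fitness,
    decode,
    schema_for,
    split_stratified,
    synchronize,
)

LR_HP = {"penalty": "l2", "C": 1.0, "max_iter": 200}


def lr_schema(n_features):
    return EncodingSchema(n_features=n_features,
                          hyperparam_specs=tuple(make_space("lr").space))


class TestDecode:
    def test_threshold_rule_selects_expected_features(self):
        sch = lr_schema(3)
        cand = decode(np.array([0.7, 0.2, 0.5, 0.5, 0.5, 0.5]), sch)
        assert cand.feature_mask.tolist() == [True, False, True]

    def test_log_uniform_midpoint(self):
        sch = lr_schema(1)
        cand = decode(np.array([0.9, 0.0, 0.5, 0.0]), sch)
        assert cand.hyperparams["C"] == pytest.approx(10 ** (-3 + 0.5 * 5), rel=1e-12)

    def test_repair_rule_selects_argmax_when_all_below_threshold(self):
        sch = lr_schema(4)
        cand = decode(np.array([0.1, 0.4, 0.2, 0.3, 0.5, 0.5, 0.5]), sch)
        assert cand.feature_mask.tolist() == [False, True, False, False]

    def test_integer_and_categorical_decoding(self):
        sch = lr_schema(1)
        lo_end = decode(np.array([0.9, 0.0, 0.0, 0.0]), sch)
        hi_end = decode(np.array([0.9, 0.999, 0.999, 0.999]), sch)
        assert lo_end.hyperparams["penalty"] == "l1"
        assert hi_end.hyperparams["penalty"] == "l2"
        assert lo_end.hyperparams["max_iter"] == 50
        assert hi_end.hyperparams["max_iter"] == 500

    def test_conditional_hyperparameter_flagged_inactive(self):
        sch = EncodingSchema(n_features=1,
                             hyperparam_specs=tuple(make_space("svm").space))
        # kernel coordinate ~0.5 -> 'rbf'; degree decoded but inactive
        cand = decode(np.array([0.9, 0.5, 0.5, 0.5, 0.5]), sch)
        assert cand.hyperparams["kernel"] == "rbf"
        assert "degree" in cand.inactive

    def test_out_of_box_coordinates_clipped_idempotently(self):
        sch = lr_schema(2)
        pos = np.array([1.7, -0.3, 0.5, 0.5, 0.5])
        c1 = decode(pos, sch)
        c2 = decode(np.clip(pos, 0, 1), sch)
        assert c1.feature_mask.tolist() == c2.feature_mask.tolist()
        assert c1.hyperparams == c2.hyperparams

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            decode(np.zeros(3), lr_schema(3))


class TestCvFitness:
    def _candidate(self, data, names):
        mask = np.array([n in names for n in data.feature_names])
        return CandidateSolution(feature_mask=mask, hyperparams=dict(LR_HP))

    def test_separable_data_reaches_perfect_f1(self, planted_data):
        cand = self._candidate(planted_data, ["signal_1", "signal_2"])
        rep = cv_fitness(cand, planted_data, "lr", seed=3)
        assert rep.mean_f1 > 0.95
        assert len(rep.per_fold) == 5
        assert rep.mean_f1 == pytest.approx(np.mean([m.f1 for m in rep.per_fold]))

    def test_noise_only_candidate_is_strictly_worse(self, planted_data):
        informative = self._candidate(planted_data, ["signal_1", "signal_2"])
        noise = self._candidate(planted_data, ["noise_1"])
        f_inf = cv_fitness(informative, planted_data, "lr", seed=3).mean_f1
        f_noise = cv_fitness(noise, planted_data, "lr", seed=3).mean_f1
        assert f_noise < f_inf

    def test_deterministic_given_seed(self, planted_data):
        cand = self._candidate(planted_data, ["signal_1", "noise_2"])
        a = cv_fitness(cand, planted_data, "lr", seed=9)
        b = cv_fitness(cand, planted_data, "lr", seed=9)
        assert a.mean_f1 == b.mean_f1
        assert [m.f1 for m in a.per_fold] == [m.f1 for m in b.per_fold]

    def test_unselected_noise_column_does_not_change_fitness(self, planted_data):
        import pandas as pd

        from cafrisk.cohort import CohortTable

        cand = self._candidate(planted_data, ["signal_1", "signal_2"])
        base = cv_fitness(cand, planted_data, "lr", seed=3).mean_f1
        frame = planted_data.frame.copy()
        frame["extra_noise"] = np.random.default_rng(0).standard_normal(len(frame))
        widened = CohortTable(frame, {**planted_data.kinds, "extra_noise": "continuous"})
        mask = np.array([n in ("signal_1", "signal_2") for n in widened.feature_names])
        cand2 = CandidateSolution(feature_mask=mask, hyperparams=dict(LR_HP))
        assert cv_fitness(cand2, widened, "lr", seed=3).mean_f1 == base

    def test_training_never_sees_held_out_rows(self, planted_data):
        # poisoning the held-out rows of each fold must not change what the
        # model learned: tag rows via an extreme value and check fold scores
        # computed on clean vs poisoned copies of *training* data only differ
        # when training rows change
        from sklearn.model_selection import StratifiedKFold

        y = planted_data.outcome_values()
        X = planted_data.features(["signal_1", "signal_2"]).to_numpy()
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        from cafrisk.learners import train as fit

        for tr, te in skf.split(X, y):
            model_clean = fit("lr", LR_HP, X[tr], y[tr], seed=3)
            X_poisoned = X.copy()
            X_poisoned[te] += 1e6  # held-out rows mutated
            model_poisoned = fit("lr", LR_HP, X_poisoned[tr], y[tr], seed=3)
            probe = X[:5]
            assert np.array_equal(model_clean.score(probe), model_poisoned.score(probe))

    def test_small_minority_class_rejected(self):
        d = planted_signal_dataset(12, 1, 1, 1.0, seed=0)
        mask = np.array([True, False])
        cand = CandidateSolution(feature_mask=mask, hyperparams=dict(LR_HP))
        with pytest.raises(ValueError, match="minority"):
            cv_fitness(cand, d, "lr", k=5, seed=0)


class TestSplitStratified:
    def test_reference_cohort_sizes(self, small_cohort):
        train_t, test_t = split_stratified(small_cohort, 0.2, seed=1)
        assert train_t.n == 433
        assert test_t.n == 108
        assert train_t.outcome_values().sum() == 288
        assert test_t.outcome_values().sum() == 72

    def test_disjoint_union_recovers_input(self, small_cohort):
        train_t, test_t = split_stratified(small_cohort, 0.2, seed=4)
        combined = (
            np.vstack([train_t.frame.select_dtypes("number"), test_t.frame.select_dtypes("number")])
        )
        assert len(combined) == small_cohort.n
        assert train_t.n + test_t.n == small_cohort.n

    def test_class_proportions_preserved_within_rounding(self, small_cohort):
        train_t, _ = split_stratified(small_cohort, 0.2, seed=2)
        full_rate = small_cohort.outcome_values().mean()
        train_rate = train_t.outcome_values().mean()
        assert abs(train_rate - full_rate) <= 1.5 / train_t.n * small_cohort.n / train_t.n

    def test_seed_reproducibility(self, small_cohort):
        a1, b1 = split_stratified(small_cohort, 0.2, seed=8)
        a2, b2 = split_stratified(small_cohort, 0.2, seed=8)
        assert a1.frame.equals(a2.frame) and b1.frame.equals(b2.frame)

    def test_invalid_fraction_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            split_stratified(small_cohort, 1.0, seed=0)


class TestSynchronize:
    def test_small_search_selects_signal_and_is_deterministic(self, planted_data):
        cfg = OptimizerConfig(population=8, iterations=8, seed=5)
        a = synchronize(planted_data, "lr", opt=cfg)
        b = synchronize(planted_data, "lr", opt=cfg)
        assert a.selected_features == b.selected_features
        assert a.fitness.mean_f1 == b.fitness.mean_f1
        assert len(a.selected_features) >= 1
        # separable planted signal: the search should find a near-perfect F1
        assert a.fitness.mean_f1 > 0.9
        assert np.all(np.diff(a.convergence_curve) <= 1e-12)

    def test_schema_mismatch_rejected(self, planted_data):
        bad = lr_schema(3)
        with pytest.raises(ValueError, match="feature count"):
            synchronize(planted_data, "lr", schema=bad,
                        opt=OptimizerConfig(population=4, iterations=2, seed=0))
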