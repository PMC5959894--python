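"""Model-development protocol: splitting, adaptive LASSO, threshold
calibration, bootstrap AUROC, overfitting check, subset comparison."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from somnotype.emr_model import (
    FeatureVector,
    ModelSpec,
    PUBLISHED_COEFFICIENTS,
    PUBLISHED_INTERCEPT,
)
from somnotype.synthetic_emr import (
    SimulationConfig,
    simulate_corpus,
    simulate_from_model,
)
from somnotype.training import (
    SUBSET_COVARIATES,
    TrainConfig,
    auroc,
    bootstrap_auroc_ci,
    compare_subsets,
    fit_adaptive_lasso,
    model_probabilities,
    overfitting_check,
    refit_standard_errors,
    select_threshold,
    split_train_validation,
    threshold_from_probabilities,
)


def two_class_labels(n_pos, n_neg):
    labels = {f"p{i:04d}": "insomnia" for i in range(n_pos)}
    labels.update({f"n{i:04d}": "no_insomnia" for i in range(n_neg)})
    return labels


class TestSplit:
    def test_cohort_sized_split_matches_two_thirds(self):
        # 493 binary-labeled patients at 2/3: floor-per-stratum training
        labels = two_class_labels(230, 263)
        train, val = split_train_validation(labels, 2 / 3, seed=0)
        assert len(train) == 328 and len(val) == 165

    def test_partition_exact_and_stratified(self):
        labels = two_class_labels(30, 60)
        train, val = split_train_validation(labels, 2 / 3, seed=1)
        assert sorted(train + val) == sorted(labels)
        assert not set(train) & set(val)
        n_pos_train = sum(1 for i in train if labels[i] == "insomnia")
        assert n_pos_train == 20  # floor(2/3 * 30)

    def test_tiny_split(self):
        labels = {"a": "insomnia", "b": "insomnia", "c": "no_insomnia"}
        train, val = split_train_validation(labels, 2 / 3, seed=0)
        assert len(train) == 1 and len(val) == 2

    def test_deterministic_under_seed(self):
        labels = two_class_labels(40, 40)
        assert (split_train_validation(labels, 2 / 3, 9)
                == split_train_validation(labels, 2 / 3, 9))
        assert (split_train_validation(labels, 2 / 3, 9)
                != split_train_validation(labels, 2 / 3, 10))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            split_train_validation({"a": "insomnia", "b": "insomnia"},
                                   2 / 3, 0)


class TestAuroc:
    def test_rank_form_agrees_with_roc_integration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 80
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            scores = rng.integers(0, 10, size=n).astype(float)  # many ties
            assert auroc(scores, y) == pytest.approx(
                roc_auc_score(y, scores), abs=1e-10)

    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        assert auroc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(12)
        n = 500
        y = rng.integers(0, 2, size=n)
        scores = rng.random(n)
        n1, n0 = int(y.sum()), int(n - y.sum())
        se = math.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(auroc(scores, y) - 0.5) <= 3 * se

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestFitAdaptiveLasso:
    def test_parameter_recovery_from_generating_model(self, published_model):
        feats, labels = simulate_from_model(published_model, 5000, seed=11)
        fit = fit_adaptive_lasso(feats, labels, TrainConfig(seed=11))
        ses = refit_standard_errors(feats, labels, fit)
        for name, true in PUBLISHED_COEFFICIENTS.items():
            est = fit.coefficients.get(name)
            assert est is not None and est > 0, f"{name} not recovered"
            assert abs(est - true) <= 3 * ses[name], name

    def test_null_covariate_usually_dropped(self):
        # generate with the joint-disorder coefficient forced to zero: the
        # selection stage should drop it in at least 80% of replicates
        coeffs = dict(PUBLISHED_COEFFICIENTS)
        coeffs["n_joint_codes"] = 0.0
        null_model = ModelSpec(intercept=PUBLISHED_INTERCEPT,
                               coefficients=coeffs)
        dropped = 0
        for seed in range(20):
            feats, labels = simulate_from_model(null_model, 2000,
                                                seed=100 + seed)
            fit = fit_adaptive_lasso(feats, labels, TrainConfig(seed=seed))
            dropped += "n_joint_codes" not in fit.coefficients
        assert dropped >= 16

    def test_single_class_labels_rejected(self, published_model):
        feats, _ = simulate_from_model(published_model, 50, seed=0)
        labels = {i: "insomnia" for i in feats}
        with pytest.raises(ValueError, match="single-class"):
            fit_adaptive_lasso(feats, labels, TrainConfig())

    def test_too_few_rows_rejected(self, published_model):
        feats, labels = simulate_from_model(published_model, 5, seed=0)
        with pytest.raises(ValueError, match="at least 10"):
            fit_adaptive_lasso(feats, labels, TrainConfig())

    def test_subset_restricts_covariates(self, published_model):
        feats, labels = simulate_from_model(published_model, 1000, seed=2)
        fit = fit_adaptive_lasso(feats, labels,
                                 TrainConfig(variable_subset="icd_only",
                                             seed=2))
        assert set(fit.coefficients) <= set(SUBSET_COVARIATES["icd_only"])
        assert fit.variable_subset == "icd_only"

    def test_returned_model_has_no_threshold(self, published_model):
        feats, labels = simulate_from_model(published_model, 500, seed=3)
        fit = fit_adaptive_lasso(feats, labels, TrainConfig(seed=3))
        assert fit.threshold is None


class TestSelectThreshold:
    def test_three_negative_enumeration(self):
        # with 3 negatives the only specificity >= 0.97 is 1.0, so the cut
        # lands just above the largest negative probability
        probs = np.array([0.1, 0.2, 0.9])
        y = np.array([0, 0, 0])
        with pytest.warns(UserWarning, match="cannot resolve"):
            t = threshold_from_probabilities(probs, y, 0.97)
        assert 0.9 < t <= np.nextafter(0.9, 1.0)

    def test_zero_target_returns_minimum_probability(self):
        probs = np.array([0.3, 0.1, 0.8])
        y = np.array([1, 0, 0])
        t = threshold_from_probabilities(probs, y, 0.0)
        assert t == 0.1
        assert np.all(probs >= t)  # everything classifies positive

    def test_achieved_specificity_recount_on_simulated_validation(
            self, published_model):
        feats, labels = simulate_from_model(published_model, 2000, seed=21)
        sel = select_threshold(published_model, feats, labels, 0.97)
        ids = sorted(feats)
        probs = model_probabilities(sel.model, feats, ids)
        neg = probs[[labels[i] == "no_insomnia" for i in ids]]
        recount = float(np.mean(neg < sel.model.threshold))
        assert 0.97 <= recount <= 1.0
        assert recount == pytest.approx(sel.achieved_specificity, abs=1e-12)

    def test_requires_negatives(self, published_model):
        feats, _ = simulate_from_model(published_model, 20, seed=0)
        labels = {i: "insomnia" for i in feats}
        with pytest.raises(ValueError, match="negatives"):
            select_threshold(published_model, feats, labels, 0.97)


class TestBootstrapAuroc:
    def test_perfectly_separated_scores(self):
        model = ModelSpec(intercept=-3.0,
                          coefficients={"n_sleep_notes": 6.0})
        feats = {f"a{i}": FeatureVector(n_sleep_notes=1) for i in range(20)}
        feats.update({f"b{i}": FeatureVector() for i in range(20)})
        labels = {i: ("insomnia" if i.startswith("a") else "no_insomnia")
                  for i in feats}
        ci = bootstrap_auroc_ci(model, feats, labels, reps=200, seed=0)
        assert ci.auroc == 1.0 and ci.ci_low == 1.0 and ci.ci_high == 1.0

    def test_ci_brackets_point_estimate(self, published_model):
        feats, labels = simulate_from_model(published_model, 300, seed=8)
        ci = bootstrap_auroc_ci(published_model, feats, labels,
                                reps=500, seed=8)
        assert ci.ci_low <= ci.auroc <= ci.ci_high

    def test_deterministic_under_seed(self, published_model):
        feats, labels = simulate_from_model(published_model, 200, seed=9)
        a = bootstrap_auroc_ci(published_model, feats, labels, 300, seed=1)
        b = bootstrap_auroc_ci(published_model, feats, labels, 300, seed=1)
        assert a == b


@pytest.fixture(scope="module")
def sim_data(published_model):
    return simulate_from_model(published_model, 900, seed=31)


@pytest.fixture(scope="module")
def corpus_features(vocab):
    from somnotype.features import extract_corpus_features
    sim = simulate_corpus(SimulationConfig(n_patients=1500, seed=13))
    return extract_corpus_features(sim.patients, vocab), sim.truth


class TestOverfittingCheck:
    def test_deterministic_under_master_seed(self, sim_data):
        feats, labels = sim_data
        cfg = TrainConfig(overfit_permutations=5, seed=17)
        a = overfitting_check(feats, labels, cfg)
        b = overfitting_check(feats, labels, cfg)
        assert a.mean_auroc == b.mean_auroc

    def test_single_permutation_has_no_standard_error(self, sim_data):
        feats, labels = sim_data
        rep = overfitting_check(feats, labels,
                                TrainConfig(overfit_permutations=1, seed=5))
        assert rep.standard_error is None and rep.gap is None

    def test_no_overfit_gap_on_well_specified_simulation(
            self, published_model):
        feats, labels = simulate_from_model(published_model, 1500, seed=41)
        train_ids, val_ids = split_train_validation(labels, 2 / 3, seed=41)
        cfg = TrainConfig(overfit_permutations=30, seed=41)
        model = fit_adaptive_lasso(feats, labels, cfg, ids=train_ids)
        probs = model_probabilities(model, feats, val_ids)
        y = np.array([labels[i] == "insomnia" for i in val_ids], dtype=int)
        external = auroc(probs, y)
        rep = overfitting_check(feats, labels, cfg, ids=train_ids,
                                external_auroc=external)
        assert rep.gap < 0.05
        assert rep.standard_error < 0.02


class TestCompareSubsets:
    def test_information_nesting_with_both_signals(self, corpus_features):
        feats, truth = corpus_features
        cfg = TrainConfig(seed=13, bootstrap_reps=200,
                          overfit_permutations=1)
        rows = {r.subset: r for r in compare_subsets(feats, truth, cfg)}
        assert rows["combined"].auroc >= rows["unstructured_only"].auroc - 0.02
        assert rows["combined"].auroc >= rows["structured_only"].auroc - 0.02
        assert rows["unstructured_only"].auroc >= rows["icd_only"].auroc - 0.02

    def test_note_only_signal_beats_codes(self, vocab):
        # plant signal exclusively in sleep notes: insomnia codes carry none
        rates = {"sleep_notes": 2.0, "psych_notes": 0.7,
                 "insomnia_codes": 0.05, "anxdep_codes": 1.0,
                 "joint_codes": 1.8, "insomnia_rx": 0.05,
                 "other_events": 15.0, "other_notes": 3.0}
        control = dict(rates, sleep_notes=0.1)
        sim = simulate_corpus(SimulationConfig(
            n_patients=1500, seed=19, case_rates=rates,
            control_rates=control))
        from somnotype.features import extract_corpus_features
        feats = extract_corpus_features(sim.patients, vocab)
        cfg = TrainConfig(seed=19, bootstrap_reps=100,
                          overfit_permutations=1)
        rows = {r.subset: r for r in compare_subsets(
            feats, sim.truth, cfg, subsets=("unstructured_only", "icd_only"))}
        assert rows["unstructured_only"].auroc > rows["icd_only"].auroc

    def test_deterministic_under_master_seed(self, corpus_features):
        feats, truth = corpus_features
        cfg = TrainConfig(seed=23, bootstrap_reps=50, overfit_permutations=1)
        a = compare_subsets(feats, truth, cfg, subsets=("icd_only",))
        b = compare_subsets(feats, truth, cfg, subsets=("icd_only",))
        assert a == b
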