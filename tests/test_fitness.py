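"""Mask-to-accuracy fitness evaluation."""

import numpy as np
import pytest

from bmnabc import (
    ClassifierSpec,
    EvalProtocol,
    FeatureGroup,
    FeatureMatrix,
    accuracy_distribution,
    evaluate_fitness,
    generate_feature_dataset,
    knn_cosine_predict,
    make_classifier,
    make_fitness,
    mask_to_columns,
)
from bmnabc.fitness import _zscore_train


def _toy_matrix(widths=(20, 20, 3), n=30, seed=0):
    rng = np.random.default_rng(seed)
    groups, col = [], 0
    for i, w in enumerate(widths):
        groups.append(FeatureGroup("eeg", "AF3", f"B{i}", col, col + w))
        col += w
    labels = np.array(["Fast", "Slow"] * (n // 2))
    return FeatureMatrix(rng.normal(size=(n, col)), groups, labels)


def test_mask_to_columns_span_arithmetic():
    fm = _toy_matrix()
    cols = mask_to_columns(np.array([1, 0, 1]), fm)
    assert set(cols) == set(range(0, 20)) | set(range(40, 43))
    assert mask_to_columns(np.zeros(3), fm).size == 0
    assert mask_to_columns(np.ones(3), fm).size == 43
    with pytest.raises(ValueError, match="mask length"):
        mask_to_columns(np.ones(4), fm)


def test_all_zero_mask_scores_zero():
    fm = _toy_matrix()
    assert evaluate_fitness(np.zeros(3), fm) == 0.0


def test_noise_features_score_near_chance():
    accs = [
        evaluate_fitness(
            np.ones(3), _toy_matrix(seed=s), ClassifierSpec(), EvalProtocol(k=5, seed=s)
        )
        for s in range(10)
    ]
    assert abs(np.mean(accs) - 0.5) < 0.1


def test_separable_feature_scores_high():
    fm = _toy_matrix(widths=(2,), n=60, seed=1)
    fm.values[fm.labels == "Fast", 0] += 4.0  # 4-SD class separation
    for name in ("knn_cosine", "svm_gaussian", "random_forest"):
        acc = evaluate_fitness(np.ones(1), fm, ClassifierSpec(name), EvalProtocol(k=5))
        assert acc >= 0.95, name


def test_fast_knn_path_matches_sklearn_estimator(rng):
    """The vectorized cosine-kNN used on the hot path predicts identically
    to the sklearn estimator it replaces."""
    X = rng.normal(size=(80, 7))
    y = rng.integers(0, 2, 80)
    X_tr, X_te = _zscore_train(X[:60], X[60:])
    clf = make_classifier(ClassifierSpec("knn_cosine"))
    clf.fit(X_tr, y[:60])
    np.testing.assert_array_equal(
        knn_cosine_predict(X_tr, y[:60], X_te), clf.predict(X_te)
    )


def test_standardization_uses_training_rows_only(rng):
    tr = rng.normal(5.0, 2.0, size=(40, 3))
    te = rng.normal(-1.0, 0.5, size=(10, 3))
    z_tr, z_te = _zscore_train(tr, te)
    # train side is centered; test side keeps its genuine offset
    np.testing.assert_allclose(z_tr.mean(axis=0), 0.0, atol=1e-12)
    assert np.all(np.abs(z_te.mean(axis=0)) > 1.0)


def test_distribution_size_and_provenance():
    """30 masks x 100 repetitions pool into 3,000 scores."""
    fm = generate_feature_dataset(n_trials=60, seed=0, effect_size=1.25)
    masks = [np.ones(fm.n_groups, dtype=np.int8)] * 30
    scores, prov = accuracy_distribution(masks, fm, reps_per_mask=100, seed=1)
    assert scores.shape == (3000,)
    assert prov.shape == (3000, 2)
    assert set(prov[:, 0]) == set(range(30))
    assert set(prov[:, 1]) == set(range(100))


def test_distribution_determinism():
    fm = generate_feature_dataset(n_trials=60, seed=0)
    masks = [np.ones(fm.n_groups, dtype=np.int8)] * 2
    a, _ = accuracy_distribution(masks, fm, reps_per_mask=5, seed=3)
    b, _ = accuracy_distribution(masks, fm, reps_per_mask=5, seed=3)
    np.testing.assert_array_equal(a, b)


def test_single_mask_single_rep():
    fm = generate_feature_dataset(n_trials=60, seed=0)
    scores, _ = accuracy_distribution(
        [np.ones(fm.n_groups, dtype=np.int8)], fm, reps_per_mask=1
    )
    assert scores.shape == (1,)
    assert 0.0 <= scores[0] <= 1.0


def test_noise_group_robustness():
    """Adding one pure-noise group to a planted mask moves accuracy < 0.05."""
    from bmnabc.experiments import planted_group_indices

    fm = generate_feature_dataset(seed=4, effect_size=1.25)
    planted = sorted(planted_group_indices(fm))
    mask = np.zeros(fm.n_groups, dtype=np.int8)
    mask[planted] = 1
    base = evaluate_fitness(mask, fm, ClassifierSpec(), EvalProtocol(k=5))
    noisy = mask.copy()
    noisy[next(i for i in range(fm.n_groups) if i not in planted)] = 1
    with_noise = evaluate_fitness(noisy, fm, ClassifierSpec(), EvalProtocol(k=5))
    assert abs(base - with_noise) < 0.05


def test_make_fitness_restricts_and_caches():
    fm = generate_feature_dataset(n_trials=60, seed=0)
    active = np.array([0, 5, 9])
    calls = []
    proto = EvalProtocol(mode="holdout", seed=0)
    fitness = make_fitness(fm, ClassifierSpec(), proto, active_groups=active)
    sub = np.array([1, 0, 1], dtype=np.int8)
    full = fitness.expand(sub)
    assert full.sum() == 2 and full[0] == 1 and full[9] == 1
    v1, v2 = fitness(sub), fitness(sub)
    assert v1 == v2


def test_classifier_spec_validation():
    with pytest.raises(ValueError, match="unknown classifier"):
        ClassifierSpec("mlp")
    with pytest.raises(ValueError):
        EvalProtocol(mode="bootstrap")
    with pytest.raises(ValueError):
        EvalProtocol(holdout_fraction=1.5)
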