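"""Synthetic data generation: determinism, balance, RT structure, nulls."""

import numpy as np
import pytest
from scipy import stats

from bmnabc import (
    RTParams,
    SynthConfig,
    generate_dataset,
    generate_feature_dataset,
    generate_response_times,
    load_dataset,
    save_dataset,
)
from bmnabc.eeg import DEFAULT_BANDS, band_filter, preprocess_epoch
from bmnabc.fnirs import reconstruct_detail, wavelet_decompose


def test_determinism_bitwise():
    cfg = SynthConfig(n_participants=2, trials_per_participant=4, seed=1,
                      eeg_epoch_s=0.25, fnirs_epoch_s=3.0)
    a, b = generate_dataset(cfg), generate_dataset(cfg)
    np.testing.assert_array_equal(a.eeg, b.eeg)
    np.testing.assert_array_equal(a.fnirs, b.fnirs)
    np.testing.assert_array_equal(a.rts, b.rts)
    np.testing.assert_array_equal(a.true_label, b.true_label)


def test_full_study_counts():
    """10 participants x 35 trials, balanced: 350 trials, 175 per class."""
    ds = generate_dataset(SynthConfig(eeg_epoch_s=0.1, fnirs_epoch_s=2.0, seed=0))
    assert ds.n_trials == 350
    assert (ds.true_label == "Fast").sum() == 175
    assert (ds.true_label == "Slow").sum() == 175
    # per participant, proportions within one trial of the balance
    for pid in np.unique(ds.participant):
        n_fast = np.sum((ds.participant == pid) & (ds.true_label == "Fast"))
        assert abs(n_fast - 17.5) <= 0.5


def test_config_validation_names_field():
    with pytest.raises(ValueError, match="channels"):
        SynthConfig(channels=("AF3",) * 9)
    with pytest.raises(ValueError, match="class_balance"):
        SynthConfig(class_balance=1.5)
    with pytest.raises(ValueError, match="planted_eeg_groups"):
        SynthConfig(planted_eeg_groups=(("XX", "Gamma"),))
    with pytest.raises(ValueError, match="planted_fnirs_groups"):
        SynthConfig(planted_fnirs_groups=(("AF3", 0),))
    with pytest.raises(ValueError, match="effect"):
        SynthConfig(eeg_effect_size=-1.0)


def test_response_time_means_match_study_parameters(rng):
    """Fast trials: question 4 drops to ~666.7 ms while questions 1-3 stay
    near the 1027.9 ms baseline."""
    cfg = SynthConfig()
    draws = np.array(
        [generate_response_times(cfg, "Fast", rng) for _ in range(1000)]
    )
    assert draws[:, :3].mean() == pytest.approx(1027.9, abs=15)
    assert draws[:, 3].mean() == pytest.approx(666.7, abs=20)
    assert np.all(draws > 0)


def test_slow_trials_have_no_rt_drop(rng):
    cfg = SynthConfig()
    draws = np.array(
        [generate_response_times(cfg, "Slow", rng) for _ in range(1000)]
    )
    assert draws[:, 3].mean() == pytest.approx(draws[:, :3].mean(), abs=15)


def test_degenerate_sd_returns_exact_means(rng):
    cfg = SynthConfig(
        rt_params=RTParams(urt_sd=0.0, drt_fast_sd=0.0, within_trial_sd=0.0)
    )
    rts = generate_response_times(cfg, "Fast", rng)
    np.testing.assert_allclose(rts, [1027.9, 1027.9, 1027.9, 666.7])


def test_unknown_label_rejected(rng):
    with pytest.raises(ValueError, match="Fast"):
        generate_response_times(SynthConfig(), "Medium", rng)


def _band_powers(ds):
    """Cheap per-trial features: EEG band powers + fNIRS level energies."""
    feats = []
    for t in range(ds.n_trials):
        row = []
        for c in range(len(ds.channels)):
            clean = preprocess_epoch(ds.eeg[t, c], ds.eeg_fs)
            for band in DEFAULT_BANDS:
                row.append(np.mean(band_filter(clean, band, ds.eeg_fs) ** 2))
            coeffs = wavelet_decompose(ds.fnirs[t, c])
            for lvl in (5, 6):
                row.append(np.sum(reconstruct_detail(coeffs, lvl) ** 2))
        feats.append(row)
    return np.array(feats)


def test_null_effects_give_nominal_rejection_rate():
    """With both effect sizes 0, class comparisons of any feature reject at
    about the nominal 5% level (Monte-Carlo over >= 200 features)."""
    pvals = []
    for seed in range(4):
        ds = generate_dataset(
            SynthConfig(
                n_participants=2, trials_per_participant=20,
                eeg_effect_size=0.0, fnirs_effect_size=0.0,
                eeg_epoch_s=1.0, seed=seed,
            )
        )
        feats = _band_powers(ds)
        fast = ds.true_label == "Fast"
        pvals += [
            stats.mannwhitneyu(feats[fast, j], feats[~fast, j]).pvalue
            for j in range(feats.shape[1])
        ]
    rate = np.mean(np.asarray(pvals) < 0.05)
    assert len(pvals) >= 200
    assert 0.02 <= rate <= 0.08


def test_hdf5_roundtrip(tmp_path, small_dataset):
    path = tmp_path / "ds.h5"
    save_dataset(small_dataset, path, tmp_path / "trials.csv")
    back = load_dataset(path)
    np.testing.assert_array_equal(back.eeg, small_dataset.eeg)
    np.testing.assert_array_equal(back.true_label, small_dataset.true_label)
    assert back.channels == small_dataset.channels
    assert back.truth_manifest == small_dataset.truth_manifest
    assert (tmp_path / "trials.csv").exists()


def test_feature_dataset_layout_and_determinism():
    a = generate_feature_dataset(seed=9)
    b = generate_feature_dataset(seed=9)
    np.testing.assert_array_equal(a.values, b.values)
    assert a.n_groups == 63
    assert len(a.groups_of_modality("eeg")) == 45
    assert len(a.groups_of_modality("fnirs")) == 18
    assert (a.labels == "Fast").sum() == 70


def test_feature_dataset_planted_separability():
    """A classifier restricted to the planted groups beats 0.8 accuracy on
    the globally-planted design; the null design sits at chance."""
    from bmnabc import ClassifierSpec, EvalProtocol, evaluate_fitness
    from bmnabc.experiments import planted_group_indices

    fm = generate_feature_dataset(seed=2, effect_size=1.25)
    mask = np.zeros(fm.n_groups, dtype=np.int8)
    mask[list(planted_group_indices(fm))] = 1
    acc = evaluate_fitness(mask, fm, ClassifierSpec(), EvalProtocol(k=5))
    assert acc > 0.8

    null = generate_feature_dataset(seed=2, effect_size=0.0)
    acc0 = evaluate_fitness(mask, null, ClassifierSpec(), EvalProtocol(k=5))
    assert abs(acc0 - 0.5) < 0.12  # binomial noise around chance
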