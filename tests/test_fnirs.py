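"""Wavelet decomposition and fNIRS feature extraction."""

import numpy as np
import pytest
from scipy import stats

from bmnabc import (
    WaveletSpec,
    detail_band,
    extract_fnirs_features,
    level_diagnostics,
    reconstruct_detail,
    wavelet_decompose,
)
from bmnabc.fnirs import reconstruct

FS = 10.0


def _epoch(freq, n=300):
    return np.sin(2 * np.pi * freq * np.arange(n) / FS)


def test_perfect_reconstruction(rng):
    x = rng.normal(size=300)
    c = wavelet_decompose(x)
    err = np.max(np.abs(reconstruct(c) - x))
    assert err < 1e-8 * np.ptp(x)


def test_detail_reconstructions_sum_to_signal(rng):
    x = rng.normal(size=300)
    c = wavelet_decompose(x)
    approx_only = c.coeff_list(keep_level=None)
    total = sum(reconstruct_detail(c, lvl) for lvl in range(1, 7))
    # remaining part is the approximation
    import pywt

    a = [c.approx] + [np.zeros_like(c.details[l]) for l in range(6, 0, -1)]
    total = total + pywt.waverec(a, "db8", mode="periodization")[:300]
    np.testing.assert_allclose(total, x, atol=1e-8)


def test_zeros_decompose_to_zeros():
    c = wavelet_decompose(np.zeros(300))
    assert np.all(c.approx == 0)
    assert all(np.all(d == 0) for d in c.details.values())


def test_too_short_epoch_rejected():
    with pytest.raises(ValueError, match="too short"):
        wavelet_decompose(np.zeros(10))


@pytest.mark.parametrize(
    "level, expected",
    [(5, (0.15625, 0.3125)), (6, (0.078125, 0.15625)), (1, (2.5, 5.0))],
)
def test_dyadic_detail_bands(level, expected):
    assert detail_band(level, FS) == expected


def test_slow_oscillation_lands_in_l6():
    """A 0.1 Hz hemodynamic-like tone concentrates in the L6 band."""
    x = _epoch(0.1)
    c = wavelet_decompose(x)
    frac = np.sum(reconstruct_detail(c, 6) ** 2) / np.sum(x**2)
    assert frac >= 0.6


def test_fast_oscillation_avoids_l5_l6():
    x = _epoch(1.0)
    c = wavelet_decompose(x)
    frac = sum(np.sum(reconstruct_detail(c, l) ** 2) for l in (5, 6)) / np.sum(x**2)
    assert frac <= 0.05


def test_energy_conservation_orthogonal_length():
    """With the periodized transform and a 2^max_level-divisible length the
    level energies partition the signal energy."""
    x = np.random.default_rng(1).normal(size=320)
    c = wavelet_decompose(x)
    total = np.sum(c.approx**2) + sum(np.sum(d**2) for d in c.details.values())
    assert total == pytest.approx(np.sum(x**2), rel=1e-9)


def test_level_diagnostics_closed_forms():
    spec = WaveletSpec()
    c = wavelet_decompose(np.random.default_rng(0).normal(size=300), spec)
    # two equal-magnitude coefficients -> entropy log 2
    c.details[6] = np.array([2.0, -2.0])
    d = level_diagnostics(c, 6)
    assert d.entropy == pytest.approx(np.log(2))
    assert d.ratio == pytest.approx(d.energy / np.log(2))
    # uniform magnitudes over k coefficients -> entropy log k
    c.details[6] = np.full(7, 3.0)
    assert level_diagnostics(c, 6).entropy == pytest.approx(np.log(7))
    # single nonzero coefficient -> degenerate distribution
    c.details[6] = np.array([5.0, 0.0, 0.0])
    d = level_diagnostics(c, 6)
    assert d.entropy == 0.0 and d.ratio is None
    # all-zero level -> zero energy, flagged ratio
    c.details[6] = np.zeros(4)
    d = level_diagnostics(c, 6)
    assert d.energy == 0.0 and d.ratio is None


def test_missing_level_rejected():
    c = wavelet_decompose(np.zeros(300))
    with pytest.raises(ValueError, match="not present"):
        reconstruct_detail(c, 9)


def test_extraction_layout_and_total_group_count(small_dataset, small_eeg_features):
    fm = extract_fnirs_features(small_dataset)
    assert fm.n_groups == 18
    assert all(g.width == 3 for g in fm.groups)
    assert small_eeg_features.n_groups + fm.n_groups == 63


def test_zero_epoch_yields_zero_subfeatures(small_dataset):
    ds = small_dataset
    silent = type(ds)(
        ds.eeg[:2], np.zeros_like(ds.fnirs[:2]), ds.rts[:2], ds.participant[:2],
        ds.true_label[:2], ds.channels, ds.eeg_fs, ds.fnirs_fs, ds.truth_manifest,
    )
    fm = extract_fnirs_features(silent)
    np.testing.assert_allclose(fm.values, 0.0)


def test_planted_level_energy_is_class_dependent(small_dataset):
    """Fast trials carry more L6 energy at the planted optode (sign test)."""
    fm = extract_fnirs_features(small_dataset)
    fast = small_dataset.true_label == "Fast"
    g = next(g for g in fm.groups if g.channel == "F7" and g.feature == "L6")
    e_fast = fm.values[fast, g.start]
    e_slow = fm.values[~fast, g.start]
    assert np.median(e_fast) > np.median(e_slow)
    assert stats.mannwhitneyu(e_fast, e_slow, alternative="greater").pvalue < 0.01
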