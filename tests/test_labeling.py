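"""Fast/Slow labeling from response times."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmnabc import (
    RTRecord,
    label_participant,
    moving_median_filter,
    split_drt_urt,
)


@pytest.mark.parametrize(
    "series, window, expected",
    [
        ([100, 100, 900, 100, 100], 5, [100, 100, 100, 100, 100]),
        ([1, 2, 3, 4, 5], 3, [1.5, 2, 3, 4, 4.5]),  # truncated edge windows
        ([7, 3, 9], 1, [7, 3, 9]),  # window 1 is the identity
    ],
)
def test_moving_median_filter(series, window, expected):
    np.testing.assert_allclose(moving_median_filter(series, window), expected)


def test_moving_median_rejects_even_window():
    with pytest.raises(ValueError, match="odd"):
        moving_median_filter([1, 2, 3], 4)


@pytest.mark.parametrize(
    "rts, drt, urt",
    [
        ((900, 1000, 1100, 600), 600, 1000),
        ((1200, 900, 900, 650), 650, 1000),
        ((800, 800, 800, 800), 800, 800),
    ],
)
def test_split_drt_urt(rts, drt, urt):
    rec = RTRecord("P0", 0, rts)
    assert split_drt_urt(rec) == (drt, urt)


def test_rtrecord_validation():
    with pytest.raises(ValueError, match="positive"):
        RTRecord("P0", 0, (100.0, -1.0, 100.0, 100.0))
    with pytest.raises(ValueError, match="four"):
        RTRecord("P0", 0, (100.0, 100.0, 100.0))


def _records(drts, urts, pid="P0"):
    return [
        RTRecord(pid, i, (u, u, u, d)) for i, (d, u) in enumerate(zip(drts, urts))
    ]


def test_equal_drt_urt_labels_all_slow(rng):
    """A DRT equal to the trial's URT can never undercut the URT interval."""
    urts = rng.normal(1000, 100, size=30)
    out = label_participant(_records(urts, urts))
    assert all(t.label == "Slow" for t in out)


def test_sustained_fast_run_is_flagged_isolated_spike_is_cleaned(rng):
    """A sustained RT drop (three consecutive fast trials) survives the
    window-5 median filter and is labeled Fast; a single-trial spike is
    exactly the outlier the filter exists to remove, so it stays Slow."""
    urts = rng.normal(1000, 100, size=31)
    drts = urts.copy()
    drts[14:17] = 400.0  # far below any 95% lower bound of this sample
    out = label_participant(_records(drts, urts))
    assert out[15].label == "Fast"

    drts = urts.copy()
    drts[15] = 400.0
    out = label_participant(_records(drts, urts))
    assert out[15].label == "Slow"


def test_single_trial_participant_rejected():
    with pytest.raises(ValueError, match="at least 3"):
        label_participant([RTRecord("P0", 0, (1.0, 1.0, 1.0, 1.0))])


def test_mixed_participants_rejected():
    recs = _records([500, 500, 500], [900, 900, 900])
    recs[1] = RTRecord("P1", 1, recs[1].rts)
    with pytest.raises(ValueError, match="one participant"):
        label_participant(recs)


def test_labels_partition_trials(rng):
    urts = rng.normal(1000, 100, size=40)
    drts = np.where(np.arange(40) < 20, 400.0, urts)
    out = label_participant(_records(drts, urts))
    n_fast = sum(t.label == "Fast" for t in out)
    n_slow = sum(t.label == "Slow" for t in out)
    assert n_fast + n_slow == 40
    assert all(t.label == ("Fast" if t.drt < t.ci_lower else "Slow") for t in out)


@settings(max_examples=15, derandomize=True, deadline=None)
@given(c=st.floats(0.05, 20.0), seed=st.integers(0, 50))
def test_scale_invariance(c, seed):
    """Rescaling all of a participant's RTs by c > 0 rescales both the DRT
    series and the interval bound, leaving every label unchanged."""
    r = np.random.default_rng(seed)
    urts = r.normal(1000, 100, size=25)
    drts = r.normal(800, 250, size=25)
    base = [t.label for t in label_participant(_records(drts, urts))]
    scaled = [t.label for t in label_participant(_records(drts * c, urts * c))]
    assert base == scaled


def test_order_invariance(rng):
    """Labels attach to trial indices regardless of record order."""
    urts = rng.normal(1000, 100, size=20)
    drts = rng.normal(850, 200, size=20)
    recs = _records(drts, urts)
    shuffled = [recs[i] for i in rng.permutation(20)]
    a = {t.trial_index: t.label for t in label_participant(recs)}
    b = {t.trial_index: t.label for t in label_participant(shuffled)}
    assert a == b


def test_percentile_interval_available(rng):
    urts = rng.normal(1000, 100, size=50)
    drts = np.full(50, 400.0)
    out = label_participant(_records(drts, urts), method="percentile")
    assert all(t.label == "Fast" for t in out)
    with pytest.raises(ValueError, match="interval method"):
        label_participant(_records(drts, urts), method="bootstrap")
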