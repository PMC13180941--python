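"""Response-time based Fast/Slow trial labeling.

Each trial contains four response times.  The fourth question probes the
hidden rule, so its RT is the *determined* response time (DRT); the mean of
the first three is the *undetermined* response time (URT).  Per participant,
both series are outlier-cleaned with a moving median filter (window 5) and a
trial is labeled "Fast" when its filtered DRT falls below the lower bound of
the participant's 95% interval of filtered URTs — an individually-calibrated
marker of the RT drop that accompanies implicit rule acquisition.

The interval is, by default, a normal-theory interval on the URT
*distribution* (mean - z * SD), not a confidence interval on the mean: the
goal is to flag individually fast responses against the participant's own
baseline spread.  An empirical-percentile interval is available via
``method="percentile"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RTRecord",
    "LabeledTrial",
    "moving_median_filter",
    "split_drt_urt",
    "label_participant",
    "label_dataset",
]


@dataclass(frozen=True)
class RTRecord:
    participant: str
    trial_index: int
    rts: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.rts) != 4:
            raise ValueError("a trial carries exactly four response times")
        if any(rt <= 0 for rt in self.rts):
            raise ValueError("response times must be strictly positive")


@dataclass(frozen=True)
class LabeledTrial:
    participant: str
    trial_index: int
    drt: float
    urt: float
    ci_lower: float
    label: str  # "Fast" or "Slow"


def moving_median_filter(series, window: int = 5) -> np.ndarray:
    """Centered moving median with windows truncated at the edges.

    Output length equals input length; element ``i`` is the median of the
    samples within ``window // 2`` positions of ``i`` that exist.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    x = np.asarray(series, dtype=np.float64)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    half = window // 2
    n = x.shape[0]
    return np.array(
        [np.median(x[max(0, i - half) : min(n, i + half + 1)]) for i in range(n)]
    )


def split_drt_urt(rec: RTRecord) -> tuple[float, float]:
    """(DRT, URT): the fourth question's RT and the mean of the other three."""
    rts = rec.rts
    return float(rts[3]), float(np.mean(rts[:3]))


def label_participant(
    records: list[RTRecord],
    ci_level: float = 0.95,
    window: int = 5,
    method: str = "normal",
) -> list[LabeledTrial]:
    """Label one participant's trials Fast/Slow against their URT interval.

    The DRT and URT series are median-filtered separately in trial order;
    the interval lower bound is computed from the filtered URT sample only.
    """
    if len(records) < 3:
        raise ValueError(
            "labeling needs at least 3 trials per participant (interval undefined)"
        )
    pids = {r.participant for r in records}
    if len(pids) != 1:
        raise ValueError(f"records must share one participant, got {sorted(pids)}")
    ordered = sorted(records, key=lambda r: r.trial_index)
    pairs = [split_drt_urt(r) for r in ordered]
    drt = moving_median_filter([p[0] for p in pairs], window)
    urt = moving_median_filter([p[1] for p in pairs], window)

    alpha = 1.0 - ci_level
    if method == "normal":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        ci_lower = float(np.mean(urt) - z * np.std(urt, ddof=1))
    elif method == "percentile":
        ci_lower = float(np.quantile(urt, alpha / 2.0))
    else:
        raise ValueError(f"unknown interval method {method!r}")

    return [
        LabeledTrial(
            rec.participant, rec.trial_index, float(d), float(u), ci_lower,
            "Fast" if d < ci_lower else "Slow",
        )
        for rec, d, u in zip(ordered, drt, urt)
    ]


def label_dataset(
    dataset, ci_level: float = 0.95, window: int = 5, method: str = "normal"
) -> pd.DataFrame:
    """Label every trial of a TrialDataset; returns a tidy per-trial table."""
    rts = np.asarray(dataset.rts, dtype=np.float64)
    participants = np.asarray(dataset.participant)
    rows = []
    for pid in pd.unique(participants):
        idx = np.flatnonzero(participants == pid)
        records = [
            RTRecord(str(pid), int(i), tuple(rts[i])) for i in idx
        ]
        for lt in label_participant(records, ci_level, window, method):
            rows.append(
                dict(
                    participant=lt.participant, trial=lt.trial_index,
                    rt1=rts[lt.trial_index, 0], rt2=rts[lt.trial_index, 1],
                    rt3=rts[lt.trial_index, 2], rt4=rts[lt.trial_index, 3],
                    drt=lt.drt, urt=lt.urt, ci_lower=lt.ci_lower, label=lt.label,
                )
            )
    frame = pd.DataFrame(rows).sort_values("trial", kind="stable").reset_index(drop=True)
    return frame
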