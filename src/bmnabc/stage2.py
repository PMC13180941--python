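"""Stage 2: recursive backward elimination (RBE) of physical sensor sites.

Operating on the Stage-1 feature set, each iteration scores every active
site by the median hold-out accuracy obtained *after* removing that site's
feature groups, removes the least critical site (the one whose absence
leaves the highest median), and validates the depleted configuration
against the full-sensor baseline.  A removal is accepted only while the
configured gate holds; on the first rejection the candidate sensor is
reinstated and the loop stops.

Two stopping rules exist and are combined by default: an absolute accuracy
floor (default 85%) and an "elbow" rule under which a drop is acceptable
only if it is not statistically significant (Mann–Whitney vs baseline) and
does not exceed a margin (default 5%).  ``elbow_rule="or"`` relaxes the
conjunction to either condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import SITE_ORDER, FeatureMatrix
from .fitness import ClassifierSpec, accuracy_distribution

__all__ = [
    "SensorSet",
    "RBEConfig",
    "RBEStep",
    "RBETrace",
    "baseline_distribution",
    "ablation_scores",
    "select_least_critical",
    "rbe_loop",
    "sensor_reduction_report",
]


@dataclass
class SensorSet:
    """Active co-located sites and the surviving feature groups they own."""

    active_sites: list[str]
    site_groups: dict[str, np.ndarray]  # site -> group indices (within stage1 set)

    @property
    def n_sites(self) -> int:
        return len(self.active_sites)

    def groups_for(self, sites) -> np.ndarray:
        idx = [self.site_groups[s] for s in sites if self.site_groups[s].size]
        if not idx:
            return np.empty(0, dtype=np.int64)
        return np.sort(np.concatenate(idx))


@dataclass(frozen=True)
class RBEConfig:
    accuracy_floor: float = 0.85
    elbow_margin: float = 0.05
    alpha: float = 0.05
    n_train_iters: int = 30
    reps_per_iter: int = 100
    stop_mode: str = "both"  # "floor", "elbow" or "both"
    elbow_rule: str = "and"  # "and": not-significant AND within margin
    holdout_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.accuracy_floor <= 1.0):
            raise ValueError("accuracy_floor must lie in (0, 1]")
        if not (0.0 <= self.elbow_margin < 1.0):
            raise ValueError("elbow_margin must lie in [0, 1)")
        if self.stop_mode not in ("floor", "elbow", "both"):
            raise ValueError("stop_mode must be 'floor', 'elbow' or 'both'")
        if self.elbow_rule not in ("and", "or"):
            raise ValueError("elbow_rule must be 'and' or 'or'")


@dataclass
class RBEStep:
    site: str
    median: float
    p_value: float
    accepted: bool
    remaining_sites: list[str]
    distribution: np.ndarray = field(repr=False, default=None)


@dataclass
class RBETrace:
    baseline_median: float
    baseline_distribution: np.ndarray
    steps: list[RBEStep]


def build_sensor_set(fm: FeatureMatrix, stage1_groups: np.ndarray) -> SensorSet:
    """Map every surviving group to its (co-located) site."""
    stage1_groups = np.asarray(stage1_groups, dtype=np.int64)
    sites = [s for s in SITE_ORDER if s in {g.channel for g in fm.groups}]
    site_groups = {
        s: np.array(
            [j for j in stage1_groups if fm.groups[j].channel == s], dtype=np.int64
        )
        for s in sites
    }
    return SensorSet(list(sites), site_groups)


def _mask_for_groups(fm: FeatureMatrix, groups: np.ndarray) -> np.ndarray:
    mask = np.zeros(fm.n_groups, dtype=np.int8)
    mask[groups] = 1
    return mask


def _distribution(fm, groups, clf_spec, cfg, seed):
    mask = _mask_for_groups(fm, groups)
    dist, _ = accuracy_distribution(
        [mask] * cfg.n_train_iters, fm, clf_spec, cfg.reps_per_iter,
        cfg.holdout_fraction, seed,
    )
    return dist


def baseline_distribution(
    fm: FeatureMatrix,
    stage1_groups: np.ndarray,
    clf_spec: ClassifierSpec = ClassifierSpec(),
    cfg: RBEConfig = RBEConfig(),
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """n_train_iters x reps_per_iter hold-out scores on the full sensor set."""
    stage1_groups = np.asarray(stage1_groups, dtype=np.int64)
    if stage1_groups.size == 0:
        raise ValueError("stage-1 group set must be nonempty")
    dist = _distribution(fm, stage1_groups, clf_spec, cfg, seed)
    return dist, float(np.median(dist))


def ablation_scores(
    sensors: SensorSet,
    fm: FeatureMatrix,
    clf_spec: ClassifierSpec,
    cfg: RBEConfig,
    current_median: float,
    seed: int = 0,
) -> dict[str, tuple[float, np.ndarray | None]]:
    """site -> (median accuracy after removing that site, its distribution).

    A site owning no surviving groups is free to remove: its score is the
    current median exactly and no models are fit (distribution None).
    """
    if sensors.n_sites < 2:
        raise ValueError("ablation needs at least 2 active sites")
    out: dict[str, tuple[float, np.ndarray | None]] = {}
    for k, site in enumerate(sensors.active_sites):
        if sensors.site_groups[site].size == 0:
            out[site] = (current_median, None)
            continue
        rest = [s for s in sensors.active_sites if s != site]
        groups = sensors.groups_for(rest)
        if groups.size == 0:
            out[site] = (0.0, np.zeros(1))
            continue
        dist = _distribution(fm, groups, clf_spec, cfg, (seed + 131 * k) % (2**31))
        out[site] = (float(np.median(dist)), dist)
    return out


def select_least_critical(scores: dict[str, tuple[float, object]]) -> str:
    """Site whose removal leaves the highest median; ties break on site order."""
    if not scores:
        raise ValueError("scores must be nonempty")

    def order(site: str) -> int:
        return SITE_ORDER.index(site) if site in SITE_ORDER else len(SITE_ORDER)

    best = max(sorted(scores, key=order), key=lambda s: scores[s][0])
    return best


def _gate_ok(cfg: RBEConfig, median: float, p: float, baseline_median: float) -> bool:
    ok_floor = median >= cfg.accuracy_floor
    drop_ok = (baseline_median - median) <= cfg.elbow_margin
    sig_ok = p > cfg.alpha
    ok_elbow = (sig_ok and drop_ok) if cfg.elbow_rule == "and" else (sig_ok or drop_ok)
    if median >= baseline_median:
        ok_elbow = True  # maintained-or-improved can never fail the elbow
    if cfg.stop_mode == "floor":
        return ok_floor
    if cfg.stop_mode == "elbow":
        return ok_elbow
    return ok_floor and ok_elbow


def rbe_loop(
    fm: FeatureMatrix,
    stage1_groups: np.ndarray,
    clf_spec: ClassifierSpec = ClassifierSpec(),
    cfg: RBEConfig = RBEConfig(),
    seed: int = 0,
) -> tuple[SensorSet, RBETrace]:
    """Iterative least-critical sensor removal with reinstatement on failure."""
    stage1_groups = np.asarray(stage1_groups, dtype=np.int64)
    rng = np.random.default_rng(seed)
    base_dist, base_med = baseline_distribution(
        fm, stage1_groups, clf_spec, cfg, int(rng.integers(0, 2**31 - 1))
    )
    sensors = build_sensor_set(fm, stage1_groups)
    trace = RBETrace(base_med, base_dist, [])
    current_median = base_med

    while sensors.n_sites >= 2:
        scores = ablation_scores(
            sensors, fm, clf_spec, cfg, current_median,
            int(rng.integers(0, 2**31 - 1)),
        )
        site = select_least_critical(scores)
        median, dist = scores[site]
        if dist is None:  # free removal: no groups owned, nothing to validate
            p = 1.0
            accepted = True
        else:
            p = float(
                stats.mannwhitneyu(dist, base_dist, alternative="two-sided").pvalue
            )
            if not np.isfinite(p):
                p = 1.0
            accepted = _gate_ok(cfg, median, p, base_med)
        remaining = [s for s in sensors.active_sites if s != site]
        trace.steps.append(
            RBEStep(site, median, p, accepted,
                    remaining if accepted else list(sensors.active_sites), dist)
        )
        if not accepted:
            break  # reinstate the candidate: sensors unchanged
        sensors = SensorSet(remaining, sensors.site_groups)
        current_median = median
    return sensors, trace


def sensor_reduction_report(
    trace: RBETrace, n_original: int, path=None
) -> tuple[pd.DataFrame, float]:
    """Per-step degradation curve and the final reduction percentage."""
    if not trace.steps:
        raise ValueError("trace must be nonempty")
    rows = [
        dict(step=0, removed_site=None, median=trace.baseline_median,
             p_value=None, accepted=True, n_sites=n_original)
    ]
    n = n_original
    removed = 0
    for i, s in enumerate(trace.steps, start=1):
        if s.accepted:
            n -= 1
            removed += 1
        rows.append(
            dict(step=i, removed_site=s.site, median=s.median, p_value=s.p_value,
                 accepted=s.accepted, n_sites=n)
        )
    frame = pd.DataFrame(rows)
    reduction_pct = 100.0 * removed / n_original
    if path is not None:
        frame.to_csv(path, index=False)
    return frame, reduction_pct
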