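"""Stage 1: feature prioritization via batched colony runs and NWS pruning.

Each cycle runs a batch of independent colony optimizations restricted to
the currently active feature groups, pools the best masks, scores every
group by its *normalized weighted sum* (NWS) — the accuracy-weighted
frequency with which the group appears in the batch's best masks — and
permanently removes groups scoring below an incrementally raised threshold.
A Mann–Whitney gate compares each cycle's hold-out accuracy distribution
with the previous valid cycle's; a significant degradation reverts to the
previous active set and terminates the loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

from .colony import ColonyConfig, run
from .features import SITE_ORDER, FeatureMatrix
from .fitness import ClassifierSpec, EvalProtocol, accuracy_distribution, make_fitness

__all__ = [
    "NWSTable",
    "Stage1Config",
    "GateResult",
    "Stage1Cycle",
    "Stage1Result",
    "run_batch",
    "compute_nws",
    "gate",
    "stage1_loop",
    "export_nws_heatmap",
]


@dataclass
class NWSTable:
    """Per-group NWS scores with the run provenance that produced them."""

    scores: np.ndarray  # full group-space length; NaN for inactive groups
    masks: np.ndarray  # (n_runs, d) best masks
    accuracies: np.ndarray  # (n_runs,) best fitnesses
    active: np.ndarray  # bool, groups in the search space for this batch


@dataclass(frozen=True)
class Stage1Config:
    t_step: float = 0.1
    alpha: float = 0.05
    n_runs: int = 30
    reps_per_mask: int = 100
    holdout_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.t_step <= 1.1):
            raise ValueError("t_step must lie in (0, 1.1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_runs < 1 or self.reps_per_mask < 1:
            raise ValueError("n_runs and reps_per_mask must be >= 1")


@dataclass(frozen=True)
class GateResult:
    passed: bool
    p_value: float
    new_median: float
    prev_median: float


@dataclass
class Stage1Cycle:
    threshold: float  # removal threshold applied *after* this cycle
    active_before: np.ndarray
    nws: NWSTable
    distribution: np.ndarray
    gate: GateResult | None
    removed: np.ndarray


@dataclass
class Stage1Result:
    final_active: np.ndarray  # group indices surviving
    cycles: list[Stage1Cycle]
    reverted: bool

    @property
    def baseline_distribution(self) -> np.ndarray:
        return self.cycles[0].distribution

    @property
    def final_distribution(self) -> np.ndarray:
        """Accuracy sample of the last cycle whose set was kept."""
        kept = [c for c in self.cycles if c.gate is None or c.gate.passed]
        return kept[-1].distribution


def run_batch(
    fm: FeatureMatrix,
    clf_spec: ClassifierSpec,
    colony_cfg: ColonyConfig,
    proto: EvalProtocol,
    n_runs: int = 30,
    active_groups: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """``n_runs`` independent colony runs restricted to the active groups.

    Each run gets its own derived colony seed and its own evaluation seed
    (the dataset splits are re-randomized per run).  Returns full-length
    best masks and their best fitnesses.
    """
    active = (
        np.arange(fm.n_groups, dtype=np.int64)
        if active_groups is None
        else np.asarray(active_groups, dtype=np.int64)
    )
    if active.size == 0:
        raise ValueError("active group set must be nonempty")
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_runs, fm.n_groups), dtype=np.int8)
    accs = np.empty(n_runs)
    for r in range(n_runs):
        colony_seed = int(rng.integers(0, 2**31 - 1))
        eval_seed = int(rng.integers(0, 2**31 - 1))
        proto_r = EvalProtocol(
            mode=proto.mode, k=proto.k, holdout_fraction=proto.holdout_fraction,
            repetitions=proto.repetitions, stratified=proto.stratified,
            seed=eval_seed,
        )
        fitness = make_fitness(fm, clf_spec, proto_r, active_groups=active)
        cfg_r = ColonyConfig(
            d=active.size, n=colony_cfg.n, max_iter=colony_cfg.max_iter,
            limit=colony_cfg.limit, t_temp=colony_cfg.t_temp, seed=colony_seed,
        )
        result = run(fitness, cfg_r)
        masks[r] = fitness.expand(result.best_x)
        accs[r] = result.best_fitness
    return masks, accs


def compute_nws(masks: np.ndarray, accuracies: np.ndarray) -> np.ndarray:
    """NWS_j = sum_r acc_r * mask_rj / sum_r acc_r, in [0, 1].

    A group selected in every run scores 1; a never-selected group scores 0.
    """
    masks = np.asarray(masks, dtype=np.float64)
    accuracies = np.asarray(accuracies, dtype=np.float64)
    if masks.shape[0] != accuracies.shape[0]:
        raise ValueError("masks and accuracies must have equal length")
    total = accuracies.sum()
    if total <= 0:
        raise ValueError("all-zero accuracies: NWS weights undefined")
    return (accuracies[:, None] * masks).sum(axis=0) / total


def gate(
    new_dist: np.ndarray, prev_dist: np.ndarray, alpha: float = 0.05
) -> GateResult:
    """Degradation-only Mann–Whitney gate.

    PASS iff the two-sided p-value exceeds ``alpha`` OR the new median is at
    least the previous one (an improvement can never fail).  Identical
    constant samples pass with p = 1 by convention.
    """
    new_dist = np.asarray(new_dist, dtype=np.float64)
    prev_dist = np.asarray(prev_dist, dtype=np.float64)
    if new_dist.size == 0 or prev_dist.size == 0:
        raise ValueError("both samples must be nonempty")
    new_med = float(np.median(new_dist))
    prev_med = float(np.median(prev_dist))
    if (
        np.ptp(new_dist) == 0
        and np.ptp(prev_dist) == 0
        and new_dist[0] == prev_dist[0]
    ):
        return GateResult(True, 1.0, new_med, prev_med)
    p = float(stats.mannwhitneyu(new_dist, prev_dist, alternative="two-sided").pvalue)
    if not np.isfinite(p):
        p = 1.0
    return GateResult(p > alpha or new_med >= prev_med, p, new_med, prev_med)


def stage1_loop(
    fm: FeatureMatrix,
    clf_spec: ClassifierSpec = ClassifierSpec(),
    colony_cfg: ColonyConfig | None = None,
    proto: EvalProtocol = EvalProtocol(),
    cfg: Stage1Config = Stage1Config(),
    seed: int = 0,
) -> Stage1Result:
    """Iterative NWS-thresholded feature removal with revert-on-failure.

    Per cycle: batch of colony runs on the active set -> pooled hold-out
    accuracy distribution of the batch's best masks -> gate against the
    previous valid distribution (first cycle is its own baseline) -> on
    pass, raise the threshold by ``t_step`` and permanently remove groups
    with NWS below it.  Terminates on gate failure (revert), when no group
    falls below the raised threshold, when removal would empty the set, or
    at the hard cycle cap ceil(1/t_step) + 2.
    """
    if colony_cfg is None:
        colony_cfg = ColonyConfig(d=fm.n_groups)
    rng = np.random.default_rng(seed)
    active = np.arange(fm.n_groups, dtype=np.int64)
    threshold = 0.0
    prev_dist: np.ndarray | None = None
    prev_active = active.copy()
    cycles: list[Stage1Cycle] = []
    reverted = False
    max_cycles = ceil(1.0 / cfg.t_step) + 2

    for _ in range(max_cycles):
        batch_seed = int(rng.integers(0, 2**31 - 1))
        dist_seed = int(rng.integers(0, 2**31 - 1))
        masks, accs = run_batch(
            fm, clf_spec, colony_cfg, proto, cfg.n_runs, active, batch_seed
        )
        dist, _ = accuracy_distribution(
            masks, fm, clf_spec, cfg.reps_per_mask, cfg.holdout_fraction, dist_seed
        )
        scores = compute_nws(masks, accs)
        scores_full = np.full(fm.n_groups, np.nan)
        scores_full[active] = scores[active]
        active_mask = np.zeros(fm.n_groups, dtype=bool)
        active_mask[active] = True
        nws = NWSTable(scores_full, masks, accs, active_mask)

        g = None if prev_dist is None else gate(dist, prev_dist, cfg.alpha)
        if g is not None and not g.passed:
            cycles.append(
                Stage1Cycle(threshold, active.copy(), nws, dist, g,
                            np.empty(0, dtype=np.int64))
            )
            active = prev_active
            reverted = True
            break

        prev_dist = dist
        prev_active = active.copy()
        threshold = round(threshold + cfg.t_step, 12)
        below = active[scores_full[active] < threshold]
        if below.size >= active.size:  # removal would empty the set
            cycles.append(
                Stage1Cycle(threshold, active.copy(), nws, dist, g,
                            np.empty(0, dtype=np.int64))
            )
            break
        cycles.append(Stage1Cycle(threshold, active.copy(), nws, dist, g, below))
        if below.size == 0:
            break
        active = np.setdiff1d(active, below)

    return Stage1Result(active, cycles, reverted)


_ROW_ORDER = ("Gamma", "Beta", "Alpha", "Theta", "Delta", "L5", "L6")


def export_nws_heatmap(
    nws: NWSTable, fm: FeatureMatrix, path=None
) -> pd.DataFrame:
    """Channels-as-columns NWS table (bands then wavelet levels as rows).

    Removed (inactive) groups are blank (NaN).  Written as CSV when ``path``
    is given.
    """
    channels = [s for s in SITE_ORDER if s in {g.channel for g in fm.groups}]
    table = pd.DataFrame(np.nan, index=list(_ROW_ORDER), columns=channels)
    for j, g in enumerate(fm.groups):
        if g.feature in table.index and g.channel in table.columns:
            if nws.active[j]:
                table.loc[g.feature, g.channel] = nws.scores[j]
    if path is not None:
        table.to_csv(path)
    return table
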