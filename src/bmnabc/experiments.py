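"""Desk-scale validation experiments with planted ground truth.

Every experiment here regenerates its own synthetic inputs, runs the
corresponding pipeline stage, and scores the outcome against the planted
truth manifest.  The problem sizes are deliberately scaled down from the
full study conditions (population 10 instead of 20 bees, 25 instead of 100
iterations, 10 instead of 30 optimizer runs per batch, 20 instead of 100
hold-out repetitions per mask) so that multi-seed recovery studies complete
on a single CPU; the planted effects are sized so the scaled pipeline has a
clear signal to recover (see docs/methods.md for the rationale).
"""

from __future__ import annotations

import math

import numpy as np

from .colony import ColonyConfig, run
from .entropy import sample_entropy
from .evaluation import ComparisonResult, run_modality_comparison
from .features import FeatureMatrix
from .fitness import ClassifierSpec, EvalProtocol
from .labeling import label_dataset
from .stage1 import Stage1Config, gate, stage1_loop
from .stage2 import RBEConfig, rbe_loop, sensor_reduction_report
from .synth import RTParams, SynthConfig, generate_dataset, generate_feature_dataset

__all__ = [
    "PLANTED_GROUPS",
    "NOISE_SITES",
    "SCALED_COLONY",
    "SCALED_PROTO",
    "SCALED_STAGE1",
    "SCALED_RBE",
    "planted_group_indices",
    "onemax_benchmark",
    "planted_mask_benchmark",
    "stage1_recovery",
    "stage2_recovery",
    "post_stage1_group_set",
    "modality_experiment",
    "labeling_fidelity",
    "sampen_gaussian_limit",
]

#: the planted (channel, feature) combinations of the default study design:
#: three critical sites, each carrying one EEG band and one wavelet level
PLANTED_GROUPS = frozenset(
    {("AF3", "Gamma"), ("FZ", "Beta"), ("F7", "Gamma"),
     ("AF3", "L6"), ("F7", "L6"), ("FZ", "L5")}
)
NOISE_SITES = ("AF4", "F3", "F4", "F5", "F6", "F8")

SCALED_COLONY = dict(n=10, max_iter=25, limit=5)
SCALED_PROTO = EvalProtocol(mode="holdout", holdout_fraction=0.25, repetitions=2)
SCALED_STAGE1 = Stage1Config(n_runs=10, reps_per_mask=20)
SCALED_RBE = RBEConfig(n_train_iters=5, reps_per_iter=20)

#: planted separations (SD units) for the feature-domain recovery designs;
#: per-group strata split the class signal 6 ways (site strata 3 ways), so
#: the per-group shift must be large for the pooled classifier to see it
STAGE1_EFFECT = 6.0
STAGE2_EFFECT = 5.0
MODALITY_EFFECT = 5.0

_CLF = ClassifierSpec("knn_cosine")


def planted_group_indices(fm: FeatureMatrix) -> set[int]:
    return {
        i for i, g in enumerate(fm.groups) if (g.channel, g.feature) in PLANTED_GROUPS
    }


def onemax_benchmark(n_seeds: int = 20, d: int = 20, seed0: int = 0) -> dict:
    """How often the colony solves OneMax exactly, under the full settings."""
    wins = 0
    monotone = True
    budget_ok = True
    for s in range(n_seeds):
        cfg = ColonyConfig(d=d, seed=seed0 + s)
        res = run(lambda x: float(x.mean()), cfg)
        wins += res.best_fitness == 1.0
        monotone &= bool(np.all(np.diff(res.history) >= 0))
        budget_ok &= res.evaluations <= cfg.n + cfg.max_iter * 3 * cfg.n
    return dict(wins=wins, n_seeds=n_seeds, monotone=monotone, budget_ok=budget_ok)


def planted_mask_benchmark(n_seeds: int = 20, d: int = 63, seed0: int = 0) -> dict:
    """Recovery of a hidden target mask under fitness 1 - Hamming/d."""
    wins = 0
    monotone = True
    for s in range(n_seeds):
        rng = np.random.default_rng(10_000 + seed0 + s)
        target = rng.integers(0, 2, d)
        res = run(
            lambda x: 1.0 - np.count_nonzero(x != target) / d,
            ColonyConfig(d=d, seed=seed0 + s),
        )
        wins += res.best_fitness == 1.0
        monotone &= bool(np.all(np.diff(res.history) >= 0))
    return dict(wins=wins, n_seeds=n_seeds, monotone=monotone)


def stage1_recovery(master_seed: int) -> dict:
    """One master seed of the stage-1 planted-group recovery study.

    The design plants 6 informative groups among 63, each the sole carrier
    of the class signal in its own stratum of trials, and asks whether the
    prioritization loop keeps all of them while discarding noise.
    """
    fm = generate_feature_dataset(
        seed=100 + master_seed, strata="group", effect_size=STAGE1_EFFECT
    )
    planted = planted_group_indices(fm)
    colony = ColonyConfig(d=fm.n_groups, seed=0, **SCALED_COLONY)
    res = stage1_loop(fm, _CLF, colony, SCALED_PROTO, SCALED_STAGE1, seed=master_seed)
    final = set(res.final_active.tolist())
    n_noise = fm.n_groups - len(planted)
    noise_removed = n_noise - len(final - planted)
    final_gate = gate(res.final_distribution, res.baseline_distribution)
    return dict(
        planted_retained=len(planted & final),
        n_planted=len(planted),
        noise_removed=noise_removed,
        n_noise=n_noise,
        gate_passed=final_gate.passed,
        n_cycles=len(res.cycles),
        success=(
            planted <= final
            and noise_removed >= math.ceil(0.5 * n_noise)
            and final_gate.passed
        ),
    )


def post_stage1_group_set(fm: FeatureMatrix) -> np.ndarray:
    """A plausible post-stage-1 group set: the planted groups plus one
    surviving noise group per non-planted site (so every sensor owns
    features and nothing is free to remove)."""
    idx = sorted(planted_group_indices(fm))
    idx += [int(fm.groups_of_site(s)[0]) for s in NOISE_SITES]
    return np.array(sorted(idx), dtype=np.int64)


def stage2_recovery(master_seed: int) -> dict:
    """One master seed of the sensor-elimination recovery study.

    Three sites carry complementary planted signal; six carry only noise.
    Success means the loop strips exactly the six noise sites (a 66.7%
    reduction) and the reinstatement property holds: every removal before
    the last was accepted, and the final (rejected) removal was undone.
    """
    fm = generate_feature_dataset(
        seed=200 + master_seed, strata="site", effect_size=STAGE2_EFFECT
    )
    sensors, trace = rbe_loop(
        fm, post_stage1_group_set(fm), _CLF, SCALED_RBE, seed=master_seed
    )
    _, reduction = sensor_reduction_report(trace, n_original=9)
    reinstatement = (
        len(trace.steps) > 0
        and not trace.steps[-1].accepted
        and all(s.accepted for s in trace.steps[:-1])
    )
    final = sorted(sensors.active_sites)
    return dict(
        final_sites=final,
        reduction_pct=reduction,
        reinstatement=reinstatement,
        success=(final == ["AF3", "F7", "FZ"] and reinstatement),
    )


def modality_experiment(seed: int = 42, n_runs: int = 30) -> ComparisonResult:
    """Complementary-information fusion study: EEG and fNIRS planted groups
    each carry the class signal for half the trials, so neither modality
    alone can reach the fused accuracy."""
    fm = generate_feature_dataset(
        seed=seed, strata="modality", effect_size=MODALITY_EFFECT
    )
    colony = ColonyConfig(d=fm.n_groups, seed=0, n=10, max_iter=15, limit=5)
    return run_modality_comparison(
        fm, _CLF, colony, SCALED_PROTO, n_runs=n_runs, seed=seed
    )


def labeling_fidelity(seed: int = 1, coincident: bool = False) -> float:
    """Agreement between RT-pipeline labels and generator ground truth.

    With ``coincident=True`` the Fast DRT distribution is set equal to the
    Slow one, so the labels carry no information and agreement should sit
    at chance.
    """
    rt = RTParams()
    if coincident:
        rt = RTParams(drt_fast_mean=rt.drt_slow_mean, drt_fast_sd=rt.drt_slow_sd)
    cfg = SynthConfig(
        rt_params=rt, eeg_epoch_s=0.1, fnirs_epoch_s=2.0, seed=seed
    )  # epochs shrunk: only the RTs matter here
    ds = generate_dataset(cfg)
    labels = label_dataset(ds)["label"].to_numpy()
    return float((labels == ds.true_label).mean())


def sampen_gaussian_limit(n_seeds: int = 50, n: int = 3000) -> dict:
    """Mean SampEn of iid Gaussian series vs the analytic -ln(erf(r/2))."""
    vals = [
        sample_entropy(np.random.default_rng(s).normal(size=n))
        for s in range(n_seeds)
    ]
    return dict(
        mean=float(np.mean(vals)),
        analytic=-math.log(math.erf(0.15 / 2.0)),
        n_seeds=n_seeds,
    )
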