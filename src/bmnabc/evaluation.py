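"""Modality comparison, convergence reporting, and pipeline orchestration.

The comparison experiment runs the colony optimizer independently in three
search spaces — EEG-only groups, fNIRS-only groups, and the concatenated
multimodal space — under one identical evaluation protocol, and tests the
resulting best-accuracy samples with a Kruskal–Wallis omnibus followed by
pairwise Mann–Whitney comparisons (raw and Holm-adjusted p-values).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .colony import ColonyConfig, run
from .eeg import extract_eeg_features
from .features import FeatureMatrix, concat_features
from .fitness import ClassifierSpec, EvalProtocol, evaluate_fitness, make_fitness
from .fnirs import WaveletSpec, extract_fnirs_features
from .labeling import label_dataset
from .stage1 import Stage1Config, stage1_loop
from .stage2 import RBEConfig, rbe_loop, sensor_reduction_report
from .synth import SynthConfig, generate_dataset, save_dataset

__all__ = ["ComparisonResult", "run_modality_comparison", "convergence_report", "end_to_end"]

CONDITIONS = ("eeg", "fnirs", "multimodal")


@dataclass
class ComparisonResult:
    best_accuracies: dict[str, np.ndarray]  # condition -> (n_runs,) sample
    full_set_baseline: dict[str, float]  # condition -> no-selection accuracy
    histories: dict[str, list[np.ndarray]]
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float]
    pairwise_p_holm: dict[tuple[str, str], float]
    protocol: EvalProtocol = field(repr=False, default=None)

    def medians(self) -> dict[str, float]:
        return {c: float(np.median(v)) for c, v in self.best_accuracies.items()}


def _condition_groups(fm: FeatureMatrix, condition: str) -> np.ndarray:
    if condition == "multimodal":
        return np.arange(fm.n_groups, dtype=np.int64)
    return fm.groups_of_modality(condition)


def _holm(pvals: dict) -> dict:
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj = {}
    running = 0.0
    for rank, (key, p) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adj[key] = running
    return adj


def run_modality_comparison(
    fm: FeatureMatrix,
    clf_spec: ClassifierSpec = ClassifierSpec(),
    colony_cfg: ColonyConfig | None = None,
    proto: EvalProtocol = EvalProtocol(),
    n_runs: int = 30,
    seed: int = 0,
) -> ComparisonResult:
    """Best-accuracy samples for EEG-only / fNIRS-only / multimodal search.

    Every condition uses the identical evaluation protocol and the same
    number of independent optimizer runs; only the search space differs.
    """
    if colony_cfg is None:
        colony_cfg = ColonyConfig(d=fm.n_groups)
    rng = np.random.default_rng(seed)
    best: dict[str, np.ndarray] = {}
    baselines: dict[str, float] = {}
    histories: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    for condition in CONDITIONS:
        groups = _condition_groups(fm, condition)
        if groups.size == 0:
            raise ValueError(f"no feature groups for condition {condition!r}")
        full_mask = np.zeros(fm.n_groups, dtype=np.int8)
        full_mask[groups] = 1
        baselines[condition] = evaluate_fitness(full_mask, fm, clf_spec, proto)
        accs = np.empty(n_runs)
        for r in range(n_runs):
            colony_seed = int(rng.integers(0, 2**31 - 1))
            eval_seed = int(rng.integers(0, 2**31 - 1))
            proto_r = EvalProtocol(
                mode=proto.mode, k=proto.k,
                holdout_fraction=proto.holdout_fraction,
                repetitions=proto.repetitions, stratified=proto.stratified,
                seed=eval_seed,
            )
            fitness = make_fitness(fm, clf_spec, proto_r, active_groups=groups)
            result = run(
                fitness,
                ColonyConfig(d=groups.size, n=colony_cfg.n,
                             max_iter=colony_cfg.max_iter, limit=colony_cfg.limit,
                             t_temp=colony_cfg.t_temp, seed=colony_seed),
            )
            accs[r] = result.best_fitness
            histories[condition].append(result.history)
        best[condition] = accs

    omnibus = float(stats.kruskal(*[best[c] for c in CONDITIONS]).pvalue)
    pairs = [("multimodal", "eeg"), ("multimodal", "fnirs"), ("eeg", "fnirs")]
    pairwise = {
        pair: float(
            stats.mannwhitneyu(best[pair[0]], best[pair[1]],
                               alternative="two-sided").pvalue
        )
        for pair in pairs
    }
    return ComparisonResult(
        best, baselines, histories, omnibus, pairwise, _holm(pairwise), proto
    )


def convergence_report(
    histories: dict[str, list[np.ndarray]],
    baselines: dict[str, float] | None = None,
    path=None,
) -> pd.DataFrame:
    """Long-form best-so-far curves (condition, run, iteration, accuracy)."""
    rows = []
    any_history = False
    for condition, runs in histories.items():
        for r, h in enumerate(runs):
            any_history = True
            for it, v in enumerate(h):
                rows.append(
                    dict(condition=condition, run=r, iteration=it, best_so_far=v,
                         baseline=(baselines or {}).get(condition, np.nan))
                )
    if not any_history:
        raise ValueError("no optimization histories to report")
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, index=False)
    return frame


def end_to_end(
    out_dir,
    synth_cfg: SynthConfig = SynthConfig(),
    clf_spec: ClassifierSpec = ClassifierSpec(),
    colony_cfg: ColonyConfig | None = None,
    proto: EvalProtocol = EvalProtocol(),
    stage1_cfg: Stage1Config = Stage1Config(),
    rbe_cfg: RBEConfig = RBEConfig(),
    wavelet: WaveletSpec = WaveletSpec(),
    mse_kwargs: dict | None = None,
    seed: int = 0,
) -> dict:
    """simulate -> label -> extract -> stage 1 -> stage 2, checkpointed.

    Every stage writes its artifact under ``out_dir`` and is skipped when the
    artifact already exists, so an interrupted run resumes where it stopped.
    A manifest records the seeds in use.  Returns a summary dict.
    """
    from .entropy import MSEParams, SampEnParams

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seeds = {name: int(rng.integers(0, 2**31 - 1))
             for name in ("stage1", "stage2")}

    data_path = out / "data.h5"
    if not data_path.exists():
        save_dataset(generate_dataset(synth_cfg), data_path, out / "trials.csv")
    from .synth import load_dataset

    dataset = load_dataset(data_path)

    labels_path = out / "labels.csv"
    if not labels_path.exists():
        label_dataset(dataset).to_csv(labels_path, index=False)
    labels = pd.read_csv(labels_path)["label"].to_numpy()

    features_path = out / "features.h5"
    if not features_path.exists():
        mse_kwargs = mse_kwargs or {}
        eeg_fm = extract_eeg_features(
            dataset,
            sampen=mse_kwargs.get("sampen", SampEnParams()),
            mse=mse_kwargs.get("mse", MSEParams()),
        )
        fnirs_fm = extract_fnirs_features(dataset, wavelet)
        fm = concat_features(eeg_fm, fnirs_fm)
        fm.labels = labels  # classify the behaviorally assigned labels
        fm.save(features_path)
    fm = FeatureMatrix.load(features_path)

    if colony_cfg is None:
        colony_cfg = ColonyConfig(d=fm.n_groups)

    stage1_path = out / "stage1.json"
    if not stage1_path.exists():
        s1 = stage1_loop(fm, clf_spec, colony_cfg, proto, stage1_cfg, seeds["stage1"])
        stage1_path.write_text(
            json.dumps(
                dict(final_active=s1.final_active.tolist(), reverted=s1.reverted,
                     n_cycles=len(s1.cycles))
            )
        )
    s1_summary = json.loads(stage1_path.read_text())
    stage1_groups = np.array(s1_summary["final_active"], dtype=np.int64)

    stage2_path = out / "stage2.json"
    if not stage2_path.exists():
        sensors, trace = rbe_loop(fm, stage1_groups, clf_spec, rbe_cfg, seeds["stage2"])
        frame, reduction = sensor_reduction_report(
            trace, len({g.channel for g in fm.groups}), out / "rbe_trace.csv"
        )
        stage2_path.write_text(
            json.dumps(
                dict(final_sites=sensors.active_sites, reduction_pct=reduction,
                     baseline_median=trace.baseline_median)
            )
        )
    s2_summary = json.loads(stage2_path.read_text())

    manifest = dict(seed=seed, stage_seeds=seeds, classifier=clf_spec.name)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return dict(stage1=s1_summary, stage2=s2_summary, manifest=manifest)
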