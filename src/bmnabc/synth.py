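"""Synthetic multimodal trial generator with known planted structure.

The study conditions emulated here: ~10 participants contributing 35 trials
each (350 trials, balanced 175 Fast / 175 Slow); EEG epochs of 3 s at
1 kHz over nine frontal sites; fNIRS HbO2 epochs of 30 s at 10 Hz over the
co-located sites; and four response times per trial in which the fourth
question's RT drops for Fast trials (implicit-rule acquisition) while the
first three follow the participant's baseline distribution.

Two planted class effects give every downstream stage a ground-truth
acceptance surface:

* **EEG**: within a planted (channel, band), the band-limited component is a
  mixture of a narrowband oscillation (low irregularity) and band-filtered
  noise (high irregularity); the mixing fraction differs by class, so the
  band's sample entropy differs while its amplitude stays matched.
* **fNIRS**: a planted (channel, level) carries a hemodynamic-like
  oscillation inside that level's dyadic band whose amplitude differs by
  class.

Non-planted channel-band/level combinations are statistically identical
across classes.  Per participant, Slow trials precede Fast trials in time
(learning onset), which is what makes the moving-median RT filter in the
labeling stage well-behaved.

A feature-domain generator (`generate_feature_dataset`) emits the same
63-group layout directly as Gaussian features with planted mean shifts —
optionally *complementary* (each planted site or modality informative only
for its own stratum of trials) — and is the workhorse for studying the
selection stages at scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .eeg import DEFAULT_BANDS, BandDefinition, band_filter
from .features import SITE_ORDER, FeatureGroup, FeatureMatrix
from .fnirs import detail_band

__all__ = [
    "RTParams",
    "SynthConfig",
    "TrialDataset",
    "generate_response_times",
    "generate_dataset",
    "generate_feature_dataset",
    "save_dataset",
    "load_dataset",
]

BAND_NAMES = tuple(b.name for b in DEFAULT_BANDS)
_BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


@dataclass(frozen=True)
class RTParams:
    """Response-time distribution parameters in ms (truncated normal, > 0).

    ``urt_sd`` is the spread of the *per-question* undetermined RTs.  The
    three undetermined questions of a trial share a momentary-speed
    component, with ``within_trial_sd`` of independent per-question jitter
    on top (the between-trial component absorbs the rest, so per-question
    marginals stay N(urt_mean, urt_sd)).  This makes the trial-level URT
    spread comparable to the Slow DRT spread, as it is for a participant
    answering all four questions in one sitting.
    """

    urt_mean: float = 1027.9
    urt_sd: float = 99.8
    drt_fast_mean: float = 666.7
    drt_fast_sd: float = 155.3
    drt_slow_mean: float = 1027.9
    drt_slow_sd: float = 99.8
    within_trial_sd: float = 50.0


@dataclass(frozen=True)
class SynthConfig:
    n_participants: int = 10
    trials_per_participant: int = 35
    class_balance: float = 0.5
    eeg_fs: float = 1000.0
    eeg_epoch_s: float = 3.0
    fnirs_fs: float = 10.0
    fnirs_epoch_s: float = 30.0
    channels: tuple[str, ...] = SITE_ORDER
    planted_eeg_groups: tuple[tuple[str, str], ...] = (
        ("AF3", "Gamma"), ("FZ", "Beta"), ("F7", "Gamma"),
    )
    planted_fnirs_groups: tuple[tuple[str, int], ...] = (
        ("AF3", 6), ("F7", 6), ("FZ", 5),
    )
    eeg_effect_size: float = 0.8
    fnirs_effect_size: float = 1.0
    rt_params: RTParams = field(default_factory=RTParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) != 9 or len(set(self.channels)) != 9:
            raise ValueError("channels: need exactly 9 unique site names")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance: must lie in (0, 1)")
        if self.eeg_fs <= 0 or self.fnirs_fs <= 0:
            raise ValueError("eeg_fs/fnirs_fs: sampling rates must be positive")
        if self.eeg_effect_size < 0 or self.fnirs_effect_size < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.n_participants < 1 or self.trials_per_participant < 1:
            raise ValueError("n_participants/trials_per_participant must be >= 1")
        for ch, band in self.planted_eeg_groups:
            if ch not in self.channels:
                raise ValueError(f"planted_eeg_groups: unknown channel {ch!r}")
            if band not in BAND_NAMES:
                raise ValueError(f"planted_eeg_groups: unknown band {band!r}")
        for ch, lvl in self.planted_fnirs_groups:
            if ch not in self.channels:
                raise ValueError(f"planted_fnirs_groups: unknown channel {ch!r}")
            if lvl < 1:
                raise ValueError("planted_fnirs_groups: level must be >= 1")


@dataclass
class TrialDataset:
    eeg: np.ndarray  # (trials, channels, samples) at eeg_fs
    fnirs: np.ndarray  # (trials, channels, samples) at fnirs_fs
    rts: np.ndarray  # (trials, 4) ms
    participant: np.ndarray  # (trials,) str
    true_label: np.ndarray  # (trials,) "Fast"/"Slow"
    channels: tuple[str, ...]
    eeg_fs: float
    fnirs_fs: float
    truth_manifest: list[tuple[str, str, str]]  # (modality, channel, feature)

    @property
    def n_trials(self) -> int:
        return self.eeg.shape[0]

    def manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                trial=np.arange(self.n_trials),
                participant=self.participant,
                label=self.true_label,
                rt1=self.rts[:, 0], rt2=self.rts[:, 1],
                rt3=self.rts[:, 2], rt4=self.rts[:, 3],
            )
        )


def _pos_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Truncated-normal draw: resample until strictly positive."""
    if sd == 0:
        return float(mean)
    while True:
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)


def generate_response_times(
    cfg: SynthConfig, label: str, rng: np.random.Generator
) -> np.ndarray:
    """Four RTs in ms: q1-3 from the URT distribution, q4 per the label."""
    if label not in ("Fast", "Slow"):
        raise ValueError(f"label must be 'Fast' or 'Slow', got {label!r}")
    p = cfg.rt_params
    within = min(p.within_trial_sd, p.urt_sd)
    between = np.sqrt(max(p.urt_sd**2 - within**2, 0.0))
    speed = rng.normal(0.0, between) if between > 0 else 0.0
    rts = [_pos_normal(rng, p.urt_mean + speed, within) for _ in range(3)]
    if label == "Fast":
        rts.append(_pos_normal(rng, p.drt_fast_mean, p.drt_fast_sd))
    else:
        rts.append(_pos_normal(rng, p.drt_slow_mean, p.drt_slow_sd))
    return np.array(rts)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-shaped noise, unit RMS."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / np.std(x)


def _unit_rms(x: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    return x if rms == 0 else x / rms


def _eeg_band_component(
    rng: np.random.Generator, band: BandDefinition, fs: float, n: int,
    noise_fraction: float,
) -> np.ndarray:
    """Band-limited mixture of a tone and band noise, unit RMS.

    ``noise_fraction`` sets the irregular share of the mixture; sample
    entropy of the band responds monotonically to it.
    """
    t = np.arange(n) / fs
    f0 = np.sqrt(band.low * band.high) if band.low > 0 else band.high / 2
    tone = np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    noise = _unit_rms(band_filter(rng.normal(size=n), band, fs))
    w = float(np.clip(noise_fraction, 0.0, 1.0))
    return _unit_rms((1.0 - w) * tone + w * noise)


def generate_dataset(cfg: SynthConfig) -> TrialDataset:
    """Deterministic (per seed) multimodal dataset with planted effects."""
    rng = np.random.default_rng(cfg.seed)
    n_eeg = int(round(cfg.eeg_fs * cfg.eeg_epoch_s))
    n_fn = int(round(cfg.fnirs_fs * cfg.fnirs_epoch_s))
    n_ch = len(cfg.channels)
    n_per = cfg.trials_per_participant
    n_trials = cfg.n_participants * n_per

    planted_eeg = {(ch, band) for ch, band in cfg.planted_eeg_groups}
    planted_fn = {(ch, lvl) for ch, lvl in cfg.planted_fnirs_groups}

    eeg = np.empty((n_trials, n_ch, n_eeg))
    fnirs = np.empty((n_trials, n_ch, n_fn))
    rts = np.empty((n_trials, 4))
    labels = np.empty(n_trials, dtype=object)
    pids = np.empty(n_trials, dtype=object)

    t_fn = np.arange(n_fn) / cfg.fnirs_fs
    trial = 0
    for p in range(cfg.n_participants):
        pid = f"P{p:02d}"
        # alternate floor/ceil so class totals hit the requested balance
        # even when n_per * balance is fractional (e.g. 17.5 with 35 trials)
        lo = int(np.floor(n_per * cfg.class_balance))
        hi = int(np.ceil(n_per * cfg.class_balance))
        n_fast = hi if (p % 2 == 1) else lo
        # pre-learning Slow block, then post-onset Fast block
        seq = ["Slow"] * (n_per - n_fast) + ["Fast"] * n_fast
        for label in seq:
            fast = label == "Fast"
            for c, ch in enumerate(cfg.channels):
                x = _pink_noise(rng, n_eeg)
                for pch, pband in cfg.planted_eeg_groups:
                    if pch != ch:
                        continue
                    w = 0.5 + (cfg.eeg_effect_size / 2 if fast else -cfg.eeg_effect_size / 2)
                    x = x + 2.0 * _eeg_band_component(
                        rng, _BAND_BY_NAME[pband], cfg.eeg_fs, n_eeg, w
                    )
                eeg[trial, c] = x

                y = 0.1 * rng.normal(size=n_fn)
                y += 0.3 * np.sin(
                    2 * np.pi * 0.02 * t_fn + rng.uniform(0, 2 * np.pi)
                )  # baseline drift
                y += 0.2 * np.sin(
                    2 * np.pi * 1.0 * t_fn + rng.uniform(0, 2 * np.pi)
                )  # cardiac
                for pch, plvl in cfg.planted_fnirs_groups:
                    if pch != ch:
                        continue
                    lo, hi = detail_band(plvl, cfg.fnirs_fs)
                    f0 = np.sqrt(lo * hi)
                    amp = 0.3 * (1.0 + cfg.fnirs_effect_size) if fast else 0.3
                    y += amp * np.sin(2 * np.pi * f0 * t_fn + rng.uniform(0, 2 * np.pi))
                fnirs[trial, c] = y

            rts[trial] = generate_response_times(cfg, label, rng)
            labels[trial] = label
            pids[trial] = pid
            trial += 1

    manifest = [("eeg", ch, band) for ch, band in sorted(planted_eeg)] + [
        ("fnirs", ch, f"L{lvl}") for ch, lvl in sorted(planted_fn)
    ]
    return TrialDataset(
        eeg, fnirs, rts, pids.astype(str), labels.astype(str),
        tuple(cfg.channels), cfg.eeg_fs, cfg.fnirs_fs, manifest,
    )


def generate_feature_dataset(
    n_trials: int = 140,
    class_balance: float = 0.5,
    planted_eeg: tuple[tuple[str, str], ...] = (
        ("AF3", "Gamma"), ("FZ", "Beta"), ("F7", "Gamma"),
    ),
    planted_fnirs: tuple[tuple[str, str], ...] = (
        ("AF3", "L6"), ("F7", "L6"), ("FZ", "L5"),
    ),
    effect_size: float = 1.25,
    strata: str | None = None,
    eeg_width: int = 1,
    fnirs_width: int = 1,
    channels: tuple[str, ...] = SITE_ORDER,
    n_participants: int = 10,
    seed: int = 0,
) -> FeatureMatrix:
    """Feature-domain surrogate: the 63-group layout as Gaussian features.

    Planted groups receive a between-class mean separation of
    ``effect_size`` (in SD units) on every column they own.  With
    ``strata=None`` every planted group is informative for all trials (the
    groups are then mutually redundant: losing one barely moves accuracy).
    The complementary regimes make planted information *unique*:
    ``strata="group"`` gives each planted group its own (round-robin)
    stratum of trials in which it is the sole carrier of the class signal;
    ``strata="site"`` does the same per planted site, so each site's
    marginal contribution to accuracy is large; ``strata="modality"``
    splits the trials between the EEG and fNIRS planted groups.
    """
    if strata not in (None, "group", "site", "modality"):
        raise ValueError("strata must be None, 'group', 'site' or 'modality'")
    rng = np.random.default_rng(seed)

    groups: list[FeatureGroup] = []
    col = 0
    for ch in channels:
        for band in BAND_NAMES:
            groups.append(FeatureGroup("eeg", ch, band, col, col + eeg_width))
            col += eeg_width
    for ch in channels:
        for lvl in ("L5", "L6"):
            groups.append(FeatureGroup("fnirs", ch, lvl, col, col + fnirs_width))
            col += fnirs_width

    n_fast = int(round(n_trials * class_balance))
    labels = np.array(["Slow"] * (n_trials - n_fast) + ["Fast"] * n_fast)
    labels = labels[rng.permutation(n_trials)]
    sign = np.where(labels == "Fast", 1.0, -1.0)
    participants = np.array(
        [f"P{i % n_participants:02d}" for i in range(n_trials)]
    )

    planted = {("eeg",) + g for g in planted_eeg} | {("fnirs",) + g for g in planted_fnirs}
    planted_keys = sorted(planted)
    planted_sites = [s for s in SITE_ORDER if any(p[1] == s for p in planted)]
    if strata == "group":
        n_strata = len(planted_keys)
    elif strata == "site":
        n_strata = len(planted_sites)
    elif strata == "modality":
        n_strata = 2
    else:
        n_strata = 1
    trial_stratum = np.arange(n_trials) % n_strata

    values = rng.normal(size=(n_trials, col))
    for g in groups:
        key = (g.modality, g.channel, g.feature)
        if key not in planted:
            continue
        if strata == "group":
            gs = planted_keys.index(key)
        elif strata == "site":
            gs = planted_sites.index(g.channel)
        elif strata == "modality":
            gs = 0 if g.modality == "eeg" else 1
        else:
            gs = 0
        rows = np.flatnonzero(trial_stratum == gs)
        shift = sign[rows] * (effect_size / 2.0)
        values[np.ix_(rows, np.arange(g.start, g.stop))] += shift[:, None]

    fm = FeatureMatrix(values, groups, labels, participants)
    fm.strata = trial_stratum
    return fm


def save_dataset(dataset: TrialDataset, path, manifest_csv=None) -> None:
    """Persist a TrialDataset to HDF5 (and optionally its trial manifest CSV)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("eeg", data=dataset.eeg)
        h5.create_dataset("fnirs", data=dataset.fnirs)
        h5.create_dataset("rt", data=dataset.rts)
        h5.create_dataset("labels", data=dataset.true_label.astype("S"))
        h5.create_dataset("participants", data=dataset.participant.astype("S"))
        h5.attrs["channels"] = ",".join(dataset.channels)
        h5.attrs["eeg_fs"] = dataset.eeg_fs
        h5.attrs["fnirs_fs"] = dataset.fnirs_fs
        man = h5.create_group("manifest")
        for i, (mod, ch, feat) in enumerate(dataset.truth_manifest):
            man.attrs[f"{i:03d}"] = f"{mod}:{ch}:{feat}"
    if manifest_csv is not None:
        dataset.manifest_frame().to_csv(manifest_csv, index=False)


def load_dataset(path) -> TrialDataset:
    with h5py.File(path, "r") as h5:
        manifest = [
            tuple(h5["manifest"].attrs[k].split(":"))
            for k in sorted(h5["manifest"].attrs)
        ]
        return TrialDataset(
            h5["eeg"][()], h5["fnirs"][()], h5["rt"][()],
            h5["participants"][()].astype(str), h5["labels"][()].astype(str),
            tuple(h5.attrs["channels"].split(",")),
            float(h5.attrs["eeg_fs"]), float(h5.attrs["fnirs_fs"]),
            manifest,
        )
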