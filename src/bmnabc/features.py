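"""Feature-group containers shared by the extraction and selection stages.

The selection stages operate on *groups*, not columns: one group is one
(channel, EEG band) or (channel, wavelet level) combination, and a binary
mask bit toggles the whole group.  A group may own several scalar
sub-features (MSE scales for EEG, wavelet summaries for fNIRS); the group
order and its column spans are fixed at construction and persisted, so that
bit ``j`` of every mask refers to group ``j`` for the lifetime of a study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["FeatureGroup", "FeatureMatrix", "mask_to_columns", "concat_features"]

#: canonical site order, used for deterministic tie-breaking everywhere
SITE_ORDER = ("AF3", "AF4", "F3", "F4", "F5", "F6", "F7", "F8", "FZ")


@dataclass(frozen=True)
class FeatureGroup:
    """One selectable feature group and the columns it owns."""

    modality: str  # "eeg" or "fnirs"
    channel: str
    feature: str  # band name ("Gamma", ...) or wavelet level ("L5"/"L6")
    start: int
    stop: int  # exclusive

    @property
    def width(self) -> int:
        return self.stop - self.start

    @property
    def name(self) -> str:
        return f"{self.channel}:{self.feature}"


@dataclass
class FeatureMatrix:
    """Trials x columns matrix plus group descriptors and per-trial labels."""

    values: np.ndarray
    groups: list[FeatureGroup]
    labels: np.ndarray  # per-trial, "Fast"/"Slow"
    participants: np.ndarray | None = None
    strata: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (trials x columns) array")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels length must equal the number of trials")
        spans = sorted((g.start, g.stop) for g in self.groups)
        cursor = 0
        for lo, hi in spans:
            if lo != cursor or hi <= lo:
                raise ValueError("group column spans must partition the columns")
            cursor = hi
        if cursor != self.values.shape[1]:
            raise ValueError("group column spans must cover all columns")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    @property
    def y(self) -> np.ndarray:
        """Labels encoded as integers (Fast=1, Slow=0)."""
        return (self.labels == "Fast").astype(np.int64)

    def groups_of_modality(self, modality: str) -> np.ndarray:
        return np.array(
            [i for i, g in enumerate(self.groups) if g.modality == modality],
            dtype=np.int64,
        )

    def groups_of_site(self, site: str) -> np.ndarray:
        return np.array(
            [i for i, g in enumerate(self.groups) if g.channel == site],
            dtype=np.int64,
        )

    def sites(self) -> list[str]:
        present = {g.channel for g in self.groups}
        ordered = [s for s in SITE_ORDER if s in present]
        ordered += sorted(present - set(SITE_ORDER))
        return ordered

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form (trial, modality, channel, feature, column, value) table."""
        rows = []
        for g in self.groups:
            for c in range(g.start, g.stop):
                rows.append((g.modality, g.channel, g.feature, c))
        meta = pd.DataFrame(rows, columns=["modality", "channel", "feature", "column"])
        frames = []
        for t in range(self.n_trials):
            f = meta.copy()
            f.insert(0, "trial", t)
            f["value"] = self.values[t, f["column"].to_numpy()]
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def save(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("values", data=self.values)
            h5.create_dataset("labels", data=self.labels.astype("S"))
            if self.participants is not None:
                h5.create_dataset("participants", data=np.asarray(self.participants).astype("S"))
            grp = h5.create_group("groups")
            for i, g in enumerate(self.groups):
                sub = grp.create_group(f"{i:04d}")
                sub.attrs.update(
                    modality=g.modality, channel=g.channel, feature=g.feature,
                    start=g.start, stop=g.stop,
                )

    @classmethod
    def load(cls, path) -> "FeatureMatrix":
        with h5py.File(path, "r") as h5:
            values = h5["values"][()]
            labels = h5["labels"][()].astype(str)
            participants = (
                h5["participants"][()].astype(str) if "participants" in h5 else None
            )
            groups = []
            for key in sorted(h5["groups"]):
                a = h5["groups"][key].attrs
                groups.append(
                    FeatureGroup(a["modality"], a["channel"], a["feature"],
                                 int(a["start"]), int(a["stop"]))
                )
        return cls(values, groups, labels, participants)


def mask_to_columns(mask: np.ndarray, fm: FeatureMatrix) -> np.ndarray:
    """Column indices owned by the groups whose mask bit is set."""
    mask = np.asarray(mask)
    if mask.shape[0] != fm.n_groups:
        raise ValueError(
            f"mask length {mask.shape[0]} != number of groups {fm.n_groups}"
        )
    cols: list[np.ndarray] = [
        np.arange(g.start, g.stop) for bit, g in zip(mask, fm.groups) if bit
    ]
    if not cols:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(cols)


def concat_features(eeg: FeatureMatrix, fnirs: FeatureMatrix) -> FeatureMatrix:
    """Feature-level fusion: column-concatenate the two modality matrices."""
    if eeg.n_trials != fnirs.n_trials:
        raise ValueError("modality matrices must describe the same trials")
    if not np.array_equal(eeg.labels, fnirs.labels):
        raise ValueError("modality matrices must share trial labels")
    offset = eeg.values.shape[1]
    groups = list(eeg.groups) + [
        FeatureGroup(g.modality, g.channel, g.feature, g.start + offset, g.stop + offset)
        for g in fnirs.groups
    ]
    return FeatureMatrix(
        np.hstack([eeg.values, fnirs.values]), groups, eeg.labels.copy(),
        eeg.participants,
    )
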