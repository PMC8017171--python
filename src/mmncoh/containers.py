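"""In-memory EEG containers: continuous recordings and epoched data.

Voltages are in microvolts throughout; channel order follows the montage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage


@dataclass
class EEGRecording:
    """Continuous multichannel EEG.

    Attributes
    ----------
    data
        (n_channels, n_samples) array, microvolts.
    montage
        Channel labels and regions; ``data`` rows follow ``montage.labels``.
    fs_hz
        Sampling rate.
    bads
        Labels of channels marked bad.
    events
        Optional (onset_sample, label) stimulus events.
    info
        Free-form provenance (ground truth, filters applied, seeds).
    """

    data: np.ndarray
    montage: Montage
    fs_hz: float
    bads: set[str] = field(default_factory=set)
    events: list[tuple[int, str]] = field(default_factory=list)
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.montage.n_channels:
            raise ValueError("data must be (n_channels, n_samples) matching the montage")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def good_labels(self) -> tuple[str, ...]:
        return tuple(lab for lab in self.montage.labels if lab not in self.bads)

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.montage.index(label)]

    def copy_with(self, **kwargs) -> "EEGRecording":
        out = replace(self, **kwargs)
        return out


@dataclass
class Epochs:
    """Epoched EEG: trials x channels x time.

    ``tmin_s`` is the epoch start relative to the locking event (0 for
    resting-state grid epochs).  ``labels`` holds one condition string per
    trial ('standard', a deviant kind, or 'resting').
    """

    data: np.ndarray
    montage: Montage
    fs_hz: float
    tmin_s: float
    labels: np.ndarray
    paradigm_id: str = "resting"
    bads: set[str] = field(default_factory=set)
    rejection_log: dict = field(default_factory=dict)
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3 or self.data.shape[1] != self.montage.n_channels:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        return self.tmin_s + np.arange(self.n_times) / self.fs_hz

    @property
    def good_labels(self) -> tuple[str, ...]:
        return tuple(lab for lab in self.montage.labels if lab not in self.bads)

    def select(self, condition: str) -> "Epochs":
        mask = self.labels == condition
        return replace(self, data=self.data[mask], labels=self.labels[mask])

    def take(self, idx) -> "Epochs":
        idx = np.asarray(idx)
        return replace(self, data=self.data[idx], labels=self.labels[idx])
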