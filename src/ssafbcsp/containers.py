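"""In-memory containers for epoched and continuous multichannel EEG.

The package works on *epoched* data throughout: a trials x channels x
samples array of microvolt values, one integer class label per trial, and
the sampling rate. :class:`EpochSet` is that container; every processing
step returns a new one (arrays are never mutated in place).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EpochSet", "ContinuousRecording"]


@dataclass(frozen=True)
class EpochSet:
    """Epoched multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal amplitude in microvolts.
    labels : ndarray of int, shape (n_trials,)
        Class label per trial, drawn from ``{0, ..., n_classes - 1}``.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per channel; autogenerated if not supplied.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        labels = np.asarray(self.labels, dtype=np.int64)
        if data.ndim != 3:
            raise ValueError(
                f"data must be trials x channels x samples, got shape {data.shape}"
            )
        if labels.ndim != 1 or labels.shape[0] != data.shape[0]:
            raise ValueError(
                f"labels length {labels.shape} does not match {data.shape[0]} trials"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("epoch data contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        names = list(self.channel_names) or [f"ch{i}" for i in range(data.shape[1])]
        if len(names) != data.shape[1]:
            raise ValueError(
                f"{len(names)} channel names for {data.shape[1]} channels"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "channel_names", names)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def with_data(self, data: np.ndarray) -> "EpochSet":
        """Copy of this set with ``data`` replaced (labels/fs/names kept)."""
        return replace(self, data=data)

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset of trials given a boolean mask or index array."""
        mask = np.asarray(mask)
        return replace(self, data=self.data[mask], labels=self.labels[mask])


@dataclass(frozen=True)
class ContinuousRecording:
    """Continuous multichannel EEG with trial-onset event markers.

    ``events`` is a list of ``(onset_sample, class_code)`` pairs with
    strictly increasing onsets, all inside the recording.
    """

    data: np.ndarray
    fs: float
    events: list[tuple[int, int]]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError(
                f"data must be channels x samples, got shape {data.shape}"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        events = [(int(o), int(c)) for o, c in self.events]
        onsets = [o for o, _ in events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        if events and (onsets[0] < 0 or onsets[-1] >= data.shape[1]):
            raise ValueError("event onsets must lie within the recording")
        names = list(self.channel_names) or [f"ch{i}" for i in range(data.shape[0])]
        if len(names) != data.shape[0]:
            raise ValueError(
                f"{len(names)} channel names for {data.shape[0]} channels"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]
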