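"""Preprocessing chain for epoched motor-imagery EEG.

Standard chain, in order: epoch extraction from the continuous recording,
broadband band-pass (0.5-40 Hz), common average reference, baseline
correction against the pre-cue fixation interval, and peak-amplitude
artifact rejection. Each step is available standalone; :func:`preprocess`
runs the whole chain.

Filtering is a 4th-order Butterworth applied forward-backward
(zero phase), so band-power timing — the quantity ERD analysis cares
about — is not delayed by the filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import ContinuousRecording, EpochSet
from .exceptions import ConfigurationError
from .filterbank import filter_array

__all__ = [
    "PreprocConfig",
    "extract_epochs",
    "bandpass",
    "common_average_reference",
    "baseline_correct",
    "reject_artifacts",
    "preprocess",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocConfig:
    """Parameters of the preprocessing chain.

    Windows are in seconds relative to trial onset (0 = start of the
    fixation cross). Defaults follow the common cross-session protocol on
    cue-paced 4-class imagery: imagery period 2-6 s, baseline 0-2 s.
    ``reject_uv`` of ``None`` disables artifact rejection (appropriate for
    synthetic data, which contains no artifacts).
    """

    broadband: tuple[float, float] = (0.5, 40.0)
    epoch_window: tuple[float, float] = (2.0, 6.0)
    baseline_window: tuple[float, float] = (0.0, 2.0)
    reject_uv: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.broadband
        if not lo < hi:
            raise ConfigurationError(f"broadband ({lo}, {hi}) needs low < high")
        for name, (a, b) in (
            ("epoch_window", self.epoch_window),
            ("baseline_window", self.baseline_window),
        ):
            if not b > a:
                raise ConfigurationError(f"{name} ({a}, {b}) has non-positive length")
        if self.reject_uv is not None and self.reject_uv <= 0:
            raise ConfigurationError("reject_uv must be positive or None")


def extract_epochs(
    rec: ContinuousRecording,
    window: tuple[float, float] = (2.0, 6.0),
) -> EpochSet:
    """Cut one epoch per event from a continuous recording.

    ``window`` is (start, end) in seconds relative to each event onset,
    half-open in samples: ``[onset + round(fs*start), onset + round(fs*start)
    + round(fs*(end-start)))``. Events whose window does not fit inside the
    recording are dropped with a logged warning.
    """
    start_s, end_s = window
    if not end_s > start_s:
        raise ConfigurationError(f"epoch window ({start_s}, {end_s}) is empty")
    n_samp = int(round(rec.fs * (end_s - start_s)))
    offset = int(round(rec.fs * start_s))

    epochs, labels, dropped = [], [], 0
    for onset, code in rec.events:
        a = onset + offset
        b = a + n_samp
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        epochs.append(rec.data[:, a:b])
        labels.append(code)
    if dropped:
        logger.warning("dropped %d event(s) whose epoch window left the recording",
                       dropped)
    if not epochs:
        raise ValueError("no event's epoch window fits inside the recording")
    return EpochSet(
        data=np.stack(epochs),
        labels=np.asarray(labels),
        fs=rec.fs,
        channel_names=rec.channel_names,
    )


def bandpass(epochs: EpochSet, low: float, high: float) -> EpochSet:
    """Zero-phase band-pass of every channel of every trial."""
    if not (0.0 < low < high < epochs.fs / 2.0):
        raise ConfigurationError(
            f"band ({low}, {high}) outside (0, {epochs.fs / 2}) Hz"
        )
    return epochs.with_data(filter_array(epochs.data, low, high, epochs.fs))


def common_average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference each sample to the instantaneous mean across channels.

    After CAR the channel mean is exactly zero at every sample, which
    removes reference-electrode drift but also reduces the data rank by
    one (the CSP stage regularizes for this).
    """
    if epochs.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    return epochs.with_data(epochs.data - epochs.data.mean(axis=1, keepdims=True))


def baseline_correct(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Subtract each channel's mean over ``window`` (seconds from epoch start)."""
    a_s, b_s = window
    if not b_s > a_s:
        raise ConfigurationError(f"baseline window ({a_s}, {b_s}) is empty")
    a = int(round(a_s * epochs.fs))
    b = int(round(b_s * epochs.fs))
    if a < 0 or b > epochs.n_samples:
        raise ConfigurationError(
            f"baseline window ({a_s}, {b_s}) s outside the epoch "
            f"(0, {epochs.n_samples / epochs.fs}) s"
        )
    base = epochs.data[:, :, a:b].mean(axis=2, keepdims=True)
    return epochs.with_data(epochs.data - base)


def reject_artifacts(
    epochs: EpochSet, thresh_uv: float | None
) -> tuple[EpochSet, np.ndarray]:
    """Drop trials whose absolute peak on any channel exceeds ``thresh_uv``.

    Deterministic surrogate for visual artifact inspection. Returns the
    surviving trials and a boolean keep-mask aligned with the input order.
    ``thresh_uv=None`` keeps everything.
    """
    if thresh_uv is None:
        return epochs, np.ones(epochs.n_trials, dtype=bool)
    if thresh_uv <= 0:
        raise ConfigurationError("rejection threshold must be positive")
    peaks = np.abs(epochs.data).max(axis=(1, 2))
    keep = peaks <= thresh_uv
    if not keep.any():
        raise ValueError(
            f"all {epochs.n_trials} trials exceed the {thresh_uv} uV threshold"
        )
    return epochs.select(keep), keep


def preprocess(rec: ContinuousRecording, cfg: PreprocConfig) -> EpochSet:
    """Full chain: extract, band-pass, CAR, baseline-correct, reject.

    The baseline window typically precedes the imagery window (fixation
    0-2 s vs imagery 2-6 s), so epochs are first cut over the union of the
    two windows, baseline-corrected there, and only then cropped to the
    imagery window.
    """
    lo = min(cfg.epoch_window[0], cfg.baseline_window[0])
    hi = max(cfg.epoch_window[1], cfg.baseline_window[1])
    wide = extract_epochs(rec, (lo, hi))
    wide = bandpass(wide, *cfg.broadband)
    wide = common_average_reference(wide)
    base_rel = (cfg.baseline_window[0] - lo, cfg.baseline_window[1] - lo)
    wide = baseline_correct(wide, base_rel)

    a = int(round((cfg.epoch_window[0] - lo) * rec.fs))
    n = int(round((cfg.epoch_window[1] - cfg.epoch_window[0]) * rec.fs))
    epochs = wide.with_data(wide.data[:, :, a : a + n])
    epochs, _ = reject_artifacts(epochs, cfg.reject_uv)
    return epochs
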