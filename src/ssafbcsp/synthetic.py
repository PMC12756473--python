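"""Synthetic motor-imagery EEG with planted ERD band-power structure.

During motor imagery, the sensorimotor cortex contralateral to the imagined
movement shows event-related desynchronization (ERD): a drop in band-limited
power of the mu (~8-12 Hz) and beta (~13-30 Hz) rhythms. This module
generates labeled epochs in which that class-dependent power modulation is
planted explicitly, so band selection and CSP feature extraction can be
exercised and validated without any recorded data.

Signal model, per trial:

* every *planted band* ``B_c`` contributes a narrow-band oscillation — a sum
  of sinusoids with frequencies drawn uniformly inside ``B_c`` — present on
  the configured source channels in **all** trials;
* in trials of class ``c`` the oscillation of band ``B_c`` is attenuated by
  ``(1 - erd_depth)`` in amplitude, i.e. ``(1 - erd_depth)**2`` in power:
  the active class desynchronizes its own rhythm;
* each trial additionally draws a log-normal amplitude multiplier per band
  (mean-square one, shared across source channels), modelling the strong
  trial-to-trial variability of single-trial rhythm power — without it the
  variance contrast would be deterministic and any decoder would separate
  the classes perfectly, which recorded EEG never allows;
* class-independent *distractor rhythms* (theta and beta-range by default)
  with the same per-trial amplitude variability occupy bands outside the
  planted ones: task-irrelevant oscillations whose fluctuating power
  penalizes banks that cover them, which is the reason sub-band selection
  matters for real EEG in the first place;
* a 1/f-shaped Gaussian noise floor, independent across channels and
  trials, models the broadband EEG background;
* source activity leaks into the remaining channels through a fixed,
  seeded random mixing matrix with small gains, giving CSP a spatial
  pattern to find.

Class information therefore lives only inside the planted bands; outside
them the classes are statistically exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .containers import EpochSet
from .exceptions import ConfigurationError

__all__ = ["SynthConfig", "generate_epochs", "band_power"]

#: Default planted bands per class: mu-band rhythms first, then beta.
_DEFAULT_BANDS = [(10.0, 14.0), (20.0, 24.0), (8.0, 12.0), (26.0, 30.0)]

#: Default class-independent distractor rhythms (theta, low/high beta).
_DEFAULT_DISTRACTORS = [(4.0, 8.0), (15.0, 19.0), (25.0, 30.0)]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic ERD/ERS generator.

    Defaults mirror a single BCI Competition IV-2a-style session: 22
    channels at 250 Hz, 4-second imagery epochs.

    Parameters
    ----------
    n_classes : int
        Number of imagery classes (2-4).
    trials_per_class : int
        Trials generated per class.
    planted_bands : list of (low, high)
        One discriminative band per class (index = class carrying the ERD).
        May be shorter than ``n_classes``: classes without a band show no
        power modulation of their own, so discrimination is confined to the
        listed bands. ``None`` selects mu/beta presets.
    erd_depth : float in [0, 1)
        Fractional amplitude attenuation of the active class's oscillation.
        Band power of the active class is ``(1 - erd_depth)**2`` times that
        of the inactive classes.
    source_channels : tuple of int
        Channels carrying the oscillations at unit gain.
    osc_amplitude : float
        RMS amplitude (microvolt) of each planted oscillation at a source
        channel, before ERD attenuation.
    noise_scale : float
        RMS amplitude (microvolt) of the 1/f background per channel.
    amplitude_jitter : float
        Log-standard-deviation of the per-trial, per-band amplitude
        multiplier (0 disables it). The multiplier has unit mean square,
        so expected band powers — and the ERD power ratio — are unchanged.
    distractor_bands : list of (low, high)
        Class-independent rhythms present in every trial with the same
        per-trial amplitude jitter; empty list disables them.
    distractor_amplitude : float
        RMS amplitude (microvolt) of each distractor rhythm at the source
        channels.
    """

    n_classes: int = 2
    trials_per_class: int = 40
    n_channels: int = 22
    fs: float = 250.0
    epoch_len: float = 4.0
    planted_bands: list[tuple[float, float]] | None = None
    erd_depth: float = 0.5
    source_channels: tuple[int, ...] = (0, 1)
    osc_amplitude: float = 10.0
    noise_scale: float = 8.0
    amplitude_jitter: float = 0.4
    distractor_bands: list[tuple[float, float]] | None = None
    distractor_amplitude: float = 10.0
    n_sinusoids: int = 3
    mixing_gain: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_classes <= 4:
            raise ConfigurationError(f"n_classes must be 2-4, got {self.n_classes}")
        if self.trials_per_class < 1:
            raise ConfigurationError("trials_per_class must be >= 1")
        if not 0.0 <= self.erd_depth < 1.0:
            raise ConfigurationError(f"erd_depth must be in [0, 1), got {self.erd_depth}")
        if self.fs <= 0 or self.epoch_len <= 0:
            raise ConfigurationError("fs and epoch_len must be positive")
        bands = self.planted_bands
        if bands is None:
            bands = _DEFAULT_BANDS[: self.n_classes]
        bands = [(float(lo), float(hi)) for lo, hi in bands]
        nyq = self.fs / 2.0
        for lo, hi in bands:
            if not (0.0 < lo < hi <= nyq):
                raise ConfigurationError(
                    f"planted band ({lo}, {hi}) must satisfy 0 < low < high <= {nyq}"
                )
        if len(bands) > self.n_classes:
            raise ConfigurationError("more planted bands than classes")
        if any(not 0 <= c < self.n_channels for c in self.source_channels):
            raise ConfigurationError("source_channels out of range")
        object.__setattr__(self, "planted_bands", bands)
        distractors = self.distractor_bands
        if distractors is None:
            distractors = [
                (lo, hi) for lo, hi in _DEFAULT_DISTRACTORS if hi <= nyq
            ]
        distractors = [(float(lo), float(hi)) for lo, hi in distractors]
        for lo, hi in distractors:
            if not (0.0 < lo < hi <= nyq):
                raise ConfigurationError(
                    f"distractor band ({lo}, {hi}) must satisfy 0 < low < high <= {nyq}"
                )
        object.__setattr__(self, "distractor_bands", distractors)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_len))


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      fs: float, rms: float) -> np.ndarray:
    """Gaussian noise with a 1/f power spectrum, unit-free RMS = ``rms``."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    # power ~ 1/f above 0.5 Hz; flat below to avoid the DC singularity
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 0.5))
    shaping[0] = 0.0  # no DC component
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=-1) * shaping
    noise = np.fft.irfft(spectrum, n=n_samples, axis=-1)
    scale = noise.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return noise / scale * rms


def generate_epochs(cfg: SynthConfig) -> EpochSet:
    """Generate a labeled :class:`EpochSet` per the planted-ERD model.

    Deterministic for a fixed ``cfg.seed``: the same configuration always
    yields bit-identical data. Trials are generated class-blocked then left
    in that order (class 0 trials first); downstream cross-validation
    shuffles, so no separate permutation is applied here.
    """
    rng = np.random.default_rng(cfg.seed)
    n_trials = cfg.n_classes * cfg.trials_per_class
    n_samp = cfg.n_samples
    t = np.arange(n_samp) / cfg.fs
    labels = np.repeat(np.arange(cfg.n_classes), cfg.trials_per_class)

    n_src = len(cfg.source_channels)
    # fixed leakage of each source channel into every non-source channel
    mixing = np.zeros((cfg.n_channels, n_src))
    for j, ch in enumerate(cfg.source_channels):
        mixing[ch, j] = 1.0
    others = [c for c in range(cfg.n_channels) if c not in cfg.source_channels]
    if others:
        gains = rng.uniform(-cfg.mixing_gain, cfg.mixing_gain, size=(len(others), n_src))
        mixing[others, :] = gains

    # per-sinusoid amplitude so the summed oscillation has RMS osc_amplitude
    amp = cfg.osc_amplitude * np.sqrt(2.0 / cfg.n_sinusoids)

    data = np.empty((n_trials, cfg.n_channels, n_samp))
    for i in range(n_trials):
        sources = np.zeros((n_src, n_samp))
        for c, (lo, hi) in enumerate(cfg.planted_bands):
            att = (1.0 - cfg.erd_depth) if labels[i] == c else 1.0
            if cfg.amplitude_jitter > 0:
                # unit-mean-square multiplier: E[g^2] = 1
                g = np.exp(cfg.amplitude_jitter * rng.standard_normal()
                           - cfg.amplitude_jitter**2)
            else:
                g = 1.0
            att = att * g
            for j in range(n_src):
                freqs = rng.uniform(lo, hi, size=cfg.n_sinusoids)
                phases = rng.uniform(0.0, 2.0 * np.pi, size=cfg.n_sinusoids)
                osc = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :]
                             + phases[:, None]).sum(axis=0)
                sources[j] += att * amp * osc
        d_amp = cfg.distractor_amplitude * np.sqrt(2.0 / cfg.n_sinusoids)
        for lo, hi in cfg.distractor_bands:
            if cfg.amplitude_jitter > 0:
                g = np.exp(cfg.amplitude_jitter * rng.standard_normal()
                           - cfg.amplitude_jitter**2)
            else:
                g = 1.0
            for j in range(n_src):
                freqs = rng.uniform(lo, hi, size=cfg.n_sinusoids)
                phases = rng.uniform(0.0, 2.0 * np.pi, size=cfg.n_sinusoids)
                osc = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :]
                             + phases[:, None]).sum(axis=0)
                sources[j] += g * d_amp * osc
        noise = _one_over_f_noise(rng, cfg.n_channels, n_samp, cfg.fs, cfg.noise_scale)
        data[i] = mixing @ sources + noise

    names = [f"ch{i}" for i in range(cfg.n_channels)]
    return EpochSet(data=data, labels=labels, fs=cfg.fs, channel_names=names)


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Average power of ``x`` inside ``band`` (Welch PSD integral, uV^2).

    Integrates the Welch power spectral density over ``[low, high]``, so
    summing over a partition of ``(0, fs/2)`` recovers the signal variance
    (Parseval). Multi-channel input is averaged over leading axes.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot estimate band power of an empty signal")
    lo, hi = float(band[0]), float(band[1])
    if not (0.0 <= lo < hi <= fs / 2.0):
        raise ConfigurationError(f"band ({lo}, {hi}) outside (0, {fs / 2})")
    nperseg = min(x.shape[-1], 256)
    freqs, psd = _sig.welch(x, fs=fs, nperseg=nperseg, axis=-1)
    if psd.ndim > 1:
        psd = psd.mean(axis=tuple(range(psd.ndim - 1)))
    mask = (freqs >= lo) & (freqs <= hi)
    if not np.any(mask):
        return 0.0
    df = freqs[1] - freqs[0]
    return float(np.sum(psd[mask]) * df)
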