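"""Frequency bands, filter banks, and per-band filtering.

A filter bank is an ordered list of (low, high) pass-bands in Hz. Banks
produced by the sparrow-search optimizer may overlap and may leave gaps:
individually optimized banks routinely do, and nothing in the CSP feature
pipeline requires a partition of the spectrum. The default search range is
4-40 Hz, covering the sensorimotor mu (8-12 Hz) and beta (13-30 Hz)
rhythms where motor-imagery contrast concentrates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .containers import EpochSet
from .exceptions import ConfigurationError

__all__ = [
    "FrequencyBand",
    "FilterBank",
    "make_uniform_bank",
    "bank_from_position",
    "position_from_bank",
    "apply_band",
    "band_sos",
]

#: Default search range for band optimization, Hz.
F_MIN_DEFAULT = 4.0
F_MAX_DEFAULT = 40.0


@dataclass(frozen=True, order=True)
class FrequencyBand:
    """A pass-band ``(low, high)`` in Hz with ``0 < low < high``."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ConfigurationError(
                f"invalid band ({self.low}, {self.high}): need 0 < low < high"
            )
        object.__setattr__(self, "low", float(self.low))
        object.__setattr__(self, "high", float(self.high))

    @property
    def width(self) -> float:
        return self.high - self.low

    def overlap(self, other: "FrequencyBand") -> float:
        """Width in Hz of the intersection with ``other`` (0 if disjoint)."""
        return max(0.0, min(self.high, other.high) - max(self.low, other.low))


@dataclass(frozen=True)
class FilterBank:
    """Ordered collection of :class:`FrequencyBand`, sorted by low edge."""

    bands: tuple[FrequencyBand, ...]

    def __post_init__(self) -> None:
        bands = tuple(
            b if isinstance(b, FrequencyBand) else FrequencyBand(*b)
            for b in self.bands
        )
        if len(bands) == 0:
            raise ConfigurationError("a filter bank needs at least one band")
        bands = tuple(sorted(bands, key=lambda b: (b.low, b.high)))
        object.__setattr__(self, "bands", bands)

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, i: int) -> FrequencyBand:
        return self.bands[i]

    @property
    def n(self) -> int:
        return len(self.bands)

    def edges(self) -> list[list[float]]:
        """Bank as a JSON-ready list of ``[low, high]`` pairs."""
        return [[b.low, b.high] for b in self.bands]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.edges()))

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterBank":
        pairs = json.loads(Path(path).read_text())
        return cls(tuple(FrequencyBand(lo, hi) for lo, hi in pairs))


def make_uniform_bank(
    n: int, f_min: float = F_MIN_DEFAULT, f_max: float = F_MAX_DEFAULT
) -> FilterBank:
    """``n`` contiguous equal-width bands spanning ``[f_min, f_max]``.

    ``make_uniform_bank(9)`` gives the classical fixed filter bank
    (4-8, 8-12, ..., 36-40 Hz) used by uniform filter-bank CSP.
    """
    if n < 1:
        raise ConfigurationError(f"need at least one band, got n={n}")
    if not f_min < f_max:
        raise ConfigurationError(f"need f_min < f_max, got ({f_min}, {f_max})")
    edges = np.linspace(f_min, f_max, n + 1)
    return FilterBank(tuple(FrequencyBand(lo, hi) for lo, hi in zip(edges, edges[1:])))


def bank_from_position(position: Sequence[float]) -> FilterBank:
    """Decode a band-configuration vector into a :class:`FilterBank`.

    The position vector holds ``2 n`` raw Hz values: consecutive pairs are
    the (low, high) edges of each band. The vector must already be feasible
    (each pair ordered, positive); the optimizer's repair step guarantees
    this for every position it evaluates.
    """
    position = np.asarray(position, dtype=float)
    if position.ndim != 1 or position.size % 2 != 0 or position.size == 0:
        raise ConfigurationError(
            f"position must be a flat vector of 2n values, got shape {position.shape}"
        )
    pairs = position.reshape(-1, 2)
    if np.any(pairs[:, 0] >= pairs[:, 1]) or np.any(pairs[:, 0] <= 0):
        raise ConfigurationError(
            "position is not repaired: every pair needs 0 < low < high"
        )
    return FilterBank(tuple(FrequencyBand(lo, hi) for lo, hi in pairs))


def position_from_bank(bank: FilterBank) -> np.ndarray:
    """Inverse of :func:`bank_from_position` (bands flattened in sorted order)."""
    return np.asarray([e for band in bank for e in (band.low, band.high)])


def band_sos(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    """Second-order sections of the band-pass filter used throughout.

    Butterworth characteristic of the given ``order``, applied
    forward-backward (zero phase) by :func:`apply_band`, so the effective
    attenuation is twice the one-pass magnitude response.
    """
    nyq = fs / 2.0
    if not (0.0 < low < high):
        raise ConfigurationError(f"invalid band ({low}, {high})")
    if high >= nyq:
        raise ConfigurationError(
            f"band edge {high} Hz at or above Nyquist ({nyq} Hz)"
        )
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def filter_array(
    data: np.ndarray, low: float, high: float, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase band-pass along the last axis of ``data``."""
    sos = band_sos(low, high, fs, order=order)
    return signal.sosfiltfilt(sos, data, axis=-1)


def apply_band(epochs: EpochSet, band: FrequencyBand | Iterable[float]) -> EpochSet:
    """Band-pass every trial and channel through ``band``, zero phase."""
    if not isinstance(band, FrequencyBand):
        band = FrequencyBand(*band)
    return epochs.with_data(filter_array(epochs.data, band.low, band.high, epochs.fs))
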