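"""Core in-memory containers shared across the pipeline stages.

The containers are thin dataclasses around numpy arrays with the invariants
each stage relies on checked at construction time:

``SignalTrial``
    a raw (or filtered) multi-channel time-domain recording,
``EpochSet``
    the trial cut into fixed-length overlapping windows,
``Spectrum`` / ``SpectraMatrix``
    one-sided magnitude spectra on the uniform 1-Hz analysis grid; the
    matrix stacks one row per (epoch, channel) pair and is the object the
    non-negative factorization consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["SignalTrial", "EpochSet", "Spectrum", "SpectraMatrix"]


@dataclass
class SignalTrial:
    """Multi-channel time-domain recording.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples, n_channels)``, voltages in arbitrary
        units, time along axis 0.
    fs
        Sampling rate in Hz.
    channel_ids
        One label per channel (e.g. ``"ch05"`` ... ``"ch16"``).
    meta
        Free-form trial metadata; the pipeline uses ``subject``, ``trial``
        and ``fatigue`` (self-reported 0-10 scale) when present.
    """

    samples: np.ndarray
    fs: float
    channel_ids: list[str] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise InvalidInputError("samples must be a (n_samples, n_channels) array")
        if not self.fs > 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("samples contain non-finite values")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i + 5:02d}" for i in range(self.n_channels)]
        if len(self.channel_ids) != self.n_channels:
            raise InvalidInputError(
                f"{len(self.channel_ids)} channel ids for {self.n_channels} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Trial duration in seconds (samples / fs)."""
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "SignalTrial":
        """Copy of this trial with the sample array replaced."""
        return SignalTrial(samples, self.fs, list(self.channel_ids), dict(self.meta))


@dataclass
class EpochSet:
    """Windowed view of a trial: ``epochs[epoch, channel, sample]``."""

    epochs: np.ndarray
    epoch_start_times: np.ndarray
    window_length: float
    step: float
    fs: float
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.epoch_start_times = np.asarray(self.epoch_start_times, dtype=float)
        if self.epochs.ndim != 3:
            raise InvalidInputError("epochs must have shape (n_epochs, n_channels, n_samples)")
        expected = int(round(self.window_length * self.fs))
        if self.epochs.shape[2] != expected:
            raise InvalidInputError(
                f"epochs hold {self.epochs.shape[2]} samples, expected {expected}"
            )
        if len(self.epoch_start_times) != self.epochs.shape[0]:
            raise InvalidInputError("one start time required per epoch")
        if len(self.epoch_start_times) > 1:
            diffs = np.diff(self.epoch_start_times)
            if np.any(diffs <= 0) or not np.allclose(diffs, self.step, atol=1e-9):
                raise InvalidInputError("start times must increase by the step size")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i + 5:02d}" for i in range(self.n_channels)]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


@dataclass
class Spectrum:
    """One-sided magnitude spectrum on a uniform frequency grid."""

    frequencies: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.frequencies.shape != self.magnitude.shape or self.frequencies.ndim != 1:
            raise InvalidInputError("frequency grid and magnitude must be 1-D and equal length")
        if len(self.frequencies) > 1:
            d = np.diff(self.frequencies)
            if np.any(d <= 0) or not np.allclose(d, d[0]):
                raise InvalidInputError("frequency grid must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.magnitude)) or np.any(self.magnitude < 0):
            raise InvalidInputError("magnitudes must be finite and nonnegative")


@dataclass
class SpectraMatrix:
    """Stack of per-(epoch, channel) magnitude spectra.

    ``values`` is ``(m, f)`` with ``m = n_epochs * n_channels`` rows in
    epoch-major order; ``row_index[i]`` is the ``(epoch_index, channel_id)``
    pair behind row ``i``.
    """

    values: np.ndarray
    row_index: list[tuple[int, str]]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("values must be a 2-D (rows, frequencies) array")
        if self.values.shape[1] != len(self.frequencies):
            raise InvalidInputError("one column required per frequency bin")
        if len(self.row_index) != self.values.shape[0]:
            raise InvalidInputError("one (epoch, channel) entry required per row")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise InvalidInputError("spectral values must be finite and nonnegative")
        self.row_index = [(int(e), str(c)) for e, c in self.row_index]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def row_spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.frequencies, self.values[i])

    @property
    def epochs(self) -> list[int]:
        """Sorted unique epoch indices present in the matrix."""
        return sorted({e for e, _ in self.row_index})

    @property
    def channels(self) -> list[str]:
        """Channel ids in first-appearance order."""
        seen: dict[str, None] = {}
        for _, c in self.row_index:
            seen.setdefault(c)
        return list(seen)
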