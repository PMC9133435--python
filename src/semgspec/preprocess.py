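"""Signal conditioning and epoching.

The conditioning chain, applied per channel with zero-phase
(forward-backward) Butterworth filters, is: 1-Hz high-pass DC removal,
optional mains notch (60 Hz default), 8-200 Hz band-pass. The conditioned
trial is then cut into 1-s windows stepped by 0.5 s; window starts are
``k * step`` for ``k = 0 ... floor(duration/step) - 1`` and a trailing
partial window is zero-padded, so a 30-s trial yields exactly 60 epochs.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal as sps

from .containers import EpochSet, SignalTrial
from .exceptions import InvalidParameterError

__all__ = ["remove_dc", "notch", "bandpass", "epoch"]


def remove_dc(trial: SignalTrial, cutoff: float = 1.0, order: int = 4) -> SignalTrial:
    """Zero-phase Butterworth high-pass removing the DC component."""
    nyq = trial.fs / 2.0
    if not 0 < cutoff < nyq:
        raise InvalidParameterError(f"high-pass cutoff {cutoff} Hz must lie in (0, {nyq}) Hz")
    sos = sps.butter(order, cutoff, btype="highpass", fs=trial.fs, output="sos")
    return trial.with_samples(sps.sosfiltfilt(sos, trial.samples, axis=0))


def notch(
    trial: SignalTrial, f0: float = 60.0, q: float = 30.0, enabled: bool = True
) -> SignalTrial:
    """Zero-phase IIR notch at the mains frequency; identity when disabled."""
    if not enabled:
        return trial
    nyq = trial.fs / 2.0
    if not 0 < f0 < nyq:
        raise InvalidParameterError(f"notch frequency {f0} Hz must lie in (0, {nyq}) Hz")
    b, a = sps.iirnotch(f0, q, fs=trial.fs)
    return trial.with_samples(sps.filtfilt(b, a, trial.samples, axis=0))


def bandpass(
    trial: SignalTrial, low: float = 8.0, high: float = 200.0, order: int = 4
) -> SignalTrial:
    """Zero-phase Butterworth band-pass onto the analysis band."""
    nyq = trial.fs / 2.0
    if not 0 < low < high < nyq:
        raise InvalidParameterError(
            f"band [{low}, {high}] Hz must satisfy 0 < low < high < {nyq} Hz"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=trial.fs, output="sos")
    return trial.with_samples(sps.sosfiltfilt(sos, trial.samples, axis=0))


def epoch(trial: SignalTrial, window: float = 1.0, step: float = 0.5) -> EpochSet:
    """Cut the trial into ``window``-long epochs stepped by ``step`` seconds.

    Epoch ``k`` starts at ``k * step``; the count is
    ``floor(duration / step)`` and any trailing partial window is
    zero-padded to full length. Non-padded samples are copied bit-exactly.
    """
    duration = trial.duration
    if window > duration + 1e-9:
        raise InvalidParameterError(
            f"window {window} s exceeds trial duration {duration:.6g} s"
        )
    if not 0 < step <= window:
        raise InvalidParameterError(f"step {step} s must satisfy 0 < step <= window {window} s")
    win_samples = int(round(window * trial.fs))
    n_epochs = int(math.floor(duration / step + 1e-9))
    step_samples = step * trial.fs
    epochs = np.zeros((n_epochs, trial.n_channels, win_samples))
    for k in range(n_epochs):
        start = int(round(k * step_samples))
        stop = min(start + win_samples, trial.n_samples)
        epochs[k, :, : stop - start] = trial.samples[start:stop].T
    starts = np.arange(n_epochs) * step
    return EpochSet(epochs, starts, window, step, trial.fs, list(trial.channel_ids))
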