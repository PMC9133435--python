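"""Per-epoch magnitude spectra and scalar spectral descriptors.

Spectra are one-sided FFT amplitudes on a uniform 1-Hz grid restricted to
the analysis band (8-200 Hz by default, 193 bins), with the ``2/N``
normalization that maps a unit-amplitude bin-centered sinusoid to a
magnitude of 1. Amplitude (not power) spectra feed the factorization;
power enters only inside :func:`median_frequency`, which uses the
cumulative squared-magnitude half-point on the discrete grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .containers import EpochSet, SpectraMatrix, Spectrum
from .exceptions import InvalidInputError, InvalidParameterError, UndefinedMedianError

__all__ = [
    "DEFAULT_BAND",
    "BandStatistics",
    "band_grid",
    "compute_spectrum",
    "spectra_matrix",
    "smooth_envelope",
    "smooth_matrix",
    "band_statistics",
    "median_frequency",
    "median_frequency_rows",
    "spectral_centroid",
    "energy",
]

DEFAULT_BAND: tuple[float, float] = (8.0, 200.0)


def band_grid(band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
    """Uniform 1-Hz frequency grid covering ``band`` inclusive."""
    low, high = band
    return np.arange(float(np.ceil(low)), float(np.floor(high)) + 0.5, 1.0)


def compute_spectrum(
    samples: np.ndarray, fs: float, band: tuple[float, float] = DEFAULT_BAND
) -> Spectrum:
    """One-sided FFT magnitude of a 1-s epoch, restricted to ``band``.

    The epoch must hold exactly ``fs`` samples so the FFT bin spacing is
    1 Hz. Magnitudes are scaled by ``2/N``: a unit-amplitude sinusoid at a
    bin center yields magnitude 1 at its bin.
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = int(round(fs))
    if len(x) != n:
        raise InvalidInputError(
            f"epoch holds {len(x)} samples; need exactly fs = {n} for 1-Hz resolution"
        )
    mag = (2.0 / n) * np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    return Spectrum(freqs[mask], mag[mask])


def spectra_matrix(epochs: EpochSet, band: tuple[float, float] = DEFAULT_BAND) -> SpectraMatrix:
    """Stack per-(epoch, channel) spectra into the matrix the NMF consumes.

    Rows are epoch-major: all channels of epoch 0, then epoch 1, ...
    """
    n = epochs.epochs.shape[2]
    if n != int(round(epochs.fs)):
        raise InvalidInputError("epochs must be 1 s long (fs samples) for 1-Hz bins")
    flat = epochs.epochs.reshape(-1, n)  # (n_epochs*n_channels, n)
    mag = (2.0 / n) * np.abs(np.fft.rfft(flat, axis=1))
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.fs)
    mask = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    rows = [
        (e, ch)
        for e in range(epochs.n_epochs)
        for ch in epochs.channel_ids
    ]
    return SpectraMatrix(mag[:, mask], rows, freqs[mask])


def _moving_average(values: np.ndarray, window_bins: int) -> np.ndarray:
    # truncated-and-renormalized centered moving average along the last axis
    sums = uniform_filter1d(values, size=window_bins, axis=-1, mode="constant", cval=0.0)
    counts = uniform_filter1d(
        np.ones(values.shape[-1]), size=window_bins, mode="constant", cval=0.0
    )
    # guard against tiny negative round-off on nonnegative inputs
    return np.maximum(sums / counts, 0.0)


def smooth_envelope(spec: Spectrum, window_bins: int = 5) -> Spectrum:
    """Centered moving average emphasizing the spectral envelope.

    Edge windows are truncated and renormalized (mean of the available
    bins), so a constant spectrum is reproduced exactly.
    """
    if window_bins < 1 or window_bins % 2 == 0:
        raise InvalidParameterError(f"window_bins must be odd and >= 1, got {window_bins}")
    return Spectrum(spec.frequencies, _moving_average(spec.magnitude, window_bins))


def smooth_matrix(spectra: SpectraMatrix, window_bins: int = 5) -> SpectraMatrix:
    """Row-wise :func:`smooth_envelope` over a whole spectra matrix."""
    if window_bins < 1 or window_bins % 2 == 0:
        raise InvalidParameterError(f"window_bins must be odd and >= 1, got {window_bins}")
    return SpectraMatrix(
        _moving_average(spectra.values, window_bins), spectra.row_index, spectra.frequencies
    )


@dataclass
class BandStatistics:
    """Across-row variability and energy per frequency, with the band both
    statistics select when thresholded at their value at ``reference_freq``."""

    frequencies: np.ndarray
    std_per_freq: np.ndarray
    rms_per_freq: np.ndarray
    reference_freq: float
    selected_band: tuple[float, float] | None


def band_statistics(spectra: SpectraMatrix, reference_freq: float = 8.0) -> BandStatistics:
    """Per-frequency std and RMS across rows; select the informative band.

    The selected band is the longest contiguous frequency run on which both
    the standard deviation and the RMS strictly exceed their values at the
    reference frequency.
    """
    if spectra.n_rows < 2:
        raise InvalidInputError("at least 2 rows needed for across-row statistics")
    freqs = spectra.frequencies
    std = spectra.values.std(axis=0, ddof=1)
    rms = np.sqrt(np.mean(spectra.values**2, axis=0))
    idx = int(np.argmin(np.abs(freqs - reference_freq)))
    if abs(freqs[idx] - reference_freq) > 1e-9:
        warnings.warn(
            f"reference frequency {reference_freq} Hz is off-grid; "
            f"using nearest bin {freqs[idx]} Hz",
            stacklevel=2,
        )
    mask = (std > std[idx]) & (rms > rms[idx])
    selected = _longest_run(mask)
    band = None
    if selected is not None:
        band = (float(freqs[selected[0]]), float(freqs[selected[1]]))
    return BandStatistics(freqs, std, rms, float(freqs[idx]), band)


def _longest_run(mask: np.ndarray) -> tuple[int, int] | None:
    best: tuple[int, int] | None = None
    start = None
    for i, flag in enumerate(list(mask) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if best is None or (i - start) > (best[1] - best[0] + 1):
                best = (start, i - 1)
            start = None
    return best


def median_frequency(spec: Spectrum) -> float:
    """Smallest grid frequency at which cumulative power reaches half the total.

    Power is squared magnitude; no inter-bin interpolation, so the result
    always lies on the grid.
    """
    power = spec.magnitude**2
    total = power.sum()
    if total <= 0:
        raise UndefinedMedianError("median frequency undefined for an all-zero spectrum")
    cum = np.cumsum(power)
    idx = int(np.searchsorted(cum, 0.5 * total - 1e-12 * total))
    return float(spec.frequencies[idx])


def median_frequency_rows(values: np.ndarray, frequencies: np.ndarray) -> np.ndarray:
    """Vectorized :func:`median_frequency` over rows; NaN where power is zero."""
    power = np.asarray(values, dtype=float) ** 2
    total = power.sum(axis=1, keepdims=True)
    out = np.full(power.shape[0], np.nan)
    ok = total[:, 0] > 0
    if np.any(ok):
        cum = np.cumsum(power[ok], axis=1)
        half = 0.5 * total[ok] * (1 - 2e-12)
        idx = (cum < half).sum(axis=1)
        out[ok] = frequencies[idx]
    return out


def spectral_centroid(spec: Spectrum) -> float:
    """Magnitude-weighted mean frequency."""
    total = spec.magnitude.sum()
    if total <= 0:
        raise UndefinedMedianError("centroid undefined for an all-zero spectrum")
    return float(np.sum(spec.frequencies * spec.magnitude) / total)


def energy(spec: Spectrum) -> float:
    """Area under the magnitude curve (trapezoidal rule), in a.u. x Hz."""
    if len(spec.frequencies) < 2:
        return 0.0
    return float(np.trapezoid(spec.magnitude, spec.frequencies))
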