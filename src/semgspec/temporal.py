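"""Per-component energy and median-frequency time-courses during contraction.

Each epoch's component contributions are reduced to areas under the
magnitude curve (one energy per component per epoch), giving per-channel
time-courses that can be aggregated across channels, trials and subjects by
pointwise means. Second-order polynomial trends summarize each curve, and
the energy crossover — the first time at which the low-frequency
component's energy reaches and thereafter stays at or above the
high-frequency component's — marks the low-frequency takeover during
sustained contraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import SpectraMatrix
from .decompose import ComponentContributions
from .exceptions import InvalidInputError
from .spectral import median_frequency_rows

__all__ = [
    "EnergyTimecourse",
    "MedianFrequencyTimecourse",
    "TrendFit",
    "energy_timecourse",
    "aggregate",
    "fit_trend",
    "polynomial_trend",
    "crossover_time",
    "medfreq_timecourse",
]

logger = logging.getLogger(__name__)


@dataclass
class EnergyTimecourse:
    """Total and per-component spectral energy per epoch.

    ``components`` is ``(n_components, n_epochs)``; the total equals the
    component sum at every epoch by construction. SD arrays are populated
    by :func:`aggregate`.
    """

    times: np.ndarray
    total: np.ndarray
    components: np.ndarray
    labels: list[str]
    scope: str = "channel"
    scope_id: str = ""
    total_sd: np.ndarray | None = None
    components_sd: np.ndarray | None = None
    count: int = 1

    def component(self, label: str) -> np.ndarray:
        return self.components[self.labels.index(label)]


@dataclass
class MedianFrequencyTimecourse:
    """Median frequency of the total spectrum and of each component
    contribution, per epoch (NaN where an epoch has zero power)."""

    times: np.ndarray
    total: np.ndarray
    components: np.ndarray
    labels: list[str]
    channel: str = ""


@dataclass
class TrendFit:
    """Least-squares degree-2 polynomial fit of a time-course.

    ``coefficients`` are in descending powers ``(a2, a1, a0)`` so the fit
    is ``a2 t^2 + a1 t + a0``.
    """

    coefficients: np.ndarray
    rss: float
    scope: str = ""


def _trapz_rows(values: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    return np.trapezoid(values, freqs, axis=-1)


def energy_timecourse(
    contributions: ComponentContributions, step: float = 0.5
) -> dict[str, EnergyTimecourse]:
    """Per-channel energy time-courses from the extracted contributions.

    Returns one :class:`EnergyTimecourse` per channel id; the per-epoch
    total is the sum of the component energies (which equals the raw
    spectrum's energy, since contributions conserve the raw spectrum).
    """
    if contributions.values.size == 0:
        raise InvalidInputError("no contribution rows to integrate")
    comp_energy = _trapz_rows(contributions.values, contributions.frequencies)  # (m, n)
    epochs = sorted({e for e, _ in contributions.row_index})
    chans: dict[str, None] = {}
    for _, c in contributions.row_index:
        chans.setdefault(c)
    epoch_pos = {e: i for i, e in enumerate(epochs)}
    n_comp = contributions.values.shape[1]
    per_channel: dict[str, np.ndarray] = {
        c: np.full((n_comp, len(epochs)), np.nan) for c in chans
    }
    for row, (e, c) in enumerate(contributions.row_index):
        per_channel[c][:, epoch_pos[e]] = comp_energy[row]
    times = np.asarray(epochs, dtype=float) * step
    out = {}
    for c, comp in per_channel.items():
        if np.any(np.isnan(comp)):
            raise InvalidInputError(f"channel {c} is missing decomposed epochs")
        out[c] = EnergyTimecourse(
            times, comp.sum(axis=0), comp, list(contributions.labels), "channel", c
        )
    return out


def aggregate(
    timecourses: list[EnergyTimecourse], level: str = "grand"
) -> EnergyTimecourse:
    """Pointwise mean (with sample SD) across a list of aligned time-courses."""
    if not timecourses:
        raise InvalidInputError("nothing to aggregate")
    ref = timecourses[0]
    for tc in timecourses[1:]:
        if len(tc.times) != len(ref.times) or not np.allclose(tc.times, ref.times):
            raise InvalidInputError("time grids are not aligned")
        if tc.labels != ref.labels:
            raise InvalidInputError("component labels differ across time-courses")
    totals = np.stack([tc.total for tc in timecourses])
    comps = np.stack([tc.components for tc in timecourses])
    ddof = 1 if len(timecourses) > 1 else 0
    return EnergyTimecourse(
        ref.times,
        totals.mean(axis=0),
        comps.mean(axis=0),
        list(ref.labels),
        level,
        "",
        totals.std(axis=0, ddof=ddof),
        comps.std(axis=0, ddof=ddof),
        len(timecourses),
    )


def polynomial_trend(times: np.ndarray, values: np.ndarray, scope: str = "") -> TrendFit:
    """Degree-2 least-squares fit of ``values`` against ``times``."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 3:
        raise InvalidInputError(f"need >= 3 time points to fit a parabola, got {len(t)}")
    coeffs = np.polyfit(t, y, deg=2)
    rss = float(np.sum((np.polyval(coeffs, t) - y) ** 2))
    return TrendFit(coeffs, rss, scope)


def fit_trend(tc: EnergyTimecourse, which: str = "total") -> TrendFit:
    """Fit the second-order trend of one curve of a time-course.

    ``which`` is ``"total"`` or one of the component labels.
    """
    y = tc.total if which == "total" else tc.component(which)
    return polynomial_trend(tc.times, y, scope=f"{tc.scope}:{tc.scope_id}:{which}")


def crossover_time(
    times: np.ndarray, low: np.ndarray, high: np.ndarray
) -> float | None:
    """First time at which ``low >= high`` and remains so until the end.

    Returns ``None`` when the low curve never takes over. A sustained-
    crossing rule is used so brief noise-induced flickers do not count.
    """
    times = np.asarray(times, dtype=float)
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    if not (len(times) == len(low) == len(high)):
        raise InvalidInputError("curves and time grid must have equal length")
    at_or_above = low >= high
    # first index from which the condition holds for the rest of the trial
    holds_to_end = np.logical_and.accumulate(at_or_above[::-1])[::-1]
    idx = np.nonzero(holds_to_end)[0]
    if len(idx) == 0:
        return None
    return float(times[idx[0]])


def medfreq_timecourse(
    contributions: ComponentContributions,
    raw: SpectraMatrix,
    step: float = 0.5,
) -> dict[str, MedianFrequencyTimecourse]:
    """Per-channel median-frequency series of the total spectrum and of
    each component contribution; zero-power epochs yield NaN and are logged."""
    if raw.values.shape[0] != contributions.values.shape[0]:
        raise InvalidInputError("raw spectra and contributions must share rows")
    mf_total = median_frequency_rows(raw.values, raw.frequencies)
    n_comp = contributions.values.shape[1]
    mf_comp = np.stack(
        [
            median_frequency_rows(contributions.values[:, x, :], contributions.frequencies)
            for x in range(n_comp)
        ]
    )  # (n, m)
    n_gaps = int(np.isnan(mf_total).sum())
    if n_gaps:
        logger.info("median-frequency time-course: %d zero-power epochs skipped", n_gaps)
    epochs = sorted({e for e, _ in raw.row_index})
    chans: dict[str, None] = {}
    for _, c in raw.row_index:
        chans.setdefault(c)
    epoch_pos = {e: i for i, e in enumerate(epochs)}
    times = np.asarray(epochs, dtype=float) * step
    total_by_ch = {c: np.full(len(epochs), np.nan) for c in chans}
    comp_by_ch = {c: np.full((n_comp, len(epochs)), np.nan) for c in chans}
    for row, (e, c) in enumerate(raw.row_index):
        total_by_ch[c][epoch_pos[e]] = mf_total[row]
        comp_by_ch[c][:, epoch_pos[e]] = mf_comp[:, row]
    return {
        c: MedianFrequencyTimecourse(
            times, total_by_ch[c], comp_by_ch[c], list(contributions.labels), c
        )
        for c in chans
    }
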