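"""Non-negative factorization of the spectra matrix and contribution filters.

The per-trial spectra matrix is approximated as ``M = W . H`` with both
factors nonnegative (multiplicative-update NMF minimizing squared Frobenius
error, best of several seeded restarts). The rank is the smallest one whose
reconstruction exceeds the VAF threshold (80% by default). From the fitted
factors, per-row frequency-contribution filters

    FF_x(f) = FC_x(f) / sum_x FC_x(f),     FC_x = W[row, x] * H[x, :]

split each *raw* (unsmoothed) spectrum into per-component contributions that
sum back to it exactly. Components are ordered by ascending median
frequency and, for a two-component fit, labelled "low" and "high"; H rows
are scale-normalized to unit maximum with the inverse scale absorbed into W.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .containers import SpectraMatrix, Spectrum
from .exceptions import (
    InvalidInputError,
    InvalidParameterError,
    NoRankFoundError,
    UndefinedVafError,
)
from .spectral import median_frequency

__all__ = [
    "ComponentSet",
    "ContributionFilters",
    "ComponentContributions",
    "RankSelection",
    "nmf",
    "vaf",
    "select_n_components",
    "contribution_filters",
    "extract_contributions",
    "normalize_pair",
]


@dataclass
class ComponentSet:
    """Fitted factorization: weights ``W`` (m x n), spectra ``H`` (n x f)."""

    W: np.ndarray
    H: np.ndarray
    n: int
    frequencies: np.ndarray
    vaf_percent: float
    labels: list[str]
    row_index: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise InvalidInputError("W and H must be elementwise nonnegative")

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H

    def component_spectrum(self, x: int) -> Spectrum:
        return Spectrum(self.frequencies, self.H[x])


@dataclass
class ContributionFilters:
    """Per-row filters ``FF`` in [0, 1] and envelope contributions ``FC``,
    both shaped ``(m, n, f)``; filters sum to 1 over components at every
    (row, frequency)."""

    FF: np.ndarray
    FC: np.ndarray
    frequencies: np.ndarray
    labels: list[str]
    row_index: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class ComponentContributions:
    """Per-row split of the raw spectra: ``values[(row, x, f)]``; summing
    over components reproduces the raw spectrum exactly."""

    values: np.ndarray
    frequencies: np.ndarray
    labels: list[str]
    row_index: list[tuple[int, str]] = field(default_factory=list)

    def component_rows(self, x: int) -> np.ndarray:
        return self.values[:, x, :]


def vaf(M: np.ndarray | SpectraMatrix, M_hat: np.ndarray) -> float:
    """Variance accounted for, percent: ``(1 - ||M - M_hat||_F^2 / ||M||_F^2) * 100``."""
    m = M.values if isinstance(M, SpectraMatrix) else np.asarray(M, dtype=float)
    m_hat = np.asarray(M_hat, dtype=float)
    if m.shape != m_hat.shape:
        raise InvalidInputError(f"shape mismatch: {m.shape} vs {m_hat.shape}")
    denom = float(np.sum(m**2))
    if denom == 0.0:
        raise UndefinedVafError("VAF undefined for an all-zero reference matrix")
    return float((1.0 - np.sum((m - m_hat) ** 2) / denom) * 100.0)


def _restart_states(seed: int, restarts: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(restarts) % (2**31)


def nmf(
    M: SpectraMatrix,
    n: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    restarts: int = 10,
    refine_iter: int = 4000,
    refine_tol: float = 1e-10,
) -> ComponentSet:
    """Rank-``n`` NMF of the spectra matrix, best of ``restarts`` random
    initializations (highest VAF kept); deterministic for a fixed seed.

    The winning solution is then run to much tighter convergence
    (``refine_iter`` further multiplicative updates at ``refine_tol``):
    multiplicative updates shrink entries toward zero only geometrically,
    and the spurious residual tails left at loose tolerances leak energy
    between components in the downstream contribution filters.

    Components are reordered by ascending median frequency of the H rows
    and H rows rescaled to unit maximum (inverse scale absorbed into W).
    """
    values = M.values
    if np.any(values < 0):
        raise InvalidInputError("spectra matrix must be nonnegative")
    m, f = values.shape
    if not 1 <= n <= min(m, f):
        raise InvalidParameterError(f"rank {n} outside [1, {min(m, f)}]")
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for state in _restart_states(seed, restarts):
            model = NMF(
                n_components=n,
                init="random",
                solver="mu",
                beta_loss="frobenius",
                max_iter=max_iter,
                tol=tol,
                random_state=int(state),
            )
            W = model.fit_transform(values)
            H = model.components_
            score = vaf(values, W @ H)
            if best is None or score > best[0]:
                best = (score, W, H)
        assert best is not None
        score, W, H = best
        if refine_iter > 0:
            model = NMF(
                n_components=n,
                init="custom",
                solver="mu",
                beta_loss="frobenius",
                max_iter=refine_iter,
                tol=refine_tol,
            )
            W = model.fit_transform(values, W=W.copy(order="C"), H=H.copy(order="C"))
            H = model.components_
            score = vaf(values, W @ H)
    # order components by ascending median frequency; zero rows sort last
    medians = []
    for x in range(n):
        if np.any(H[x] > 0):
            medians.append(median_frequency(Spectrum(M.frequencies, H[x])))
        else:
            medians.append(np.inf)
    order = np.argsort(medians, kind="stable")
    W, H = W[:, order], H[order]
    # unit-max H rows, inverse scale into W
    scales = H.max(axis=1)
    nz = scales > 0
    H[nz] /= scales[nz, None]
    W[:, nz] *= scales[nz]
    labels = ["low", "high"] if n == 2 else [f"comp{x + 1}" for x in range(n)]
    return ComponentSet(W, H, n, M.frequencies, score, labels, list(M.row_index))


@dataclass
class RankSelection:
    """Smallest rank whose VAF beats the threshold, plus the whole curve."""

    n: int
    vaf_curve: dict[int, float]
    vaf_threshold: float


def select_n_components(
    M: SpectraMatrix,
    vaf_threshold: float = 80.0,
    n_max: int = 10,
    seed: int = 0,
    **nmf_kwargs,
) -> RankSelection:
    """Smallest rank in 1..n_max with VAF strictly above the threshold."""
    curve: dict[int, float] = {}
    limit = min(n_max, min(M.values.shape))
    for n in range(1, limit + 1):
        curve[n] = nmf(M, n, seed=seed, **nmf_kwargs).vaf_percent
        if curve[n] > vaf_threshold:
            return RankSelection(n, curve, vaf_threshold)
    raise NoRankFoundError(
        f"no rank up to {limit} reached VAF > {vaf_threshold}%", curve
    )


def contribution_filters(components: ComponentSet) -> ContributionFilters:
    """Per-row frequency-contribution filters from the fitted factors.

    ``FC_x = W[row, x] * H[x, :]``; ``FF_x = FC_x / sum_x FC_x``, with the
    even split ``1/n`` wherever the denominator is zero. The filters are
    invariant to the W/H scale ambiguity.
    """
    FC = components.W[:, :, None] * components.H[None, :, :]  # (m, n, f)
    denom = FC.sum(axis=1, keepdims=True)
    n = components.n
    with np.errstate(invalid="ignore", divide="ignore"):
        FF = np.where(denom > 0, FC / np.where(denom > 0, denom, 1.0), 1.0 / n)
    return ContributionFilters(
        FF, FC, components.frequencies, list(components.labels), list(components.row_index)
    )


def extract_contributions(
    raw: SpectraMatrix, filters: ContributionFilters
) -> ComponentContributions:
    """Apply the filters to the raw (unsmoothed) spectra.

    ``contribution_x(f) = FF_x(f) * raw(f)`` per row; the contributions sum
    back to the raw spectrum bin by bin.
    """
    if raw.values.shape[0] != filters.FF.shape[0]:
        raise InvalidInputError("row count mismatch between raw spectra and filters")
    if len(raw.frequencies) != len(filters.frequencies) or not np.allclose(
        raw.frequencies, filters.frequencies
    ):
        raise InvalidInputError("raw spectra and filters are on different frequency grids")
    values = filters.FF * raw.values[:, None, :]
    return ComponentContributions(
        values, raw.frequencies, list(filters.labels), list(raw.row_index)
    )


def normalize_pair(H: np.ndarray) -> np.ndarray:
    """Normalize a two-row component matrix by the single maximum of the pair."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != 2:
        raise InvalidInputError(f"expected a 2-row component matrix, got shape {H.shape}")
    peak = H.max()
    if peak <= 0:
        raise InvalidInputError("cannot normalize an all-zero component pair")
    return H / peak
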