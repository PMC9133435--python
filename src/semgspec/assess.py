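"""Component separability and statistical comparisons.

Separability between the recovered low- and high-frequency component groups
is quantified by the Gaussian Bhattacharyya distance

    D = 1/8 (mu1 - mu2)' S^-1 (mu1 - mu2) + 1/2 ln( det S / sqrt(det S1 det S2) ),
    S = (S1 + S2) / 2,

computed in a compact three-feature space per extracted component: median
frequency, spectral centroid, and log total energy of its pair-normalized
spectrum. ``D > 3.5`` (strict) flags the groups as highly separable (Bayes
error below ~2% under the calibration this threshold comes from). Group
differences in median frequency are tested with Wilcoxon rank-sum tests
(exact permutation distribution for small untied samples, normal
approximation with tie and continuity corrections otherwise), with
step-down Holm correction for the pairwise by-subject and by-trial
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .decompose import ComponentSet, normalize_pair
from .exceptions import InsufficientDataError, InvalidInputError
from .spectral import energy, median_frequency, spectral_centroid
from .containers import Spectrum

__all__ = [
    "FEATURE_COLUMNS",
    "BDIST_THRESHOLD",
    "SeparabilityReport",
    "bhattacharyya_gaussian",
    "bhattacharyya_distance",
    "component_features",
    "separability",
    "wilcoxon_ranksum",
    "holm_bonferroni",
]

FEATURE_COLUMNS = ["median_freq_hz", "centroid_hz", "log_energy"]
#: Bhattacharyya distance above which two classes are called highly separable.
BDIST_THRESHOLD = 3.5
_RIDGE = 1e-8


def bhattacharyya_gaussian(
    mu1: np.ndarray, cov1: np.ndarray, mu2: np.ndarray, cov2: np.ndarray
) -> float:
    """Closed-form Bhattacharyya distance between two Gaussians."""
    mu1, mu2 = np.atleast_1d(np.asarray(mu1, float)), np.atleast_1d(np.asarray(mu2, float))
    cov1 = np.atleast_2d(np.asarray(cov1, float))
    cov2 = np.atleast_2d(np.asarray(cov2, float))
    pooled = 0.5 * (cov1 + cov2)
    d = len(mu1)
    eye = np.eye(d)
    for ridge in (0.0, _RIDGE):
        s1, s2, sp = cov1 + ridge * eye, cov2 + ridge * eye, pooled + ridge * eye
        sign_p, logdet_p = np.linalg.slogdet(sp)
        sign_1, logdet_1 = np.linalg.slogdet(s1)
        sign_2, logdet_2 = np.linalg.slogdet(s2)
        if min(sign_p, sign_1, sign_2) > 0:
            diff = mu1 - mu2
            maha = float(diff @ np.linalg.solve(sp, diff))
            return 0.125 * maha + 0.5 * (logdet_p - 0.5 * (logdet_1 + logdet_2))
    raise InvalidInputError("covariances singular even after ridge regularization")


def bhattacharyya_distance(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Gaussian Bhattacharyya distance between two samples of feature vectors.

    Each group must have at least 3 observations; means and (sample)
    covariances are fitted per group, with a small ridge added if the
    pooled covariance is singular.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise InvalidInputError("groups must be 2-D with equal feature dimension")
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise InsufficientDataError(
            f"each group needs >= 3 observations, got {a.shape[0]} and {b.shape[0]}"
        )
    cov_a = np.cov(a, rowvar=False, ddof=1)
    cov_b = np.cov(b, rowvar=False, ddof=1)
    return bhattacharyya_gaussian(a.mean(axis=0), cov_a, b.mean(axis=0), cov_b)


def component_features(
    components: ComponentSet, subject: int | str = 0, trial: int | str = 0
) -> pd.DataFrame:
    """One feature row per extracted component of a fitted decomposition.

    Features are computed from the pair-normalized H rows (unit-max rows
    for ranks other than 2): median frequency, spectral centroid, and log
    total energy.
    """
    H = components.H
    if components.n == 2:
        H = normalize_pair(H)
    rows = []
    for x, label in enumerate(components.labels):
        spec = Spectrum(components.frequencies, H[x])
        rows.append(
            {
                "subject": subject,
                "trial": trial,
                "label": label,
                "median_freq_hz": median_frequency(spec),
                "centroid_hz": spectral_centroid(spec),
                "log_energy": float(np.log(energy(spec))),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SeparabilityReport:
    """Bhattacharyya separability of the low/high groups plus the
    median-frequency statistics tables."""

    bdist: float
    highly_separable: bool
    threshold: float
    group_summary: pd.DataFrame
    low_vs_high_p: float
    subject_tests: pd.DataFrame = field(default_factory=pd.DataFrame)
    trial_tests: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "bdist": self.bdist,
            "highly_separable": self.highly_separable,
            "threshold": self.threshold,
            "group_summary": self.group_summary.to_dict(orient="records"),
            "low_vs_high_p": self.low_vs_high_p,
            "subject_tests": self.subject_tests.to_dict(orient="records"),
            "trial_tests": self.trial_tests.to_dict(orient="records"),
        }


def _pairwise_tests(df: pd.DataFrame, group_col: str, alpha: float) -> pd.DataFrame:
    """Holm-corrected pairwise rank-sum tests of median frequency between
    levels of ``group_col``, run separately within each component label."""
    rows = []
    for label, sub in df.groupby("label", sort=True):
        levels = sorted(sub[group_col].unique())
        pairs = [
            (a, b)
            for a, b in combinations(levels, 2)
            if len(sub[sub[group_col] == a]) > 0 and len(sub[sub[group_col] == b]) > 0
        ]
        if not pairs:
            continue
        pvals = [
            wilcoxon_ranksum(
                sub.loc[sub[group_col] == a, "median_freq_hz"].to_numpy(),
                sub.loc[sub[group_col] == b, "median_freq_hz"].to_numpy(),
            )
            for a, b in pairs
        ]
        reject, adjusted = holm_bonferroni(pvals, alpha=alpha)
        for (a, b), p, p_adj, rej in zip(pairs, pvals, adjusted, reject):
            rows.append(
                {
                    "label": label,
                    "group_a": a,
                    "group_b": b,
                    "p": p,
                    "p_holm": p_adj,
                    "reject": bool(rej),
                }
            )
    return pd.DataFrame(rows)


def separability(features: pd.DataFrame, alpha: float = 0.05,
                 threshold: float = BDIST_THRESHOLD) -> SeparabilityReport:
    """Separability of the low vs high component groups across trials.

    ``features`` is the concatenation of :func:`component_features` over
    all decomposed trials (>= 3 trials, i.e. >= 3 observations per label).
    """
    required = {"label", *FEATURE_COLUMNS}
    if not required.issubset(features.columns):
        raise InvalidInputError(f"features frame must contain columns {sorted(required)}")
    labels = sorted(features["label"].unique())
    if len(labels) != 2:
        raise InvalidInputError(f"exactly two component labels expected, got {labels}")
    lo = features[features["label"] == "low"] if "low" in labels else features[features["label"] == labels[0]]
    hi = features[features["label"] == "high"] if "high" in labels else features[features["label"] == labels[1]]
    bdist = bhattacharyya_distance(lo[FEATURE_COLUMNS].to_numpy(), hi[FEATURE_COLUMNS].to_numpy())
    summary = (
        features.groupby("label")["median_freq_hz"]
        .agg(center="mean", spread="std", count="count")
        .reset_index()
    )
    p = wilcoxon_ranksum(lo["median_freq_hz"].to_numpy(), hi["median_freq_hz"].to_numpy())
    subject_tests = (
        _pairwise_tests(features, "subject", alpha)
        if "subject" in features.columns and features["subject"].nunique() > 1
        else pd.DataFrame()
    )
    trial_tests = (
        _pairwise_tests(features, "trial", alpha)
        if "trial" in features.columns and features["trial"].nunique() > 1
        else pd.DataFrame()
    )
    return SeparabilityReport(
        bdist=float(bdist),
        highly_separable=bool(bdist > threshold),
        threshold=threshold,
        group_summary=summary,
        low_vs_high_p=float(p),
        subject_tests=subject_tests,
        trial_tests=trial_tests,
    )


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float], two_sided: bool = True) -> float:
    """Wilcoxon rank-sum p-value.

    Uses the exact permutation distribution when ``len(x) + len(y) <= 20``
    and there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InvalidInputError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    alternative = "two-sided" if two_sided else "greater"
    res = sstats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.pvalue)


def holm_bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm correction: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, adjusted
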