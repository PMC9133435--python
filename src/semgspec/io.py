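"""On-disk formats: trial CSVs with JSON sidecars, ground truth, bundles.

A trial is a comma-separated file with a header row, the time column
(seconds) first and one column per channel; the sampling rate and trial
metadata live in a JSON sidecar next to it (``<name>.meta.json``). Writing
then reading a trial reproduces the samples to full precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SignalTrial, SpectraMatrix
from .exceptions import FormatError
from .synthetic import ComponentTemplate, MixingEnvelope, SyntheticGroundTruth

__all__ = [
    "sidecar_path",
    "write_signals",
    "read_signals",
    "write_spectra",
    "read_spectra",
    "write_ground_truth",
    "read_ground_truth",
    "file_checksum",
]


def sidecar_path(path: Path | str) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta.json")


def write_signals(trial: SignalTrial, path: Path | str) -> Path:
    """Write a trial as CSV (time first, one column per channel) plus a
    JSON sidecar holding the sampling rate, channel ids and metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(trial.n_samples) / trial.fs
    frame = pd.DataFrame({"time_s": t})
    for i, ch in enumerate(trial.channel_ids):
        frame[ch] = trial.samples[:, i]
    # %.17g + round_trip parsing on the read side preserves float64 exactly
    frame.to_csv(path, index=False, float_format="%.17g")
    meta = {"fs": trial.fs, "channel_ids": list(trial.channel_ids), "meta": trial.meta}
    sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def _locate_bad_cell(path: Path) -> tuple[int, str] | None:
    frame = pd.read_csv(path, dtype=str)
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            return int(bad.idxmax()) + 2, col  # +2: header line and 1-based rows
    return None


def read_signals(path: Path | str) -> SignalTrial:
    """Read a trial CSV written by :func:`write_signals`.

    Fails fast: a missing or malformed sidecar (no sampling rate) raises
    :class:`FormatError`, as does any non-numeric cell (reported with its
    row and column).
    """
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing sidecar header {side} (no sampling rate)")
    try:
        meta = json.loads(side.read_text())
        fs = float(meta["fs"])
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as err:
        raise FormatError(f"malformed sidecar header {side}: {err}") from err
    try:
        frame = pd.read_csv(path, dtype=float, float_precision="round_trip")
    except (ValueError, TypeError) as err:
        location = _locate_bad_cell(path)
        if location is not None:
            row, col = location
            raise FormatError(
                f"non-numeric cell in {path} at row {row}, column '{col}'"
            ) from err
        raise FormatError(f"cannot parse {path}: {err}") from err
    if frame.shape[1] < 2:
        raise FormatError(f"{path} must hold a time column plus >= 1 channel column")
    channel_ids = list(frame.columns[1:])
    declared = meta.get("channel_ids")
    if declared and list(declared) != channel_ids:
        raise FormatError(
            f"channel ids in {path} ({channel_ids}) disagree with sidecar ({declared})"
        )
    return SignalTrial(
        frame.iloc[:, 1:].to_numpy(), fs, channel_ids, dict(meta.get("meta", {}))
    )


def write_spectra(matrix: SpectraMatrix, path: Path | str) -> Path:
    """Write a spectra matrix as CSV: epoch_idx, channel, then one column
    per frequency bin named f008...f200."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(matrix.row_index, columns=["epoch_idx", "channel"])
    for j, f in enumerate(matrix.frequencies):
        frame[f"f{int(round(f)):03d}"] = matrix.values[:, j]
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_spectra(path: Path | str) -> SpectraMatrix:
    """Read a spectra matrix written by :func:`write_spectra`."""
    frame = pd.read_csv(Path(path), float_precision="round_trip")
    freq_cols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
    if not freq_cols or "epoch_idx" not in frame or "channel" not in frame:
        raise FormatError(f"{path} is not a spectra-matrix CSV")
    freqs = np.array([float(c[1:]) for c in freq_cols])
    rows = list(zip(frame["epoch_idx"].astype(int), frame["channel"].astype(str)))
    return SpectraMatrix(frame[freq_cols].to_numpy(float), rows, freqs)


def write_ground_truth(truth: SyntheticGroundTruth, path: Path | str) -> Path:
    """Serialize generator ground truth (templates, envelopes, gains, seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "templates": [
            {
                "frequency_grid": t.frequency_grid.tolist(),
                "magnitude": t.magnitude.tolist(),
                "nominal_median_frequency": t.nominal_median_frequency,
            }
            for t in truth.templates
        ],
        "envelopes": {
            "time_grid": truth.envelopes.time_grid.tolist(),
            "weights": truth.envelopes.weights.tolist(),
        },
        "channel_gains": truth.channel_gains.tolist(),
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_ground_truth(path: Path | str) -> SyntheticGroundTruth:
    payload = json.loads(Path(path).read_text())
    templates = [
        ComponentTemplate(
            np.asarray(t["frequency_grid"]),
            np.asarray(t["magnitude"]),
            t["nominal_median_frequency"],
        )
        for t in payload["templates"]
    ]
    env = MixingEnvelope(
        np.asarray(payload["envelopes"]["time_grid"]),
        np.asarray(payload["envelopes"]["weights"]),
    )
    return SyntheticGroundTruth(
        templates, env, np.asarray(payload["channel_gains"]),
        payload["noise_sd"], payload["seed"],
    )


def file_checksum(path: Path | str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
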