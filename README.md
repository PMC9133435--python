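# semgspec

Decomposition of surface-EMG (sEMG) spectra into low- and high-frequency
components via non-negative matrix factorization, with quantification of the
energy exchange between them during sustained isometric contraction.

## The problem

During a fatiguing isometric contraction the sEMG spectrum shifts toward
lower frequencies. The classical fatigue index — the decline of the median
frequency — measures this shift only indirectly. An alternative view treats
the spectrum of every 1-s epoch as a nonnegative mixture of a small number
of fixed spectral components (families of motor-unit action-potential
shapes) whose mixing weights change over time. Decomposing the epoch
spectra then turns the vague "spectral shift" into a concrete, quantitative
energy exchange between a low-frequency and a high-frequency component.

This package implements that analysis end to end for multi-channel
recordings (nominally 12 channels at 2000 Hz, 30-s trials):

1. **preprocess** — zero-phase Butterworth conditioning (1-Hz DC high-pass,
   optional 50/60-Hz notch, 8–200 Hz band-pass) and epoching into 1-s
   windows stepped by 0.5 s (60 epochs per 30-s trial).
2. **spectral** — one-sided FFT magnitude spectra on the 1-Hz grid
   (8–200 Hz, 193 bins), envelope smoothing, per-frequency band statistics,
   median frequency, spectral energy.
3. **decompose** — the factorization `M = W·H` of the 720-row
   (epochs × channels) spectra matrix, with `W ∈ R^{m×n}`, `H ∈ R^{n×f}`
   nonnegative; rank selected as the smallest `n` with VAF > 80 %, where
   `VAF = (1 − ‖M − WH‖²_F / ‖M‖²_F) × 100`. Per-row frequency-contribution
   filters `FF_x(f) = FC_x(f) / Σ_x FC_x(f)` with `FC_x = W[row,x]·H[x,·]`
   split each raw spectrum into component contributions that sum back to it
   exactly.
4. **temporal** — per-component energy time-courses (area under the
   magnitude curve per epoch), channel/trial/session aggregation,
   second-order polynomial trends, energy-crossover detection, and
   median-frequency tracking.
5. **assess** — Gaussian Bhattacharyya distance between the low- and
   high-component feature clouds (highly separable above 3.5), Wilcoxon
   rank-sum tests and step-down Holm correction.
6. **synthetic** — a seeded generator of sEMG-like trials whose per-epoch
   spectra are ground-truth two-component mixtures, used for validation and
   as a stand-in for recordings that are not publicly deposited.

## Worked example

```bash
python examples/decompose_trial.py
```

prints (abridged):

```
spectra matrix: 720 rows (60 epochs x 12 channels) x 193 frequency bins
VAF by rank: {1: 74.95, 2: 90.33}
selected n = 2 (smallest rank with VAF > 80%)
  low-frequency component: median frequency 46 Hz (generator template: 48 Hz)
  high-frequency component: median frequency 87 Hz (generator template: 86 Hz)
reconstruction VAF: 90.33%
```

A rank-1 fit cannot reach the 80 % VAF threshold while rank 2 passes it
comfortably, and the two recovered components land on the generator's
template medians — two spectrally distinct processes are both necessary
and sufficient to describe these spectra. `examples/energy_timecourse.py`
shows the energy exchange (high component decaying, low component rising,
crossover near 22 s) and `examples/separability_report.py` the
Bhattacharyya separability of the recovered component groups.

There is also a thin CLI for shell use:

```bash
semgspec run --simulate --set synthesis.subjects=2 --out results/run1
```

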