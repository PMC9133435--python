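# Methods

## Model

Each 1-s epoch of conditioned sEMG yields a one-sided FFT magnitude
spectrum on the uniform 1-Hz grid covering 8–200 Hz (193 bins; 2/N
amplitude normalization, so a unit bin-centered sinusoid maps to magnitude
1). Stacking all epochs and channels of one trial gives the nonnegative
matrix `M ∈ R^{m×f}` (m = 60 epochs × 12 channels = 720). The analysis
model is bilinear:

    M ≈ W · H,   W ∈ R^{m×n}, H ∈ R^{n×f}, all entries ≥ 0,

with `H` rows the spectral components and `W` their per-(epoch, channel)
weights. Amplitude (not power) spectra feed the factorization; power enters
only in the median frequency, defined as the smallest grid frequency at
which cumulative squared magnitude reaches half the total (no inter-bin
interpolation; resolution 1 Hz).

`M` is smoothed row-wise with a 5-bin centered moving average (truncated
and renormalized at the edges) before fitting; the contribution filters are
applied to the *unsmoothed* spectra. The rank is the smallest `n` whose
reconstruction exceeds VAF 80 %, with VAF computed over the whole matrix on
the uncentered Frobenius norm. For two components, rows of `H` are ordered
by ascending median frequency, labelled low/high, scale-normalized to unit
maximum (inverse scale absorbed into `W`), and pair-normalized (division by
the single maximum over both rows) for reporting.

Per row, the envelope contributions `FC_x = W[row,x]·H[x,·]` define the
frequency-contribution filters `FF_x = FC_x / Σ_x FC_x` (even split `1/n`
where the denominator vanishes). Applied bin-wise to the raw spectrum they
give component contributions that conserve it exactly; integrating each
contribution (trapezoid over frequency) gives the per-epoch component
energies.

## Numerical choices

* **Filters.** Butterworth order 4, applied forward–backward
  (zero-phase) so epoch alignment is not distorted; notch is an IIR notch
  at 60 Hz, Q = 30, on by default and switchable to 50 Hz or off.
* **Epoching.** Window starts at k·step for k = 0 … floor(duration/step)−1
  with the trailing partial window zero-padded, so a 30-s trial yields
  exactly 60 epochs. A strictly-inside rule would yield 59; the padding
  convention is configurable in spirit by trimming the input.
* **NMF.** Multiplicative updates on the squared Frobenius objective
  (scikit-learn's `mu` solver), best of 10 seeded random restarts by VAF.
  The winner is then refined in place to much tighter convergence
  (4000 further updates, tol 1e-10): multiplicative updates shrink entries
  toward zero only geometrically, and the residual tails left at the loose
  search tolerance otherwise leak energy between components in the
  contribution filters, biasing the energy crossover early by 1–2 s.
  Fixed seeds make every fit bit-reproducible.
* **Bhattacharyya feature space.** The distance is computed between the
  per-component feature clouds across trials, three features per extracted
  component: median frequency, spectral centroid, and log total energy of
  the pair-normalized `H` row. Full 193-bin spectra would give singular
  covariances at session sample sizes; a 1e-8 ridge is added if the pooled
  covariance is still singular. The >3.5 threshold is strict.
* **Rank-sum tests.** Exact permutation distribution when the pooled
  sample is ≤ 20 without ties, otherwise normal approximation with tie and
  continuity corrections. "95 % confidence" is read as α = 0.05 two-sided.
  Holm's step-down correction handles the pairwise by-subject and by-trial
  comparisons.
* **Crossover.** First time at which the low-component energy is ≥ the
  high-component energy and remains so until the end of the trial; the
  sustained rule ignores isolated noise flickers. Single-trial detections
  carry a 1–2 s spread; session-average curves (all channels and trials,
  as the analysis reports them) are the intended input.

## The synthetic generator

No recordings are publicly deposited, so a seeded generator emulates the
study conditions and carries its own ground truth. Defaults (one
`SessionConfig`): 9 subjects × 4 trials × 12 channels, 30 s at 2000 Hz,
self-reported fatigue 1.44 / 2.5 / 3.4 / 4.22 across trials.

* **Templates.** Unimodal log-normal-shaped bumps on the 1-Hz grid,
  peak-normalized, zero outside 8–200 Hz; width parameter 10 Hz (the
  log-domain SD mapped to Hz at the center). Centers are tuned by bisection
  so the discrete median frequencies land on the grid points nearest
  47.55 Hz (low) and 86.47 Hz (high), the group medians reported for the
  two components in this kind of recording.
* **Envelopes.** The low weight rises linearly from a small positive
  start (0.05 → 1.2 over the trial); the high weight rises over the first
  ~4–6 s (Gaussian onset) then decays exponentially, with decay rate
  0.04·(1 + 0.1·fatigue) s⁻¹ — higher initial fatigue raises the high
  component's starting weight and speeds its decay. The high curve is
  scaled so the curves cross exactly once at the requested crossover (22 s
  by default, inside the reported 20–25 s window). The composer then
  rescales the high envelope by the ratio of template areas so the *energy*
  curves (weight × template area, what the analysis measures) cross at the
  requested time.
* **Physiological variability.** Two seeded mean-1 log-normal sources:
  per-epoch, per-channel, per-component weight jitter (CV 0.9) — motor-unit
  pool activity fluctuates epoch to epoch — and a faster within-epoch
  amplitude modulation (SD 1.8 on a 0.125-s grid) that makes single-epoch
  spectra fluctuate around the template mixture the way real interference
  patterns do. The jitter keeps the spectra matrix exactly bilinear (it
  lives in `W`); the modulation creates the unstructured spectral residual
  that real epoch spectra show. Together they produce the reconstruction
  regime of interest: a rank-1 fit stays below the 80 % VAF threshold
  (~72 % on average, never above ~79 % in validation runs) while rank 2 passes it (~91 %), so rank selection
  lands on 2. Channel gains are log-uniform in [0.7, 1.3] (electrode-
  location amplitude variation without spectral distortion). White sensor
  noise has SD 0.02 in signal units.
* **Time-domain synthesis.** One white Gaussian stream per trial is
  shaped by one linear-phase FIR filter per template (firwin2, 501 taps).
  Because the filters share their group delay, the shaped sources add
  coherently and the expected epoch magnitude spectrum equals the
  weight-mixed template sum — the bilinear model exactly, with per-bin
  Rayleigh-type fluctuation as in any single-taper FFT of a stochastic
  signal. Envelopes, jitter and modulation are applied as slowly varying
  amplitude modulation (linear interpolation between grid points).
* **Spectral-domain synthesis.** For fast deterministic decomposition
  tests, `synthesize_spectra` builds `M = W_true·H_true` directly (jitter
  included in `W_true`, plus clipped additive Gaussian bin noise) and
  returns the generating factors.

## What the synthetic data do and do not show

The generator reproduces the *structure* the method targets — two
spectrally separated nonnegative components, fatigue-like energy exchange
with a late crossover, channel-gain diversity, realistic per-epoch spectral
noise. It does not simulate motor-unit action-potential trains, conduction
velocity, volume conduction, within-trial changes of component *shape*, or
force output. Passing tests therefore validate the pipeline's correctness
and its recovery behavior under the stated noise model, not the
physiological claims themselves; data-dependent figures from real
recordings (e.g. a particular VAF or Bhattacharyya value) are not
reproduction targets.

## Problem sizes used in validation

Tests and the acceptance script run at desk scale: single trials for
reconstruction checks; 8–12 trials (2–3 subjects × 4 trials) for
separability; 20 seeded trials for median-frequency recovery; 20 sessions
of 12 spectral-domain trials for crossover recovery. These sizes keep the
variance of each measured quantity well inside its stated tolerance.

## Known limitations

* The uncentered VAF makes rank-1 reconstructions of nonnegative data look
  strong (the mean spectrum dominates); the two-component regime is only
  visible because realistic epoch spectra carry substantial unstructured
  residual. With noise and variability switched off entirely, a rank-1 fit
  of an exactly rank-2 mixture can still exceed 80 % VAF, so rank
  selection on *noise-free* matrices is not a meaningful test of the
  criterion (the noise-free invariants tested instead are exactness of the
  ground-truth factorization and matrix rank 2).
* Energy-crossover estimates from single noisy trials scatter by 1–2 s;
  session-average curves are the reliable input.
* The Bhattacharyya distance depends on the feature space; values are
  comparable only within one feature-space convention.
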