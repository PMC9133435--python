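"""Decompose one synthetic trial's spectra into two components.

Runs the conditioning chain (DC high-pass, 60-Hz notch, 8-200 Hz
band-pass), cuts 1-s epochs stepped by 0.5 s, computes the 720-row
magnitude-spectra matrix, selects the component count by the VAF > 80%
rule and reports the recovered component shapes.
"""

from semgspec import decompose, preprocess, spectral, synthetic

truth = synthetic.make_ground_truth(seed=7)
trial = synthetic.synthesize_trial(truth)

x = preprocess.remove_dc(trial)
x = preprocess.notch(x)
x = preprocess.bandpass(x)
epochs = preprocess.epoch(x)
raw = spectral.spectra_matrix(epochs)
smoothed = spectral.smooth_matrix(raw, window_bins=5)

print(f"spectra matrix: {raw.values.shape[0]} rows "
      f"({epochs.n_epochs} epochs x {epochs.n_channels} channels) "
      f"x {raw.values.shape[1]} frequency bins")

selection = decompose.select_n_components(smoothed, vaf_threshold=80.0, seed=7)
print("VAF by rank:", {n: round(v, 2) for n, v in selection.vaf_curve.items()})
print(f"selected n = {selection.n} (smallest rank with VAF > 80%)")

components = decompose.nmf(smoothed, selection.n, seed=7)
for i, label in enumerate(components.labels):
    mf = spectral.median_frequency(components.component_spectrum(i))
    print(f"  {label}-frequency component: median frequency {mf:.0f} Hz "
          f"(generator template: "
          f"{truth.templates[i].nominal_median_frequency:.0f} Hz)")
print(f"reconstruction VAF: {components.vaf_percent:.2f}%")
print("A rank-1 fit stays below the threshold, so two spectrally distinct "
      "processes are genuinely needed to explain these spectra.")
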