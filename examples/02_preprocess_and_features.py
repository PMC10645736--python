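"""Preprocess the spectra and build the 55-wavenumber feature matrix.

The chain is min-max normalization, Savitzky-Golay smoothing (window 11,
order 3) and iterative order-2 polynomial baseline correction; features are
the intensities at 5 characteristic-peak windows (centre +/- 5 grid
points).  Training and test sets come from Kennard-Stone maximin selection.
"""

import numpy as np

import sersmix as sm

dataset = sm.generate_dataset()
processed = sm.preprocess_set(dataset)

raw = dataset[0].intensities
clean = processed[0].intensities
print(f"first spectrum: raw range [{raw.min():.2f}, {raw.max():.2f}] a.u. -> "
      f"preprocessed range [{clean.min():.3f}, {clean.max():.3f}]")
print("  (normalized to [0,1], then the fluorescence baseline removed)")

features = sm.select_peak_windows(processed)
print(f"feature matrix: {features.n_samples} samples x "
      f"{features.n_features} wavenumbers")
print("  first columns:", ", ".join(features.column_names()[:3]), "...")

split = sm.kennard_stone_split(features, 50)
print(f"Kennard-Stone split: {split.train.size} train / {split.test.size} test")
counts = np.bincount(features.labels[split.train], minlength=4)[1:]
print(f"  training-set class counts (mix/pyr/chl): {counts}")
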