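"""Generate the default 78-spectrum synthetic SERS dataset and summarize it.

The dataset mimics SERS measurements of chlorpyrifos (class 3),
pyrimethanil (class 2) and their volume-ratio mixtures (class 1) on a
200-1700 cm^-1 grid, with a fluorescence baseline, solvent bands and noise.
"""

import numpy as np

import sersmix as sm

dataset = sm.generate_dataset()
labels = dataset.labels

print(f"spectra: {len(dataset)}, grid points: {dataset.wavenumbers.size} "
      f"({dataset.wavenumbers[0]:.0f}-{dataset.wavenumbers[-1]:.0f} cm^-1)")
for code, name in [(1, "mixture"), (2, "pyrimethanil"), (3, "chlorpyrifos")]:
    print(f"  class {code} ({name}): {np.sum(labels == code)} spectra")

# peak intensity (mean +/- sd) at the two analyte-diagnostic bands
for center, analyte in [(558.0, "pyrimethanil"), (675.0, "chlorpyrifos")]:
    for code in (1, 2, 3):
        members = sm.LabeledSpectrumSet(
            [s for s in dataset if s.label == code])
        mean, sd = sm.peak_intensity(members, center, 10.0)
        print(f"I({center:.0f} cm^-1 | class {code}) = {mean:.2f} +/- {sd:.2f}")
    print(f"  -> the {analyte} band is strong only where that analyte is present")
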