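"""Calibrate and apply the lipid + Suess corrections on synthetic data.

The lipid model is an averaged bootstrapped OLS of the bulk-to-extracted
offset on the C:N mass ratio, applied only above C:N = 3.5; the Suess
correction then standardises every d13C to the 2021 oceanic baseline at
-0.022 permil per year.
"""

import numpy as np

from isoniche import (
    CalibrationPair,
    correct_samples,
    fit_lipid_correction,
    generate_species,
    nz_odontocetes_scenario,
)

config = next(c for c in nz_odontocetes_scenario() if c.species == "Common dolphin")
samples = generate_species(config, seed=4)

pairs = [
    CalibrationPair(s.d13C_bulk, s.d13C_lipid_extracted, s.cn_ratio)
    for s in samples
    if s.d13C_lipid_extracted is not None and s.cn_ratio > 3.5
]
model = fit_lipid_correction(pairs, n_bootstrap=10_000, seed=4)
print(f"calibration: {len(pairs)} paired samples")
print(f"fitted offset: delta-d13C = {model.beta0:.3f} + {model.beta1:.3f} x C:N  (permil)\n")

corrected = correct_samples(samples, model)
print(f"{'id':8s} {'year':>4} {'C:N':>5} {'bulk':>8} {'corrected':>9}")
for s in corrected[:8]:
    print(f"{s.sample_id:8s} {s.year:>4} {s.cn_ratio:>5.2f} {s.d13C_bulk:>8.2f} {s.d13C_corrected:>9.2f}")

bulk = np.mean([s.d13C_bulk for s in samples])
corr = np.mean([s.d13C_corrected for s in corrected])
print(
    f"\nspecies mean d13C: bulk {bulk:.2f} -> corrected {corr:.2f} "
    f"(configured truth {config.mean_d13C:.2f}); the correction removes the"
    "\nlipid depletion and year-to-year Suess drift from the bulk values."
)
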