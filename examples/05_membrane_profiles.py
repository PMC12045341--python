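"""Measure intermembrane distances from cryo-EM-style line profiles.

Simulates 1-D density profiles across a cell-cell contact (two
outer-membrane density peaks ~28.8 nm apart) and across a single envelope
(relaxed periplasm, ~37.5 nm), locates the density centers to subsample
precision, measures the separations, and compares the two groups by
one-way ANOVA.
"""

import numpy as np

from omequant import memprofile, synthetic

rng = np.random.default_rng(42)

contact, relaxed = [], []
for _ in range(30):
    sep = rng.normal(28.8, 3.4)
    prof, _ = synthetic.simulate_density_profile(
        [10.0, 10.0 + sep], peak_widths=3.0, amplitudes=1.0,
        noise_sd=0.05, rng=rng)
    centers = memprofile.locate_density_centers(prof, 2, polarity="peaks")
    contact.append(memprofile.measure_separation(centers, kind="OM-OM").separation)

    sep = rng.normal(37.5, 5.9)
    prof, _ = synthetic.simulate_density_profile(
        [10.0, 10.0 + sep], peak_widths=3.0, amplitudes=1.0,
        noise_sd=0.05, rng=rng)
    centers = memprofile.locate_density_centers(prof, 2, polarity="peaks")
    relaxed.append(memprofile.measure_separation(centers, kind="OM-IM").separation)

cmp = memprofile.anova_one_way([contact, relaxed])
print(f"OM-OM distance at contact sites: "
      f"{np.mean(contact):.1f} ± {np.std(contact, ddof=1):.1f} nm (n=30)")
print(f"relaxed periplasm thickness:     "
      f"{np.mean(relaxed):.1f} ± {np.std(relaxed, ddof=1):.1f} nm (n=30)")
print(f"one-way ANOVA: F = {cmp.F:.1f}, p = {cmp.p:.2e}")
print("Membranes at contact sites stay ~29 nm apart (electrostatic "
      "repulsion, no spontaneous fusion) while the periplasm is compressed "
      "relative to non-contact sides.")
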