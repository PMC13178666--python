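"""Basal-foot rotational polarity from a two-channel spot image.

Renders basal-body and basal-foot puncta for four cells — two tightly
polarized (von Mises kappa = 8) and two unpolarized (kappa = 0) — then
detects, pairs and summarizes them with circular statistics.
"""

import numpy as np

from ciliaquant import (
    SpotFieldSpec,
    cell_polarity,
    detect_spots,
    generate_spot_field,
    pair_spots,
)

spec = SpotFieldSpec(n_cells=4, spots_per_cell=40,
                     kappa=8.0, mu_per_cell=[0.5, 1.5, 0.0, -2.0], seed=2)
image, mask, truth = generate_spot_field(spec)
# overwrite cells 3 and 4 with uniform angles by regenerating at kappa=0
spec0 = SpotFieldSpec(n_cells=4, spots_per_cell=40, kappa=0.0, seed=3)
image0, _, _ = generate_spot_field(spec0)
image[:, mask > 2] = image0[:, mask > 2]

kw = dict(pixel_size_nm=spec.pixel_size, sigma_nm=spec.psf_sigma)
bodies = detect_spots(image[0], channel=0, **kw)
feet = detect_spots(image[1], channel=1, **kw)
pairs, unpaired_bb, unpaired_feet = pair_spots(bodies, feet, spec.pixel_size)
print(f"{len(bodies)} basal bodies, {len(feet)} feet, {len(pairs)} mutual-NN pairs")

for cell in cell_polarity(pairs, mask):
    print(f"cell {cell.label}: n={cell.n_pairs}  "
          f"mean={np.degrees(cell.circular_mean):7.1f} deg  "
          f"R={cell.resultant_length:.3f}  rayleigh_p={cell.rayleigh_p:.2e}")
# R near 1 with a tiny Rayleigh p marks a polarized cell (all basal feet
# point the same way); R well below 0.5 with large p marks disrupted
# rotational polarity.
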