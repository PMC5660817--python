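"""Reinitialization-free level-set refinement of a clustering ROI.

The binary-step initialization relaxes toward a signed distance function
while the zero contour locks onto the lesion edge.
"""

import numpy as np

from ugfc import (
    EvolutionParams,
    default_head_spec,
    edge_indicator,
    enhance_image,
    evolve,
    extract_roi,
    init_phi,
    internal_energy,
    make_phantom,
    ugfc_cluster,
)
from ugfc.metrics import evaluate_masks

img, truth, _ = make_phantom(default_head_spec(seed=0))
enhanced = enhance_image(img, float_output=True)
roi = extract_roi(ugfc_cluster(enhanced, c=4), enhanced.shape)

g = edge_indicator(enhanced, sigma=1.5)
print(f"edge indicator: min {g.min():.4f} (lesion boundary), "
      f"max {g.max():.4f} (flat tissue)")

phi0 = init_phi(roi.mask, c0=8.0)
phi, mask, iters = evolve(phi0, g, EvolutionParams())

gy, gx = np.gradient(phi)
band = np.abs(phi) < 6
reg = np.abs(np.hypot(gx, gy)[band] - 1.0).mean()
print(f"{iters} iterations; P(phi) {internal_energy(phi0):.0f} -> "
      f"{internal_energy(phi):.0f}")
print(f"mean ||grad phi| - 1| near the contour: {reg:.3f} "
      "(phi stays an approximate signed distance function)")
print(f"final Dice vs truth: "
      f"{evaluate_masks(truth.astype(int), mask.astype(int)).dice:.3f}")
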