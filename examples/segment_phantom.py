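"""Unified gravitational fuzzy clustering on an enhanced phantom.

Shows the KDE-seeded centroids, the hard/fuzzy pixel split and the
extracted lesion region of interest.
"""

import numpy as np

from ugfc import (
    default_head_spec,
    enhance_image,
    extract_roi,
    find_critical_bandwidth,
    make_phantom,
    ugfc_cluster,
)
from ugfc.clustering import FUZZY_LABEL
from ugfc.metrics import evaluate_masks

img, truth, _ = make_phantom(default_head_spec(seed=0))
enhanced = enhance_image(img, float_output=True)

h_crit, v0 = find_critical_bandwidth(enhanced, c=4)
print(f"critical bandwidth h = {h_crit}, initial centroids {v0}")

state = ugfc_cluster(enhanced, c=4, w=1.7)
n_fuzzy = int(np.sum(state.hard_labels == FUZZY_LABEL))
print(f"converged in {state.t} iterations; centroids "
      f"{np.round(state.centroids, 1)}")
print(f"hard-clustered pixels: {state.masses.sum()} "
      f"({n_fuzzy} remain fuzzy at tissue interfaces)")

roi = extract_roi(state, enhanced.shape, rule="brightest")
dice = evaluate_masks(truth.astype(int), roi.mask.astype(int)).dice
print(f"lesion ROI (brightest cluster): {roi.mask.sum()} px, "
      f"Dice vs truth = {dice:.3f}")
# Nearly every pixel is hard-assigned; the fuzzy remainder sits on tissue
# boundaries where the partial volume effect mixes intensities.
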