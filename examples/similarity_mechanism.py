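"""Why correlation-of-correlations separates background from cells.

Generates a 31x31 patch containing one disk cell whose signal variance
equals the pixel noise variance (pairwise correlation 0.5 inside the
cell, 0 elsewhere), computes (sim)^2 feature vectors, and compares
average Gaussian edge weights within the background against
background-to-cell weights.
"""

import numpy as np

from hnccorr import SynthConfig, compute_features, generate, sample_reference_set, weigh_edges
from hnccorr.movie_io import Patch

cfg = SynthConfig(
    frame_shape=(31, 31),
    T=1000,
    n_cells=1,
    radius_range=(5.0, 5.0),
    min_center_spacing=1.0,
    background=0.0,
    rng_seed=0,
)
movie, truth, _ = generate(cfg)
patch = Patch(data=movie.data, origin=(0, 0), m=31)
reference = sample_reference_set(patch, gamma=0.32, rng_seed=0)
features = compute_features(patch, reference)

cell = sorted({r * 31 + c for r, c in truth[0].pixels})
background = sorted(set(range(961)) - set(cell))
rng = np.random.default_rng(0)
bg_pairs = np.array(
    [(a, b) for a, b in zip(rng.choice(background, 500), rng.choice(background, 500)) if a != b]
)
mixed_pairs = np.column_stack([rng.choice(background, 500), rng.choice(cell, 500)])

w_bg = weigh_edges(features, bg_pairs, alpha=1.0).weights.mean()
w_mixed = weigh_edges(features, mixed_pairs, alpha=1.0).weights.mean()
print(f"mean background-background weight: {w_bg:.4f}")
print(f"mean background-cell weight:       {w_mixed:.4f}")
print(
    "\nBackground pixels are pairwise *uncorrelated*, yet their correlation\n"
    "images are nearly identical (all near zero), so (sim)^2 assigns them\n"
    "high mutual similarity; a background-cell pair differs at the cell's\n"
    "reference pixels and gets a lower weight.  This pushes the background\n"
    "into one cluster and lets the cut isolate the cell."
)
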