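"""Suppress sparse-view streaks with the PSD-informed BM3D filter.

Learns the artifact PSD from a small cohort, reconstructs an unseen
three-ellipse phantom from a 180-view scan, filters it, and reports the L2
error against the truth before and after filtering.
"""

import numpy as np

from sparsect import (
    BM3DConfig,
    GridImage,
    RayDrivenProjector,
    ScanGeometry,
    Sinogram,
    bm3d_filter,
    fov_mask,
    learn_artifact_psd,
    rasterize,
    reconstruct,
    sample_random_phantom,
)
from sparsect.evaluate import l2_error, substream

grid = 128
geometry = ScanGeometry("fan_equiangular", n_views=180, n_channels=224)

psd = learn_artifact_psd(25, 2, geometry, grid, substream(0, "learning"))
print(f"learned artifact PSD from {psd.n_averaged} two-ellipse phantoms")

phantom = sample_random_phantom(3, substream(0, "testing"), grid)
truth = rasterize(phantom)
projector = RayDrivenProjector(geometry, grid)
sino = Sinogram(projector.forward(truth.pixels), geometry, projector.betas)
raw = reconstruct(sino, grid_size=grid)

mask = fov_mask(grid)
filtered = bm3d_filter(raw, psd, BM3DConfig(lambda_scale=1.0))
filtered = GridImage(np.where(mask, filtered.pixels, 0.0))

e_raw = l2_error(truth, raw, mask)
e_flt = l2_error(truth, filtered, mask)
print(f"raw sparse-view FBP error (L2):  {e_raw:.3f}")
print(f"after BM3D with learned PSD:     {e_flt:.3f}")
print(f"error reduction: {100 * (1 - e_flt / e_raw):.1f}%")
# the filter removes energy at the frequencies the cohort identified as
# aliasing-dominated while leaving the ellipses' structure intact
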