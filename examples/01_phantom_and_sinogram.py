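"""Sample a random ellipse phantom and simulate its sparse-view sinogram.

Builds a two-ellipse phantom, rasterizes it to a 128x128 grid, and projects
it in the default fan-beam geometry with 180 views over 360 degrees — the
sparse-scan condition that produces angular aliasing streaks.
"""

import numpy as np

from sparsect import (
    ScanGeometry,
    forward_project_image,
    forward_project_phantom,
    rasterize,
    sample_random_phantom,
)

phantom = sample_random_phantom(2, np.random.default_rng(0), grid_size=128)
for i, e in enumerate(phantom.ellipses):
    print(f"ellipse {i}: center=({e.cx:+.3f},{e.cy:+.3f}) axes=({e.a:.3f},{e.b:.3f}) "
          f"theta={e.theta:.3f} rho={e.rho:.3f}")

image = rasterize(phantom)
print(f"rasterized: {image.n}x{image.n}, max intensity {image.pixels.max():.3f}, "
      f"covered fraction {np.mean(image.pixels > 0):.3f}")

geometry = ScanGeometry("fan_equiangular", n_views=180, n_channels=224)
sino_numeric = forward_project_image(image, geometry)
sino_exact = forward_project_phantom(phantom, geometry)
err = np.abs(sino_numeric.data - sino_exact.data).mean() / sino_exact.data.max()
print(f"sinogram: {sino_numeric.data.shape} (views x channels), "
      f"peak {sino_exact.data.max():.3f}")
print(f"ray-driven vs closed-form mean deviation: {100 * err:.3f}% of peak")
# the two projection paths agree to a fraction of a percent on average; the
# closed form is exact, the ray-driven path integrates the pixel grid
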