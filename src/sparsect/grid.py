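"""Square grid images and the normalized field-of-view convention.

All images in this package live on an N x N grid of pixel centers covering
the square [-1, 1] x [-1, 1]; the scanner field of view (FOV) is the
inscribed unit disk.  Row index increases downward while the physical y
axis points up, so pixel (row, col) sits at

    x = (col - (N - 1) / 2) * (2 / N)
    y = ((N - 1) / 2 - row) * (2 / N)

Physical scaling (mm) only enters through :class:`~sparsect.projector.ScanGeometry`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridImage", "pixel_coords", "fov_mask"]


@dataclass
class GridImage:
    """A 2-D real-valued square image on the normalized FOV grid.

    Parameters
    ----------
    pixels
        ``(N, N)`` array of finite real values.
    pixel_size
        Physical width of one pixel (mm); ``1.0`` when working purely in
        normalized units.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"GridImage must be square 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("GridImage pixels must be finite")

    @property
    def n(self) -> int:
        return self.pixels.shape[0]

    def copy(self) -> "GridImage":
        return GridImage(self.pixels.copy(), self.pixel_size)

    def __add__(self, other: "GridImage") -> "GridImage":
        return GridImage(self.pixels + other.pixels, self.pixel_size)

    def __sub__(self, other: "GridImage") -> "GridImage":
        return GridImage(self.pixels - other.pixels, self.pixel_size)


def pixel_coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (x, y) coordinates of pixel centers of an ``n x n`` grid.

    Returns two ``(n, n)`` arrays indexed ``[row, col]``.
    """
    half = (n - 1) / 2.0
    step = 2.0 / n
    cols = np.arange(n)
    rows = np.arange(n)
    x = (cols[None, :] - half) * step * np.ones((n, 1))
    y = (half - rows[:, None]) * step * np.ones((1, n))
    return x, y


def fov_mask(n: int, radius: float = 1.0) -> np.ndarray:
    """Boolean mask of pixel centers inside the FOV disk of given radius."""
    x, y = pixel_coords(n)
    return x * x + y * y <= radius * radius
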