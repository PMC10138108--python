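"""Random ellipse phantoms: sampling, rasterization, and analytic projections.

A phantom is a list of additive ellipses in normalized FOV coordinates
(the unit disk).  Each ellipse has a closed-form line integral, so a
multi-ellipse phantom can be projected exactly; the rasterized image is
the point-sampled indicator sum on the pixel grid.  The analytic
projection doubles as an oracle for the numeric ray-driven projector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import GridImage, pixel_coords

__all__ = [
    "Ellipse",
    "Phantom",
    "sample_random_phantom",
    "rasterize",
    "analytic_projection",
    "save_phantom",
    "load_phantom",
]

# Sampling defaults: the ellipse parameter distributions used for random
# phantom cohorts.  Centers are drawn uniformly in a disk of radius 0.6,
# semi-axes uniformly in [0.08, 0.35], orientation uniformly in [0, pi),
# intensity uniformly in [0.2, 1.0]; candidates whose bounding circle
# leaves the unit disk are rejected and redrawn.  This keeps every
# phantom fully inside the scan FOV while producing varied streak
# patterns from sparse-view scans.
CENTER_RADIUS = 0.6
AXIS_RANGE = (0.08, 0.35)
RHO_RANGE = (0.2, 1.0)


@dataclass(frozen=True)
class Ellipse:
    """An additive ellipse in normalized FOV coordinates.

    Parameters
    ----------
    cx, cy
        Center, dimensionless, in ``[-1, 1]``.
    a, b
        Semi-axes as fractions of the FOV half-width.
    theta
        Rotation angle of the ``a`` axis from +x, radians, counterclockwise.
    rho
        Additive intensity (attenuation, dimensionless units).
    """

    cx: float
    cy: float
    a: float
    b: float
    theta: float
    rho: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("ellipse semi-axes must be positive")
        if np.hypot(self.cx, self.cy) + max(self.a, self.b) > 1.0 + 1e-12:
            raise ValueError("ellipse bounding circle must lie inside the unit disk")
        if not np.isfinite(self.rho):
            raise ValueError("ellipse intensity must be finite")


@dataclass(frozen=True)
class Phantom:
    """An ordered collection of additive ellipses plus a raster grid size."""

    ellipses: tuple[Ellipse, ...]
    grid_size: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "ellipses", tuple(self.ellipses))
        if len(self.ellipses) < 1:
            raise ValueError("phantom needs at least one ellipse")
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")


def sample_random_phantom(
    n_ellipses: int, rng: np.random.Generator, grid_size: int = 512
) -> Phantom:
    """Draw a random phantom of ``n_ellipses`` additive ellipses.

    Identical generator state yields an identical phantom.  Learning
    cohorts use two ellipses per phantom; test cohorts use three.
    """
    if n_ellipses < 1:
        raise ValueError("n_ellipses must be >= 1")
    ellipses = []
    for _ in range(n_ellipses):
        while True:
            # uniform in the disk of radius CENTER_RADIUS
            r = CENTER_RADIUS * np.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * np.pi)
            cx, cy = r * np.cos(phi), r * np.sin(phi)
            a = rng.uniform(*AXIS_RANGE)
            b = rng.uniform(*AXIS_RANGE)
            theta = rng.uniform(0.0, np.pi)
            rho = rng.uniform(*RHO_RANGE)
            if np.hypot(cx, cy) + max(a, b) <= 1.0:
                ellipses.append(Ellipse(cx, cy, a, b, theta, rho))
                break
    return Phantom(tuple(ellipses), grid_size)


def rasterize(phantom: Phantom) -> GridImage:
    """Point-sample the phantom on its grid (pixel-center inclusion test).

    Overlapping ellipses add their intensities; the background is zero.
    No anti-aliasing is applied.
    """
    n = phantom.grid_size
    x, y = pixel_coords(n)
    img = np.zeros((n, n))
    for e in phantom.ellipses:
        dx = x - e.cx
        dy = y - e.cy
        c, s = np.cos(e.theta), np.sin(e.theta)
        u = dx * c + dy * s
        v = -dx * s + dy * c
        inside = (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0
        img[inside] += e.rho
    return GridImage(img, pixel_size=2.0 / n)


def analytic_projection(
    ellipse: Ellipse, view_angle: np.ndarray | float, s: np.ndarray | float
) -> np.ndarray:
    """Closed-form line integral of an ellipse along the ray (view_angle, s).

    The ray is the line ``x cos(view_angle) + y sin(view_angle) = s``.  For a
    centered ellipse the chord length is ``2 rho a b sqrt(w^2 - s^2) / w^2``
    with ``w^2 = a^2 cos^2(view_angle - theta) + b^2 sin^2(view_angle - theta)``;
    an offset center shifts the effective detector coordinate.  Broadcasts
    over ``view_angle`` and ``s``.
    """
    view_angle = np.asarray(view_angle, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    ang = view_angle - ellipse.theta
    w2 = (ellipse.a * np.cos(ang)) ** 2 + (ellipse.b * np.sin(ang)) ** 2
    s_eff = s - (ellipse.cx * np.cos(view_angle) + ellipse.cy * np.sin(view_angle))
    under = w2 - s_eff**2
    out = np.where(
        under > 0.0,
        2.0 * ellipse.rho * ellipse.a * ellipse.b * np.sqrt(np.maximum(under, 0.0)) / w2,
        0.0,
    )
    return out


def save_phantom(phantom: Phantom, path: str | Path) -> None:
    """Write a phantom as a JSON record of (cx, cy, a, b, theta, rho) tuples."""
    rec = {
        "grid_size": phantom.grid_size,
        "ellipses": [
            [e.cx, e.cy, e.a, e.b, e.theta, e.rho] for e in phantom.ellipses
        ],
    }
    Path(path).write_text(json.dumps(rec, indent=2))


def load_phantom(path: str | Path) -> Phantom:
    rec = json.loads(Path(path).read_text())
    ells = tuple(Ellipse(*params) for params in rec["ellipses"])
    return Phantom(ells, int(rec["grid_size"]))
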