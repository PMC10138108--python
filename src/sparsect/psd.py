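"""Artifact images and the averaged artifact power spectral density (PSD).

The artifact image of a phantom is the difference between its true
(rasterized) image and its sparse-view FBP reconstruction: in noiseless
sparse-view CT this difference is dominated by deterministic angular
aliasing streaks, not random noise.  Its power spectrum — the squared
modulus of the unnormalized 2-D DFT — is averaged over a cohort of random
phantoms so that phantom-specific shape information cancels and only the
geometry-dependent artifact spectrum remains.  The averaged PSD is the
"noise" spectrum handed to the correlated-noise BM3D filter.

Aliasing artifacts are not stationary, so a true artifact PSD does not
exist; the averaged periodogram built here is an explicitly ad hoc
stationary surrogate for it.

PSDs are stored in DFT layout (zero frequency at index (0, 0)); the
visualization export shifts the origin to the image center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .fbp import reconstruct
from .grid import GridImage
from .phantoms import Phantom, rasterize, sample_random_phantom
from .projector import (
    RayDrivenProjector,
    ScanGeometry,
    Sinogram,
    forward_project_phantom,
)

__all__ = [
    "SpectrumImage",
    "PSDImage",
    "artifact_image",
    "power_spectrum",
    "average_psd",
    "learn_artifact_psd",
    "save_psd",
    "load_psd",
    "psd_to_png_array",
]


@dataclass
class SpectrumImage:
    """Unnormalized forward 2-D DFT of a grid image, origin at index (0, 0)."""

    coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.complex128)
        if self.coeffs.ndim != 2 or self.coeffs.shape[0] != self.coeffs.shape[1]:
            raise ValueError("spectrum must be square 2-D")


@dataclass
class PSDImage:
    """Real nonnegative power image in DFT layout, with averaging count."""

    power: np.ndarray
    n_averaged: int = 1

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.ndim != 2 or self.power.shape[0] != self.power.shape[1]:
            raise ValueError("PSD must be square 2-D")
        if not np.all(np.isfinite(self.power)) or np.any(self.power < 0):
            raise ValueError("PSD values must be finite and nonnegative")
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")

    @property
    def n(self) -> int:
        return self.power.shape[0]


def artifact_image(truth: GridImage, recon: GridImage) -> GridImage:
    """Elementwise difference truth - reconstruction (the artifact image)."""
    if truth.pixels.shape != recon.pixels.shape:
        raise ValueError(
            f"shape mismatch: truth {truth.pixels.shape} vs recon {recon.pixels.shape}"
        )
    return GridImage(truth.pixels - recon.pixels, truth.pixel_size)


def power_spectrum(a: GridImage) -> PSDImage:
    """Squared modulus of the unnormalized forward DFT of an image."""
    coeffs = np.fft.fft2(a.pixels)
    return PSDImage(np.abs(coeffs) ** 2, n_averaged=1)


def average_psd(spectra: Sequence[PSDImage] | Iterable[PSDImage]) -> PSDImage:
    """Count-weighted elementwise mean of power spectra."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("average_psd needs at least one PSD")
    n = spectra[0].n
    total = np.zeros((n, n))
    count = 0
    for p in spectra:
        if p.n != n:
            raise ValueError("PSDs must share dimensions")
        total += p.power * p.n_averaged
        count += p.n_averaged
    return PSDImage(total / count, n_averaged=count)


def simulate_artifact_pair(
    phantom: Phantom,
    geometry: ScanGeometry,
    projector: str = "raster",
    _ray_proj: RayDrivenProjector | None = None,
) -> tuple[GridImage, GridImage]:
    """True image and its sparse-view FBP reconstruction for one phantom.

    ``projector="raster"`` projects the rasterized image with the numeric
    ray-driven projector (data consistent with the pixel grid);
    ``"analytic"`` uses the exact ellipse line integrals.
    """
    truth = rasterize(phantom)
    if projector == "analytic":
        sino = forward_project_phantom(phantom, geometry)
    elif projector == "raster":
        proj = _ray_proj if _ray_proj is not None else RayDrivenProjector(geometry, phantom.grid_size)
        sino = Sinogram(proj.forward(truth.pixels), geometry, proj.betas)
    else:
        raise ValueError(f"unknown projector {projector!r}")
    recon = reconstruct(sino, grid_size=phantom.grid_size)
    return truth, recon


def learn_artifact_psd(
    n_phantoms: int,
    n_ellipses: int,
    geometry: ScanGeometry,
    grid_size: int,
    seed: int | np.random.Generator,
    projector: str = "raster",
) -> PSDImage:
    """Average artifact PSD over a cohort of random phantoms.

    For each phantom: sample, rasterize, project (noiseless), reconstruct
    with FBP, form the artifact image, and take its power spectrum; the
    cohort mean is returned.  Deterministic for a fixed seed.
    """
    if n_phantoms < 1:
        raise ValueError("n_phantoms must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ray_proj = RayDrivenProjector(geometry, grid_size) if projector == "raster" else None
    total = np.zeros((grid_size, grid_size))
    for _ in range(n_phantoms):
        ph = sample_random_phantom(n_ellipses, rng, grid_size)
        truth, recon = simulate_artifact_pair(ph, geometry, projector, _ray_proj=ray_proj)
        a = artifact_image(truth, recon)
        total += np.abs(np.fft.fft2(a.pixels)) ** 2
    return PSDImage(total / n_phantoms, n_averaged=n_phantoms)


def save_psd(psd: PSDImage, path: str | Path, meta: dict | None = None) -> None:
    """NPY power image plus a JSON sidecar with provenance metadata."""
    path = Path(path)
    np.save(path, psd.power)
    record = {"n_averaged": psd.n_averaged, "grid_size": psd.n}
    if meta:
        record.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(record, indent=2))


def load_psd(path: str | Path) -> PSDImage:
    path = Path(path)
    power = np.load(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return PSDImage(power, n_averaged=int(meta.get("n_averaged", 1)))


def psd_to_png_array(psd: PSDImage) -> np.ndarray:
    """Log-scaled, center-shifted uint8 rendering of a PSD for export."""
    shifted = np.fft.fftshift(psd.power)
    img = np.log1p(shifted)
    hi = img.max()
    if hi > 0:
        img = img / hi
    return (img * 255.0 + 0.5).astype(np.uint8)
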