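"""Image file I/O shared by the library and the CLI.

NPY round-trips float64 pixel data bit-exactly and is the interchange
format; TIFF stores float32; PNG is a visualization format — 8-bit files
load as ``value / 255`` and 16-bit as ``value / 65535``, and saving a PNG
linearly rescales the image's [min, max] to [0, 255].
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grid import GridImage

__all__ = ["load_image", "save_image"]

_FORMATS = {".npy": "NPY", ".tif": "TIFF", ".tiff": "TIFF", ".png": "PNG"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.upper()
    try:
        return _FORMATS[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer image format from suffix {path.suffix!r}") from None


def load_image(path: str | Path, fmt: str | None = None) -> GridImage:
    """Read a square grayscale image from NPY, TIFF, or PNG."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    fmt = _infer_format(path, fmt)
    if fmt not in ("NPY", "TIFF", "PNG"):
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        if fmt == "NPY":
            pixels = np.load(path)
        elif fmt == "TIFF":
            import tifffile

            pixels = np.asarray(tifffile.imread(path), dtype=np.float64)
        else:
            import imageio.v3 as iio

            raw = iio.imread(path)
            if raw.ndim == 3:  # collapse RGB(A) to luminance
                raw = raw[..., :3].mean(axis=-1)
            scale = 65535.0 if raw.dtype == np.uint16 else 255.0
            pixels = np.asarray(raw, dtype=np.float64) / scale
    except Exception as exc:  # corrupt/truncated file
        raise IOError(f"failed to read image {path}: {exc}") from exc
    if pixels.dtype.kind not in "fiu":
        raise ValueError(f"unsupported pixel dtype {pixels.dtype} in {path}")
    return GridImage(np.asarray(pixels, dtype=np.float64))


def save_image(image: GridImage, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "NPY":
        np.save(path, image.pixels)
    elif fmt == "TIFF":
        import tifffile

        tifffile.imwrite(path, image.pixels.astype(np.float32))
    elif fmt == "PNG":
        import imageio.v3 as iio

        lo, hi = image.pixels.min(), image.pixels.max()
        span = hi - lo if hi > lo else 1.0
        iio.imwrite(path, ((image.pixels - lo) / span * 255.0 + 0.5).astype(np.uint8))
    else:
        raise ValueError(f"unsupported format {fmt!r}")
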