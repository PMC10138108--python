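"""BM3D collaborative filtering with a user-supplied correlated-noise PSD.

The filter treats sparse-view aliasing streaks as stationary correlated
"noise" whose power spectral density is supplied externally (learned from a
phantom cohort).  It follows the classic two-stage BM3D structure:

1. *Hard thresholding*: group similar blocks, apply a separable 3-D
   transform (2-D orthonormal DCT per block + 1-D orthonormal Haar across
   the group), zero coefficients below a threshold proportional to the
   per-coefficient noise standard deviation, and aggregate the inverse
   transforms with inverse-count weights.
2. *Empirical Wiener filtering*: re-group by matching on the stage-1
   estimate, shrink each 3-D coefficient by ``b^2 / (b^2 + sigma^2)`` where
   ``b`` is the corresponding coefficient of the stage-1 estimate, and
   aggregate.

The supplied PSD (scaled by ``lambda_scale``) is mapped to a per-coefficient
noise variance by pushing the implied stationary autocovariance through the
2-D block transform; the variance is assumed constant along the 1-D group
transform.  The 2-D DC coefficient of every block is never shrunk, which
preserves local means exactly and makes constant images fixed points.

Everything here is deterministic: identical inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dctn, idctn

from .grid import GridImage
from .psd import PSDImage

__all__ = [
    "BM3DConfig",
    "block_match",
    "stage1_hard_threshold",
    "stage2_wiener",
    "bm3d_filter",
    "psd_to_coefficient_variance",
]


@dataclass(frozen=True)
class BM3DConfig:
    """Tuning parameters of the collaborative filter.

    ``lambda_scale`` multiplies the supplied PSD before it is converted to
    coefficient noise variances; it is the single operating-point knob
    (larger values smooth more).
    """

    block_size: int = 8
    step: int = 4
    search_radius: int = 16
    max_group: int = 16
    match_threshold: float = np.inf
    hard_threshold_factor: float = 2.7
    lambda_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.block_size < 4:
            raise ValueError("block_size must be >= 4")
        if self.max_group < 1 or (self.max_group & (self.max_group - 1)) != 0:
            raise ValueError("max_group must be a power of two >= 1")
        if self.lambda_scale < 0:
            raise ValueError("lambda_scale must be nonnegative")
        if self.step < 1 or self.search_radius < 1:
            raise ValueError("step and search_radius must be >= 1")


# ---------------------------------------------------------------------------
# transforms


def _haar_forward(group: np.ndarray) -> np.ndarray:
    """Orthonormal Haar wavelet along axis 0 (length must be a power of two)."""
    out = group.copy()
    n = out.shape[0]
    while n > 1:
        a = out[0:n:2].copy()
        b = out[1:n:2].copy()
        out[: n // 2] = (a + b) / np.sqrt(2.0)
        out[n // 2 : n] = (a - b) / np.sqrt(2.0)
        n //= 2
    return out


def _haar_inverse(group: np.ndarray) -> np.ndarray:
    out = group.copy()
    n = 2
    while n <= out.shape[0]:
        s = out[: n // 2].copy()
        d = out[n // 2 : n].copy()
        out[0:n:2] = (s + d) / np.sqrt(2.0)
        out[1:n:2] = (s - d) / np.sqrt(2.0)
        n *= 2
    return out


def psd_to_coefficient_variance(psd: PSDImage, cfg: BM3DConfig) -> np.ndarray:
    """Noise variance of each 2-D DCT block coefficient under the PSD.

    A stationary field with power spectrum ``lambda_scale * psd``
    (unnormalized-DFT convention) has autocovariance ``r = ifft2(P) / N^2``;
    the covariance of a block is block-Toeplitz in ``r``, and the variance
    of DCT coefficient ``m`` is ``phi_m^T C phi_m``.
    """
    n = psd.n
    bs = cfg.block_size
    r = np.fft.ifft2(cfg.lambda_scale * psd.power).real / (n * n)
    # block covariance: C[(i,j),(k,l)] = r[(i-k) mod N, (j-l) mod N]
    ii, jj = np.meshgrid(np.arange(bs), np.arange(bs), indexing="ij")
    flat_i = ii.ravel()
    flat_j = jj.ravel()
    di = (flat_i[:, None] - flat_i[None, :]) % n
    dj = (flat_j[:, None] - flat_j[None, :]) % n
    C = r[di, dj]
    eye = np.eye(bs)
    d1 = dctn(eye, axes=(0,), norm="ortho")  # rows are 1-D DCT basis images
    # 2-D separable DCT basis as a (bs*bs, bs*bs) matrix
    phi = np.kron(d1.T, d1.T).T  # phi[m] is basis function m flattened
    var = np.einsum("mp,pq,mq->m", phi, C, phi)
    return np.clip(var, 0.0, None).reshape(bs, bs)


# ---------------------------------------------------------------------------
# block matching


class _BlockEngine:
    """Precomputed DCT coefficients of every block of an image."""

    def __init__(self, pixels: np.ndarray, cfg: BM3DConfig):
        self.cfg = cfg
        bs = cfg.block_size
        n = pixels.shape[0]
        if n < bs:
            raise ValueError("image smaller than block size")
        self.n_pos = n - bs + 1
        windows = sliding_window_view(pixels, (bs, bs))
        self.dct = dctn(windows, axes=(-2, -1), norm="ortho")

    def match(self, ref: tuple[int, int]) -> np.ndarray:
        """Matched top-left positions for a reference block, reference first.

        Candidates are every integer position within the search radius
        (Chebyshev) whose block lies inside the image; they are ranked by
        squared block distance with raster-scan tie-breaking, cut at the
        match threshold, and truncated to the largest power of two not
        exceeding ``max_group``.
        """
        cfg = self.cfg
        ri, ci = ref
        if not (0 <= ri < self.n_pos and 0 <= ci < self.n_pos):
            raise ValueError(f"reference block at {ref} is not fully inside the image")
        r0, r1 = max(0, ri - cfg.search_radius), min(self.n_pos, ri + cfg.search_radius + 1)
        c0, c1 = max(0, ci - cfg.search_radius), min(self.n_pos, ci + cfg.search_radius + 1)
        cand = self.dct[r0:r1, c0:c1]
        ref_coeffs = self.dct[ri, ci]
        dist = ((cand - ref_coeffs) ** 2).sum(axis=(-2, -1))
        dist[ri - r0, ci - c0] = -1.0  # force the reference to sort first
        flat = dist.ravel()
        order = np.argsort(flat, kind="stable")
        keep = order[flat[order] <= cfg.match_threshold]
        keep = keep[: cfg.max_group]
        k = 1 << (len(keep).bit_length() - 1)  # largest power of two <= matches
        keep = keep[:k]
        rows = keep // (c1 - c0) + r0
        cols = keep % (c1 - c0) + c0
        return np.stack([rows, cols], axis=1)


def block_match(
    image: GridImage, ref_position: tuple[int, int], cfg: BM3DConfig
) -> np.ndarray:
    """Positions of blocks grouped with the reference block (reference first)."""
    return _BlockEngine(image.pixels, cfg).match(ref_position)


def _reference_grid(n_pos: int, step: int) -> np.ndarray:
    """Reference positions at the given step, always including the last one."""
    refs = list(range(0, n_pos, step))
    if refs[-1] != n_pos - 1:
        refs.append(n_pos - 1)
    return np.asarray(refs)


# ---------------------------------------------------------------------------
# stages


def _aggregate(
    n: int, bs: int, blocks: list[np.ndarray], positions: list[np.ndarray], weights: list[float]
) -> np.ndarray:
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for blk, pos, w in zip(blocks, positions, weights):
        spatial = idctn(blk, axes=(-2, -1), norm="ortho")
        for (r, c), sb in zip(pos, spatial):
            num[r : r + bs, c : c + bs] += w * sb
            den[r : r + bs, c : c + bs] += w
    return num / den


def stage1_hard_threshold(image: GridImage, psd: PSDImage, cfg: BM3DConfig) -> GridImage:
    """Collaborative hard-thresholding stage (the basic estimate)."""
    if psd.n != image.n:
        raise ValueError(f"PSD grid {psd.n} does not match image grid {image.n}")
    bs = cfg.block_size
    sigma2d = np.sqrt(psd_to_coefficient_variance(psd, cfg))
    thr = cfg.hard_threshold_factor * sigma2d
    engine = _BlockEngine(image.pixels, cfg)
    refs = _reference_grid(engine.n_pos, cfg.step)

    blocks, positions, weights = [], [], []
    for ri in refs:
        for ci in refs:
            pos = engine.match((ri, ci))
            group = engine.dct[pos[:, 0], pos[:, 1]]
            tgroup = _haar_forward(group)
            mask = np.abs(tgroup) > thr[None, :, :]
            mask[:, 0, 0] = True  # the block DC is never thresholded
            n_ret = int(mask.sum())
            tgroup = np.where(mask, tgroup, 0.0)
            blocks.append(_haar_inverse(tgroup))
            positions.append(pos)
            weights.append(1.0 / (1.0 + n_ret))
    return GridImage(_aggregate(image.n, bs, blocks, positions, weights), image.pixel_size)


def stage2_wiener(
    image: GridImage, basic: GridImage, psd: PSDImage, cfg: BM3DConfig
) -> GridImage:
    """Empirical Wiener stage: grouping on the basic estimate, shrinking the input."""
    if not (image.n == basic.n == psd.n):
        raise ValueError("image, basic estimate, and PSD must share dimensions")
    bs = cfg.block_size
    var2d = psd_to_coefficient_variance(psd, cfg)
    engine_basic = _BlockEngine(basic.pixels, cfg)
    engine_noisy = _BlockEngine(image.pixels, cfg)
    refs = _reference_grid(engine_basic.n_pos, cfg.step)

    blocks, positions, weights = [], [], []
    for ri in refs:
        for ci in refs:
            pos = engine_basic.match((ri, ci))
            bgroup = _haar_forward(engine_basic.dct[pos[:, 0], pos[:, 1]])
            ngroup = _haar_forward(engine_noisy.dct[pos[:, 0], pos[:, 1]])
            b2 = bgroup**2
            denom = b2 + var2d[None, :, :]
            with np.errstate(invalid="ignore"):
                gains = np.where(denom > 0.0, b2 / denom, 1.0)
            gains[:, 0, 0] = 1.0  # block DC passes unshrunk
            blocks.append(_haar_inverse(gains * ngroup))
            positions.append(pos)
            weights.append(1.0 / (1.0 + float((gains**2).sum())))
    return GridImage(_aggregate(image.n, bs, blocks, positions, weights), image.pixel_size)


def bm3d_filter(g: GridImage, psd: PSDImage, cfg: BM3DConfig | None = None) -> GridImage:
    """Full two-stage BM3D filter of an image against an artifact PSD.

    With ``lambda_scale = 0`` the noise power vanishes, every hard threshold
    is zero and every Wiener gain is one, so the filter is the identity; it
    is short-circuited to return the input unchanged.
    """
    cfg = cfg if cfg is not None else BM3DConfig()
    if psd.n != g.n:
        raise ValueError(
            f"PSD grid size {psd.n} does not match image grid size {g.n}; "
            "re-learn the PSD at the image grid (or resample the image)"
        )
    if cfg.lambda_scale == 0.0:
        return g.copy()
    basic = stage1_hard_threshold(g, psd, cfg)
    return stage2_wiener(g, basic, psd, cfg)
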