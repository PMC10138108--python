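"""Collaborative filtering: matching, both shrinkage stages, and the full filter.

The deep check here is a naive reference implementation of both stages
(explicit loops, explicitly constructed DCT and Haar matrices) that must
agree exactly with the vectorized implementation on small images.
"""

import numpy as np
import pytest

from sparsect import (
    BM3DConfig,
    GridImage,
    PSDImage,
    block_match,
    bm3d_filter,
    stage1_hard_threshold,
    stage2_wiener,
)
from sparsect.bm3d import psd_to_coefficient_variance

# ---------------------------------------------------------------------------
# naive reference implementation


def _dct_matrix(n):
    k = np.arange(n)
    mat = np.cos(np.pi * (2 * k[None, :] + 1) * k[:, None] / (2 * n))
    mat *= np.sqrt(2.0 / n)
    mat[0] /= np.sqrt(2.0)
    return mat


def _haar_matrix(n):
    if n == 1:
        return np.eye(1)
    h = _haar_matrix(n // 2)
    top = np.kron(h, [1.0, 1.0]) / np.sqrt(2.0)
    bot = np.kron(np.eye(n // 2), [1.0, -1.0]) / np.sqrt(2.0)
    return np.vstack([top, bot])


def _naive_variance(psd_power, lam, bs):
    n = psd_power.shape[0]
    uu, vv = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")

    def autocov(d1, d2):
        ph = 2 * np.pi * (uu * d1 + vv * d2) / n
        return np.sum(lam * psd_power * np.cos(ph)) / n**4

    D = _dct_matrix(bs)
    var = np.zeros((bs, bs))
    pix = [(i, j) for i in range(bs) for j in range(bs)]
    C = np.array([[autocov(a[0] - b[0], a[1] - b[1]) for b in pix] for a in pix])
    for p in range(bs):
        for q in range(bs):
            phi = np.outer(D[p], D[q]).ravel()
            var[p, q] = phi @ C @ phi
    return np.clip(var, 0.0, None)


def _naive_match(pixels, ref, cfg):
    bs, n = cfg.block_size, pixels.shape[0]
    ri, ci = ref
    refblk = pixels[ri : ri + bs, ci : ci + bs]
    cands = []
    for r in range(max(0, ri - cfg.search_radius), min(n - bs, ri + cfg.search_radius) + 1):
        for c in range(max(0, ci - cfg.search_radius), min(n - bs, ci + cfg.search_radius) + 1):
            d = np.sum((pixels[r : r + bs, c : c + bs] - refblk) ** 2)
            cands.append((d if (r, c) != (ri, ci) else -1.0, r, c))
    cands.sort(key=lambda t: t[0])  # python sort is stable; raster order preserved
    kept = [(r, c) for d, r, c in cands if d <= cfg.match_threshold][: cfg.max_group]
    k = 1
    while 2 * k <= len(kept):
        k *= 2
    return kept[:k]


def _naive_stage1(pixels, psd_power, cfg):
    bs, n = cfg.block_size, pixels.shape[0]
    D = _dct_matrix(bs)
    thr = cfg.hard_threshold_factor * np.sqrt(_naive_variance(psd_power, cfg.lambda_scale, bs))
    refs = sorted(set(list(range(0, n - bs + 1, cfg.step)) + [n - bs]))
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for ri in refs:
        for ci in refs:
            pos = _naive_match(pixels, (ri, ci), cfg)
            group = np.array([D @ pixels[r : r + bs, c : c + bs] @ D.T for r, c in pos])
            H = _haar_matrix(len(pos))
            tg = np.einsum("km,mij->kij", H, group)
            mask = np.abs(tg) > thr[None]
            mask[:, 0, 0] = True
            kept = np.where(mask, tg, 0.0)
            w = 1.0 / (1.0 + mask.sum())
            back = np.einsum("km,mij->kij", H.T, kept)
            for (r, c), blk in zip(pos, back):
                num[r : r + bs, c : c + bs] += w * (D.T @ blk @ D)
                den[r : r + bs, c : c + bs] += w
    return num / den


def _naive_stage2(pixels, basic, psd_power, cfg):
    bs, n = cfg.block_size, pixels.shape[0]
    D = _dct_matrix(bs)
    var = _naive_variance(psd_power, cfg.lambda_scale, bs)
    refs = sorted(set(list(range(0, n - bs + 1, cfg.step)) + [n - bs]))
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for ri in refs:
        for ci in refs:
            pos = _naive_match(basic, (ri, ci), cfg)
            H = _haar_matrix(len(pos))
            bg = np.einsum(
                "km,mij->kij", H, np.array([D @ basic[r : r + bs, c : c + bs] @ D.T for r, c in pos])
            )
            ng = np.einsum(
                "km,mij->kij", H, np.array([D @ pixels[r : r + bs, c : c + bs] @ D.T for r, c in pos])
            )
            denom = bg**2 + var[None]
            gains = np.where(denom > 0, bg**2 / denom, 1.0)
            gains[:, 0, 0] = 1.0
            back = np.einsum("km,mij->kij", H.T, gains * ng)
            w = 1.0 / (1.0 + np.sum(gains**2))
            for (r, c), blk in zip(pos, back):
                num[r : r + bs, c : c + bs] += w * (D.T @ blk @ D)
                den[r : r + bs, c : c + bs] += w
    return num / den


# ---------------------------------------------------------------------------


TINY_CFG = BM3DConfig(block_size=4, step=2, search_radius=4, max_group=8, lambda_scale=1.0)


class TestVarianceMapping:
    def test_white_noise_gives_constant_coefficient_variance(self):
        n, sigma = 32, 0.3
        flat = PSDImage(np.full((n, n), sigma**2 * n * n))
        var = psd_to_coefficient_variance(flat, BM3DConfig(lambda_scale=1.0))
        assert np.allclose(var, sigma**2, rtol=1e-10)

    def test_matches_naive_construction(self, rng):
        power = np.abs(rng.normal(size=(16, 16))) ** 2
        power = power + power[(-np.arange(16)) % 16][:, (-np.arange(16)) % 16]  # symmetric
        psd = PSDImage(power)
        got = psd_to_coefficient_variance(psd, TINY_CFG)
        want = _naive_variance(power, 1.0, 4)
        assert np.allclose(got, want, atol=1e-12)


class TestBlockMatch:
    def test_constant_image_fills_group_in_raster_order(self):
        img = GridImage(np.ones((16, 16)))
        got = block_match(img, (6, 6), TINY_CFG)
        want = _naive_match(img.pixels, (6, 6), TINY_CFG)
        assert [tuple(p) for p in got] == want
        assert len(got) == TINY_CFG.max_group
        assert tuple(got[0]) == (6, 6)

    def test_unique_block_matches_only_itself(self):
        pixels = np.zeros((16, 16))
        pixels[6:10, 6:10] = 5.0
        cfg = BM3DConfig(block_size=4, step=2, search_radius=4, max_group=8,
                         match_threshold=1e-6)
        got = block_match(GridImage(pixels), (6, 6), cfg)
        assert len(got) == 1 and tuple(got[0]) == (6, 6)

    def test_periodic_stripes_match_at_period_multiples(self):
        n, p = 24, 4
        pixels = np.tile((np.arange(n) % p < p // 2).astype(float), (n, 1))
        cfg = BM3DConfig(block_size=4, step=2, search_radius=8, max_group=16,
                         match_threshold=1e-9)
        got = block_match(GridImage(pixels), (10, 10), cfg)
        assert all((c - 10) % p == 0 for _, c in got)
        assert [tuple(q) for q in got] == _naive_match(pixels, (10, 10), cfg)

    def test_out_of_bounds_reference_rejected(self):
        with pytest.raises(ValueError):
            block_match(GridImage(np.zeros((16, 16))), (14, 0), TINY_CFG)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matching_agrees_with_brute_force_on_random_images(self, seed):
        pixels = np.random.default_rng(seed).normal(size=(16, 16))
        cfg = BM3DConfig(block_size=4, step=2, search_radius=4, max_group=4)
        for ref in [(0, 0), (5, 7), (12, 12)]:
            got = [tuple(p) for p in block_match(GridImage(pixels), ref, cfg)]
            assert got == _naive_match(pixels, ref, cfg)


class TestStagesAgainstNaiveReference:
    @pytest.mark.parametrize("seed", [3, 4])
    def test_stage1_exactly_reproduces_naive_reference(self, seed):
        rng = np.random.default_rng(seed)
        pixels = rng.normal(size=(16, 16))
        power = np.full((16, 16), 0.05 * 16 * 16)
        got = stage1_hard_threshold(GridImage(pixels), PSDImage(power), TINY_CFG)
        want = _naive_stage1(pixels, power, TINY_CFG)
        assert np.allclose(got.pixels, want, atol=1e-11)

    def test_stage2_exactly_reproduces_naive_reference(self):
        rng = np.random.default_rng(6)
        pixels = rng.normal(size=(16, 16))
        basic = pixels + 0.1 * rng.normal(size=(16, 16))
        power = np.full((16, 16), 0.02 * 16 * 16)
        got = stage2_wiener(GridImage(pixels), GridImage(basic), PSDImage(power), TINY_CFG)
        want = _naive_stage2(pixels, basic, power, TINY_CFG)
        assert np.allclose(got.pixels, want, atol=1e-11)


class TestFilterContracts:
    def test_lambda_zero_is_bitwise_identity(self, rng):
        img = GridImage(rng.normal(size=(32, 32)))
        psd = PSDImage(np.abs(rng.normal(size=(32, 32))))
        out = bm3d_filter(img, psd, BM3DConfig(lambda_scale=0.0))
        assert np.array_equal(out.pixels, img.pixels)

    def test_constant_image_is_fixed_point(self, rng):
        img = GridImage(np.full((32, 32), 2.5))
        psd = PSDImage(np.abs(rng.normal(size=(32, 32))))
        for lam in (0.0002, 0.002, 1.0):
            out = bm3d_filter(img, psd, BM3DConfig(lambda_scale=lam))
            assert np.allclose(out.pixels, 2.5, atol=1e-10)

    def test_grid_mismatch_rejected_with_guidance(self, rng):
        img = GridImage(rng.normal(size=(32, 32)))
        psd = PSDImage(np.ones((64, 64)))
        with pytest.raises(ValueError, match="re-learn"):
            bm3d_filter(img, psd)

    def test_white_noise_denoising_reduces_mse(self):
        rng = np.random.default_rng(11)
        n, sigma = 64, 0.1
        clean = np.zeros((n, n))
        clean[16:48, 16:48] = 1.0
        clean[24:40, 8:20] += 0.5
        noisy = clean + sigma * rng.normal(size=(n, n))
        flat = PSDImage(np.full((n, n), sigma**2 * n * n))
        out = bm3d_filter(GridImage(noisy), flat, BM3DConfig(lambda_scale=1.0))
        assert np.mean((out.pixels - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_mean_preserved_and_deterministic(self):
        rng = np.random.default_rng(12)
        img = GridImage(1.0 + 0.2 * rng.normal(size=(48, 48)))
        psd = PSDImage(np.full((48, 48), 0.04 * 48 * 48))
        a = bm3d_filter(img, psd, BM3DConfig(lambda_scale=1.0))
        b = bm3d_filter(img, psd, BM3DConfig(lambda_scale=1.0))
        assert np.array_equal(a.pixels, b.pixels)
        assert abs(a.pixels.mean() - img.pixels.mean()) <= 0.005 * abs(img.pixels.mean())

    def test_wiener_with_zero_basic_collapses_to_block_means(self, rng):
        img = GridImage(rng.normal(size=(16, 16)))
        basic = GridImage(np.zeros((16, 16)))
        power = np.full((16, 16), 16.0 * 16.0)  # unit-variance noise
        out = stage2_wiener(img, basic, PSDImage(power), TINY_CFG)
        want = _naive_stage2(img.pixels, basic.pixels, power, TINY_CFG)
        assert np.allclose(out.pixels, want, atol=1e-11)
        # off-DC gains are zero, so high-frequency content collapses
        assert np.std(out.pixels) < np.std(img.pixels)

    def test_stripe_artifact_suppressed_where_psd_indicates(self):
        # artifact = single spatial frequency; PSD mass on that frequency
        n, k = 64, 12
        rng = np.random.default_rng(13)
        base = np.full((n, n), 0.5)
        base[20:44, 20:44] = 1.0
        stripe = 0.15 * np.cos(2 * np.pi * k * np.arange(n) / n)[None, :] * np.ones((n, 1))
        noisy = base + stripe
        power = np.zeros((n, n))
        power[0, k] = power[0, n - k] = (n * n / 2) ** 2 * 0.15**2
        out = bm3d_filter(GridImage(noisy), PSDImage(power), BM3DConfig(lambda_scale=1.0))
        amp = lambda im: 2 * np.abs(np.fft.fft2(im)[0, k]) / n**2  # noqa: E731
        assert amp(out.pixels) < amp(noisy)
        flat = noisy[:10]  # stripe-only region
        assert abs(out.pixels[:10].mean() - flat.mean()) <= 0.01 * abs(flat.mean()) + 1e-12
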