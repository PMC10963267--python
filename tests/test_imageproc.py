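"""Photometry chain vs brute-force oracles: opening, peak scan, registration."""

import numpy as np
import pandas as pd
import pytest

from deepscreen import imageproc, synthcell


def brute_opening(img: np.ndarray, radius: int) -> np.ndarray:
    """Sliding-window min-then-max morphological opening with a disk."""
    offs = [(dy, dx) for dy in range(-radius, radius + 1)
            for dx in range(-radius, radius + 1)
            if dx * dx + dy * dy <= radius * radius]
    big = np.iinfo(img.dtype).max if img.dtype.kind in "ui" else np.inf

    def shift(a, dy, dx, fill):
        out = np.full_like(a, fill)
        h, w = a.shape
        ys = slice(max(0, dy), min(h, h + dy))
        xs = slice(max(0, dx), min(w, w + dx))
        ys_src = slice(max(0, -dy), min(h, h - dy))
        xs_src = slice(max(0, -dx), min(w, w - dx))
        out[ys, xs] = a[ys_src, xs_src]
        return out

    eroded = np.min([shift(img, dy, dx, big) for dy, dx in offs], axis=0)
    # reflect-free dilation: pad erosion with the minimum so borders behave
    small = eroded.min()
    return np.max([shift(eroded, -dy, -dx, small) for dy, dx in offs], axis=0)


def brute_peaks(img: np.ndarray, threshold: float) -> np.ndarray:
    """Exhaustive per-pixel 3x3 neighbourhood-maximum scan."""
    h, w = img.shape
    out = []
    for y in range(h):
        for x in range(w):
            neigh = img[max(0, y - 1):y + 2, max(0, x - 1):x + 2]
            if img[y, x] == neigh.max() and img[y, x] > threshold:
                out.append((x, y))
    return np.array(out).reshape(-1, 2)


def brute_best_shift(det: np.ndarray, ref: np.ndarray, shape, span: int = 15):
    """Exhaustive cross-correlation over all integer shifts of binary rasters."""
    def raster(points):
        img = np.zeros(shape)
        for x, y in np.rint(points).astype(int):
            if 0 <= y < shape[0] and 0 <= x < shape[1]:
                img[y, x] = 1.0
        return img

    rd, rr = raster(det), raster(ref)
    best, best_v = (0, 0), -1.0
    for dy in range(-span, span + 1):
        for dx in range(-span, span + 1):
            shifted = np.roll(np.roll(rr, dy, axis=0), dx, axis=1)
            v = float((rd * shifted).sum())
            if v > best_v:
                best, best_v = (dx, dy), v
    return best


class TestCorrectIllumination:
    def test_constant_image_zeroed(self):
        img = np.full((64, 64), 500, dtype=np.uint16)
        assert (imageproc.correct_illumination(img) == 0).all()

    def test_isolated_bright_pixel_preserved(self):
        img = np.zeros((64, 64), dtype=np.uint16)
        img[30, 30] = 1000
        out = imageproc.correct_illumination(img)
        assert out[30, 30] == 1000

    def test_gradient_plus_spot_vs_brute_force(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = (200 + 3 * xx + 2 * yy).astype(np.uint16)
        img[32, 40] += 900
        radius = 5
        out = imageproc.correct_illumination(img, disk_radius=radius)
        oracle = img.astype(np.int64) - brute_opening(img, radius).astype(np.int64)
        assert np.array_equal(out.astype(np.int64), np.clip(oracle, 0, None))

    def test_random_instances_vs_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            img = rng.integers(0, 2000, size=(48, 48)).astype(np.uint16)
            out = imageproc.correct_illumination(img, disk_radius=4)
            oracle = img.astype(np.int64) - brute_opening(img, 4).astype(np.int64)
            assert np.array_equal(out.astype(np.int64), np.clip(oracle, 0, None))

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            imageproc.correct_illumination(np.zeros((4, 4, 4)))


class TestDetectPeaks:
    def test_flat_below_threshold_empty(self):
        img = np.full((32, 32), 500, dtype=np.uint16)
        assert len(imageproc.detect_peaks(img, 600)) == 0

    def test_single_pixel_above_threshold(self):
        img = np.zeros((32, 32), dtype=np.uint16)
        img[5, 20] = 700
        peaks = imageproc.detect_peaks(img, 600)
        assert peaks.tolist() == [[20, 5]]

    def test_random_instances_match_exhaustive_scan(self):
        # 100 seeded instances against the brute-force neighbourhood scan
        for seed in range(100):
            rng = np.random.default_rng(seed)
            img = rng.integers(0, 1500, size=(32, 32)).astype(np.uint16)
            got = imageproc.detect_peaks(img, 600)
            want = brute_peaks(img, 600)
            assert np.array_equal(got, want), f"seed {seed}"


class TestAlignment:
    @staticmethod
    def _grid_points(rng, n=120, lo=10, hi=110):
        return rng.uniform(lo, hi, size=(n, 2)).round()

    def test_identical_point_sets_zero_shift(self, rng):
        pts = self._grid_points(rng)
        assert imageproc.coarse_align(pts, pts, (128, 128)) == (0, 0)

    def test_constructed_shift_recovered(self, rng):
        ref = self._grid_points(rng)
        det = ref + np.array([5.0, 7.0])
        assert imageproc.coarse_align(det, ref, (128, 128)) == (5, 7)

    def test_shift_with_spurious_points(self, rng):
        ref = self._grid_points(rng, n=100, lo=15, hi=100)
        det = ref + np.array([-3.0, 11.0])
        spurious = self._grid_points(rng, n=10, lo=15, hi=100)
        det = np.vstack([det, spurious])
        got = imageproc.coarse_align(det, ref, (128, 128))
        assert got == (-3, 11)
        assert got == brute_best_shift(det, ref, (128, 128))

    def test_shift_recovery_with_half_shared_points(self):
        # any constructed shift is recovered when >= 50% of points are shared
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ref = self._grid_points(rng, n=80, lo=15, hi=100)
            shift = rng.integers(-8, 9, size=2)
            det = np.vstack([ref[:40] + shift,
                             self._grid_points(rng, n=40, lo=15, hi=100)])
            got = imageproc.coarse_align(det, ref, (128, 128))
            assert got == tuple(shift), f"seed {seed}"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            imageproc.coarse_align(np.empty((0, 2)), np.ones((3, 2)), (64, 64))


class TestRefineOffsets:
    def test_global_shift_propagates_to_all_subtiles(self, rng):
        ref = rng.uniform(10, 240, size=(400, 2)).round()
        det = ref + np.array([4.0, 2.0])
        om = imageproc.refine_offsets(det, ref, (256, 256), subtile=128)
        assert (om.dx == 4).all() and (om.dy == 2).all()

    def test_piecewise_shift_detected_per_subtile(self, rng):
        # left half shifted (1,0); right half (0,1)
        ref = np.column_stack([rng.uniform(10, 246, 800), rng.uniform(10, 246, 800)]).round()
        left = ref[:, 0] < 120
        right = ref[:, 0] >= 136
        det = np.vstack([ref[left] + [1, 0], ref[right] + [0, 1]])
        ref_used = np.vstack([ref[left], ref[right]])
        om = imageproc.refine_offsets(det, ref_used, (256, 256), subtile=128)
        assert (om.dx[:, 0] == 1).all() and (om.dy[:, 0] == 0).all()
        assert (om.dx[:, 1] == 0).all() and (om.dy[:, 1] == 1).all()

    def test_empty_subtile_inherits_global_offset(self, rng):
        # points only in the top-left subtile
        ref = rng.uniform(10, 110, size=(200, 2)).round()
        det = ref + np.array([2.0, 3.0])
        om = imageproc.refine_offsets(det, ref, (256, 256), subtile=128)
        assert om.lookup(200, 200) == (2.0, 3.0)


class TestPsfKernel:
    def test_centre_weight_is_one(self):
        k = imageproc.make_psf_kernel()
        assert k.weights[4, 4] == 1.0

    def test_fourfold_symmetry_and_monotone_decay(self):
        k = imageproc.make_psf_kernel()
        w = k.weights
        assert w[4, 5] == w[4, 3] == w[5, 4] == w[3, 4]
        assert np.array_equal(w, np.rot90(w))
        centre_dist = np.hypot(*np.mgrid[-4:5, -4:5])
        order = np.argsort(centre_dist.ravel())
        assert (np.diff(w.ravel()[order]) <= 1e-12).all()

    def test_kernel_sum_matches_direct_summation(self):
        k = imageproc.make_psf_kernel(9, 0.5)
        oracle = sum(np.exp(-(dx * dx + dy * dy) / (2 * 0.25))
                     for dx in range(-4, 5) for dy in range(-4, 5))
        assert k.weights.sum() == pytest.approx(oracle, rel=1e-12)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            imageproc.make_psf_kernel(8, 0.5)


class TestExtractIntensity:
    def setup_method(self):
        self.kernel = imageproc.make_psf_kernel()

    def test_zero_image_gives_zero(self):
        img = np.zeros((32, 32))
        fi, rej = imageproc.extract_intensity(img, 16, 16, self.kernel)
        assert fi == 0 and not rej

    def test_uniform_image_gives_value_times_kernel_sum(self):
        img = np.full((32, 32), 7.0)
        fi, rej = imageproc.extract_intensity(img, 16, 16, self.kernel)
        assert fi == pytest.approx(7.0 * self.kernel.weights.sum())

    def test_cluster_near_edge_rejected(self):
        img = np.ones((32, 32))
        fi, rej = imageproc.extract_intensity(img, 2, 16, self.kernel)
        assert rej and np.isnan(fi)

    def test_linearity(self, rng):
        img1 = rng.uniform(0, 100, size=(32, 32))
        img2 = rng.uniform(0, 100, size=(32, 32))
        f1, _ = imageproc.extract_intensity(img1, 15, 17, self.kernel)
        f2, _ = imageproc.extract_intensity(img2, 15, 17, self.kernel)
        f12, _ = imageproc.extract_intensity(3 * img1 + 2 * img2, 15, 17, self.kernel)
        assert f12 == pytest.approx(3 * f1 + 2 * f2, rel=1e-10)


class TestFullChain:
    def test_zero_noise_rank_order_preserved(self):
        clones = synthcell.make_library(30, seed=21)
        clusters = synthcell.lay_out_clusters(clones, redundancy=1, seed=21)
        true_vals = np.linspace(300, 3000, len(clusters))
        img = synthcell.render_tile(clusters, true_vals, noise_sd=0)
        table = imageproc.quantify_tile(img, clusters, "c", "T", threshold=100)
        assert not table["rejected"].any()
        got_rank = np.argsort(np.argsort(table["fi"].to_numpy()))
        want_rank = np.argsort(np.argsort(true_vals))
        assert np.array_equal(got_rank, want_rank)

    def test_zero_noise_rank_order_preserved_subpixel(self):
        # fixed-window photometry of sub-pixel-placed spots carries a
        # phase sensitivity of up to ~17%; values spaced 30% apart must
        # still rank correctly
        clones = synthcell.make_library(15, seed=23)
        clusters = synthcell.lay_out_clusters(clones, redundancy=1, seed=23,
                                              jitter=1.0, min_spacing=8)
        true_vals = 100.0 * 1.3 ** np.arange(len(clusters))
        img = synthcell.render_tile(clusters, true_vals, noise_sd=0)
        table = imageproc.quantify_tile(img, clusters, "c", "T", threshold=50)
        keep = ~table["rejected"]
        got_rank = np.argsort(np.argsort(table.loc[keep, "fi"].to_numpy()))
        want_rank = np.argsort(np.argsort(true_vals[keep.to_numpy()]))
        assert np.array_equal(got_rank, want_rank)

    def test_round_trip_recovers_values_to_global_constant(self):
        # integer-snapped placement isolates the photometric chain from the
        # sub-pixel phase sensitivity of fixed-window extraction
        clones = synthcell.make_library(40, seed=22)
        clusters = synthcell.lay_out_clusters(clones, redundancy=1, seed=22)
        true_vals = np.linspace(500, 2500, len(clusters))
        img = synthcell.render_tile(clusters, true_vals, noise_sd=0)
        table = imageproc.quantify_tile(img, clusters, "c", "T", threshold=100)
        ratio = table["fi"].to_numpy() / true_vals
        assert np.std(ratio) / np.mean(ratio) < 0.01
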