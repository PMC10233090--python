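"""Post-processing operators against brute-force oracles."""

import numpy as np
import pytest

from octowound.core import TissueClass
from octowound.phantom import PhantomSpec, desk_geometry, generate_phantom
from octowound.postprocess import (
    PostprocessConfig,
    detect_surface,
    elliptic_fourier_smooth,
    postprocess_scan,
    remove_isolated_pixels,
    remove_small_islands,
    smooth_boundary_fourier,
    truncate_depth,
)
from skimage import draw


def brute_force_isolated(labels, connectivity=8):
    """Per-pixel neighbour scan, the slow way."""
    h, w = labels.shape
    out = labels.copy()
    offs4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    offs = offs4 + ([(-1, -1), (-1, 1), (1, -1), (1, 1)] if connectivity == 8 else [])
    for y in range(h):
        for x in range(w):
            nb = [
                labels[y + dy, x + dx]
                for dy, dx in offs
                if 0 <= y + dy < h and 0 <= x + dx < w
            ]
            if all(v != labels[y, x] for v in nb):
                counts = np.bincount(nb, minlength=7)
                out[y, x] = counts.argmax()
    return out


def brute_force_islands(labels, min_px, connectivity=8):
    """Flood-fill component labelling and boundary-mode reassignment."""
    h, w = labels.shape
    out = labels.copy()
    offs4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    offs = offs4 + ([(-1, -1), (-1, 1), (1, -1), (1, 1)] if connectivity == 8 else [])
    seen = np.zeros((h, w), bool)
    for y0 in range(h):
        for x0 in range(w):
            if seen[y0, x0]:
                continue
            cls = out[y0, x0]
            stack, comp = [(y0, x0)], []
            seen[y0, x0] = True
            while stack:
                y, x = stack.pop()
                comp.append((y, x))
                for dy, dx in offs:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and not seen[yy, xx] and out[yy, xx] == cls:
                        seen[yy, xx] = True
                        stack.append((yy, xx))
            if len(comp) >= min_px:
                continue
            ring = set()
            for y, x in comp:
                for dy, dx in offs:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and (yy, xx) not in comp:
                        ring.add((yy, xx))
            if ring:
                votes = np.bincount([out[p] for p in ring], minlength=7)
                for y, x in comp:
                    out[y, x] = votes.argmax()
    return out


class TestRemoveIsolatedPixels:
    def test_single_pixel_absorbed(self):
        f = np.full((7, 7), int(TissueClass.LATE_GRANULATION), np.uint8)
        f[3, 3] = TissueClass.EARLY_GRANULATION
        out = remove_isolated_pixels(f)
        assert out[3, 3] == TissueClass.LATE_GRANULATION

    def test_uniform_frame_unchanged(self):
        f = np.full((7, 7), 1, np.uint8)
        assert np.array_equal(remove_isolated_pixels(f), f)

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        f = rng.integers(0, 4, (20, 20)).astype(np.uint8)
        assert np.array_equal(
            remove_isolated_pixels(f, connectivity),
            brute_force_isolated(f, connectivity),
        )


class TestRemoveSmallIslands:
    def test_blob_absorbed_into_surroundings(self):
        f = np.ones((20, 20), np.uint8)
        f[5, 5:8] = TissueClass.BLOOD_CLOT  # 3-px clot blob in dermis
        out = remove_small_islands(f, min_island_px=10)
        assert (out == 1).all()

    def test_component_at_threshold_retained(self):
        f = np.ones((20, 20), np.uint8)
        f[5:7, 5:10] = 5  # exactly 10 pixels
        out = remove_small_islands(f, min_island_px=10)
        assert np.array_equal(out, f)

    def test_single_class_frame_unchanged(self):
        f = np.full((12, 12), 3, np.uint8)
        assert np.array_equal(remove_small_islands(f, 10), f)

    def test_matches_flood_fill_oracle_on_100_random_frames(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            # Blocky random frames so components have non-trivial sizes.
            f = rng.integers(0, 3, (8, 8)).astype(np.uint8)
            f = np.repeat(np.repeat(f, 4, 0), 4, 1)
            f[rng.random((32, 32)) < 0.05] = 5
            assert np.array_equal(
                remove_small_islands(f, 6), brute_force_islands(f, 6)
            ), f"mismatch at seed {seed}"


class TestFourierSmoothing:
    def test_disc_nearly_invariant(self):
        mask = np.zeros((64, 64), np.uint8)
        rr, cc = draw.disk((32, 32), 15)
        mask[rr, cc] = 2
        out = smooth_boundary_fourier(mask, 2, n_harmonics=4)
        a0, a1 = (mask == 2).sum(), (out == 2).sum()
        assert abs(a1 - a0) / a0 < 0.02

    def test_square_corners_rounded_low_harmonics(self):
        sq = np.zeros((64, 64), np.uint8)
        sq[20:44, 20:44] = 2
        out = smooth_boundary_fourier(sq, 2, n_harmonics=2)
        ratio = (out == 2).sum() / (sq == 2).sum()
        assert 0.85 < ratio < 1.15
        assert out[21, 21] != 2  # corner was cut

    def test_identity_in_all_harmonics_limit(self):
        sq = np.zeros((64, 64), np.uint8)
        sq[20:44, 20:44] = 2
        out = smooth_boundary_fourier(sq, 2, n_harmonics=200)
        assert np.array_equal(out, sq)

    def test_absent_class_passthrough(self):
        f = np.ones((16, 16), np.uint8)
        assert np.array_equal(smooth_boundary_fourier(f, 5, 8), f)

    def test_tiny_component_passthrough(self):
        f = np.ones((16, 16), np.uint8)
        f[8, 8] = 5
        out = smooth_boundary_fourier(f, 5, 8)
        assert out[8, 8] == 5

    def test_pixel_count_conserved(self):
        mask = np.zeros((64, 64), np.uint8)
        rr, cc = draw.ellipse(30, 32, 10, 18)
        mask[rr, cc] = 2
        out = smooth_boundary_fourier(mask, 2, n_harmonics=3)
        assert out.size == mask.size  # labels reassigned, never dropped

    def test_efd_reconstruction_closed_curve(self):
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        contour = np.stack([32 + 10 * np.sin(theta), 32 + 10 * np.cos(theta)], 1)
        rec = elliptic_fourier_smooth(contour, n_harmonics=1, n_points=100)
        # A circle is exactly representable by the first harmonic.
        assert np.allclose(
            np.hypot(rec[:, 0] - 32, rec[:, 1] - 32), 10, atol=0.1
        )


class TestSurfaceAndDepth:
    def test_flat_bright_surface_found(self):
        f = np.zeros((64, 64), np.float32)
        f[40:] = 0.8
        surface, flagged = detect_surface(f)
        assert (surface == 40).all() and not flagged.any()

    def test_specular_dropout_bridged_by_median(self):
        f = np.zeros((64, 64), np.float32)
        f[40:] = 0.8
        f[:, 30] = 0.0
        surface, _ = detect_surface(f)
        assert surface[30] == 40

    def test_all_dark_frame_flagged(self):
        f = np.zeros((64, 64), np.float32)
        surface, flagged = detect_surface(f)
        assert flagged.all()
        assert (surface == 63).all()

    def test_truncate_flat_surface_arithmetic(self):
        # limit 1 mm at 5 um pitch cuts from row 200 below a row-0 surface
        lab = np.ones((256, 8), np.uint8)
        out = truncate_depth(lab, np.zeros(8, int), 1.0, 0.005)
        assert (out[:200] == 1).all() and (out[200:] == 0).all()

    def test_truncate_noop_when_limit_exceeds_frame(self):
        lab = np.ones((32, 8), np.uint8)
        out = truncate_depth(lab, np.zeros(8, int), 10.0, 0.005)
        assert np.array_equal(out, lab)

    def test_truncation_follows_tilted_surface(self):
        lab = np.ones((64, 16), np.uint8)
        surface = np.arange(16)
        out = truncate_depth(lab, surface, 0.1, 0.005)  # 20 px limit
        for col in range(16):
            cut = surface[col] + 20
            assert (out[:cut, col] == 1).all()
            assert (out[cut:, col] == 0).all()


class TestPostprocessScan:
    @pytest.fixture(scope="class")
    def phantom(self):
        # Frame depth (1.28 mm) close to the 1 mm analysis limit, so the
        # depth cut does not dominate the comparisons below.
        from octowound.core import ScanGeometry

        geo = ScanGeometry(
            n_frames=8, frame_spacing=0.75, frame_height_px=64,
            frame_width_px=192, pixel_pitch=0.02,
        )
        return generate_phantom(PhantomSpec(geometry=geo, stage=0.3, seed=21))

    def test_label_noise_volume_error_decreases(self, phantom):
        scan, truth = phantom
        rng = np.random.default_rng(0)
        noisy = truth.labels.copy()
        flip = rng.random(noisy.shape) < 0.02
        noisy[flip] = rng.integers(0, 7, int(flip.sum()))
        from octowound.core import LabelStack, WOUND_CLASSES

        raw = LabelStack(geometry=truth.geometry, labels=noisy)
        clean = postprocess_scan(raw, scan)
        true_v = truth.class_volumes()
        raw_v = raw.class_volumes()
        clean_v = clean.class_volumes()
        err_raw = sum(abs(raw_v[c] - true_v[c]) for c in WOUND_CLASSES)
        err_clean = sum(abs(clean_v[c] - true_v[c]) for c in WOUND_CLASSES)
        assert err_clean < err_raw

    def test_approximately_idempotent(self, phantom):
        scan, truth = phantom
        once = postprocess_scan(truth, scan)
        twice = postprocess_scan(once, scan)
        changed = (once.labels != twice.labels).mean()
        assert changed < 0.01

    def test_pixel_count_conserved(self, phantom):
        scan, truth = phantom
        out = postprocess_scan(truth, scan)
        assert out.labels.shape == truth.labels.shape

    def test_clean_stack_changes_confined_to_boundaries(self, phantom):
        scan, truth = phantom
        out = postprocess_scan(truth, scan)
        assert (out.labels != truth.labels).mean() < 0.03

    def test_geometry_mismatch_rejected(self, phantom):
        scan, truth = phantom
        other_geo = desk_geometry(n_frames=3, frame_spacing=2.0)
        import numpy as np
        from octowound.core import LabelStack

        other = LabelStack(
            geometry=other_geo, labels=np.zeros(other_geo.shape, np.uint8)
        )
        with pytest.raises(ValueError):
            postprocess_scan(other, scan)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PostprocessConfig(connectivity=6)
        with pytest.raises(ValueError):
            PostprocessConfig(depth_limit=0)
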