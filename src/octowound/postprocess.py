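"""Cleaning of raw per-frame predictions.

Per frame, in this fixed order:

1. isolated-pixel removal (a pixel all of whose neighbours disagree is
   reassigned to its modal neighbour class),
2. small-island removal (connected components below an area threshold are
   absorbed into the modal class of their boundary ring),
3. elliptic-Fourier boundary smoothing of each quantified wound class,
4. surface detection on the intensity frame (Otsu threshold + column-wise
   median filter),
5. truncation of analysis to a fixed depth (default 1 mm) below the
   detected surface — truncated pixels become NON_TISSUE.

All operators reassign labels but never drop pixels, so the frame pixel
count is conserved throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw, filters, measure

from .core import LabelStack, N_CLASSES, OCTScan, TissueClass, WOUND_CLASSES

__all__ = [
    "PostprocessConfig",
    "remove_isolated_pixels",
    "remove_small_islands",
    "elliptic_fourier_smooth",
    "smooth_boundary_fourier",
    "detect_surface",
    "truncate_depth",
    "postprocess_frame",
    "postprocess_scan",
]

logger = logging.getLogger(__name__)

# Island threshold expressed as a physical area; the pixel threshold is
# this area divided by pitch**2 (64 px at 5 um pitch).
DEFAULT_MIN_ISLAND_MM2 = 64 * 0.005**2


@dataclass(frozen=True)
class PostprocessConfig:
    min_island_mm2: float = DEFAULT_MIN_ISLAND_MM2
    connectivity: int = 8  # 4 or 8
    n_fourier_harmonics: int = 16
    depth_limit: float = 1.0  # mm below the detected surface
    surface_median_window: int = 15  # columns

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_island_mm2 < 0 or self.n_fourier_harmonics < 1:
            raise ValueError("invalid postprocess parameters")
        if self.depth_limit <= 0:
            raise ValueError("depth_limit must be positive")

    def min_island_px(self, pixel_pitch: float) -> int:
        return max(1, int(round(self.min_island_mm2 / pixel_pitch**2)))


_NO_NEIGHBOUR = 255  # sentinel for out-of-frame positions


def _neighbour_stack(labels: np.ndarray, connectivity: int) -> np.ndarray:
    """Stack of neighbour labels per pixel; out-of-frame -> sentinel."""
    shifts4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    shifts8 = shifts4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    shifts = shifts4 if connectivity == 4 else shifts8
    h, w = labels.shape
    out = np.empty((len(shifts), h, w), dtype=np.uint8)
    for i, (dy, dx) in enumerate(shifts):
        sh = np.full((h, w), _NO_NEIGHBOUR, dtype=np.uint8)
        ys = slice(max(dy, 0), h + min(dy, 0))
        yd = slice(max(-dy, 0), h + min(-dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        xd = slice(max(-dx, 0), w + min(-dx, 0))
        sh[yd, xd] = labels[ys, xs]
        out[i] = sh
    return out


def _modal_class(values: np.ndarray) -> int:
    """Most frequent class code; ties broken by the lowest code."""
    counts = np.bincount(values, minlength=N_CLASSES)
    return int(counts.argmax())


def remove_isolated_pixels(labels: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Reassign pixels none of whose neighbours share their class.

    Each such pixel takes the modal class of its neighbourhood (ties ->
    lowest code); every other pixel is unchanged.
    """
    labels = np.asarray(labels)
    nb = _neighbour_stack(labels, connectivity)
    # A neighbour "agrees" only if it exists and carries the same class.
    valid = nb != _NO_NEIGHBOUR
    isolated = ~np.any(valid & (nb == labels[None]), axis=0)
    isolated &= valid.any(axis=0)
    if not isolated.any():
        return labels.copy()
    out = labels.copy()
    ys, xs = np.nonzero(isolated)
    votes = nb[:, ys, xs]  # (n_neigh, n_isolated), sentinel-padded
    onehot = np.zeros((N_CLASSES, ys.size), dtype=np.int32)
    for k in range(N_CLASSES):
        onehot[k] = (votes == k).sum(axis=0)
    out[ys, xs] = onehot.argmax(axis=0)
    return out


def _cc_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def remove_small_islands(
    labels: np.ndarray, min_island_px: int, connectivity: int = 8
) -> np.ndarray:
    """Absorb per-class connected components smaller than the threshold.

    A component with area < ``min_island_px`` is reassigned to the modal
    class of the pixels bordering it (ties -> lowest code).  Components of
    exactly the threshold size are retained.
    """
    labels = np.asarray(labels)
    out = labels.copy()
    struct = _cc_structure(connectivity)
    for cls in range(N_CLASSES):
        mask = out == cls
        if not mask.any():
            continue
        comp, n = ndimage.label(mask, structure=struct)
        if n == 0:
            continue
        areas = np.bincount(comp.ravel())[1:]
        for ci in np.nonzero(areas < min_island_px)[0] + 1:
            blob = comp == ci
            ring = ndimage.binary_dilation(blob, structure=struct) & ~blob
            if not ring.any():
                continue  # component fills the frame
            out[blob] = _modal_class(out[ring])
    return out


# ---------------------------------------------------------------------------
# Elliptic Fourier descriptors (Kuhl & Giardina parameterisation)
# ---------------------------------------------------------------------------

def _efd_coefficients(contour: np.ndarray, n_harmonics: int):
    """EFD coefficients of a closed contour given as (K, 2) (row, col)."""
    d = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    dt = np.where(dt == 0, 1e-12, dt)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2 * np.pi * t / T
    n = np.arange(1, n_harmonics + 1)[:, None]
    c1 = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    s1 = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2 * n**2 * np.pi**2)
    dx = d[:, 0] / dt
    dy = d[:, 1] / dt
    a = const[:, 0] * (c1 @ dx)
    b = const[:, 0] * (s1 @ dx)
    c = const[:, 0] * (c1 @ dy)
    dcoef = const[:, 0] * (s1 @ dy)
    # DC terms
    xi = np.cumsum(d[:, 0]) - d[:, 0] / dt * t[1:]
    a0 = contour[0, 0] + (1 / T) * np.sum(
        d[:, 0] / (2 * dt) * (t[1:] ** 2 - t[:-1] ** 2) + xi * dt
    )
    delta = np.cumsum(d[:, 1]) - d[:, 1] / dt * t[1:]
    c0 = contour[0, 1] + (1 / T) * np.sum(
        d[:, 1] / (2 * dt) * (t[1:] ** 2 - t[:-1] ** 2) + delta * dt
    )
    return a0, c0, np.stack([a, b, c, dcoef], axis=1)


def _efd_reconstruct(a0, c0, coeffs, n_points: int) -> np.ndarray:
    phi = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    n = np.arange(1, coeffs.shape[0] + 1)[:, None]
    cosn = np.cos(n * phi)
    sinn = np.sin(n * phi)
    x = a0 + coeffs[:, 0] @ cosn + coeffs[:, 1] @ sinn
    y = c0 + coeffs[:, 2] @ cosn + coeffs[:, 3] @ sinn
    return np.stack([x, y], axis=1)


def elliptic_fourier_smooth(
    contour: np.ndarray, n_harmonics: int, n_points: int = 256
) -> np.ndarray:
    """Smooth a closed (row, col) contour by truncating its EFD expansion."""
    a0, c0, coeffs = _efd_coefficients(contour, n_harmonics)
    return _efd_reconstruct(a0, c0, coeffs, n_points)


def smooth_boundary_fourier(
    labels: np.ndarray,
    cls: int,
    n_harmonics: int,
    connectivity: int = 8,
    min_boundary_points: int = 8,
) -> np.ndarray:
    """Smooth the outer boundary of every component of one class.

    Each component's outer contour is expanded in elliptic Fourier
    descriptors, truncated to ``n_harmonics``, re-rasterised and written
    back.  Pixels the class loses are reassigned to their nearest
    surrounding class; pixels it gains take the class.  Interior holes are
    preserved (only outer contours are smoothed).  Components whose contour
    is shorter than ``min_boundary_points`` pass through unchanged.
    """
    labels = np.asarray(labels)
    mask = labels == cls
    if not mask.any():
        return labels.copy()
    struct = _cc_structure(connectivity)
    comp, n = ndimage.label(mask, structure=struct)
    new_mask = np.zeros_like(mask)
    h, w = labels.shape
    for ci in range(1, n + 1):
        blob = comp == ci
        filled = ndimage.binary_fill_holes(blob)
        holes = filled & ~blob
        contours = measure.find_contours(
            np.pad(filled.astype(float), 1), 0.5
        )
        if not contours:
            new_mask |= blob
            continue
        outer = max(contours, key=len) - 1.0  # undo the pad offset
        if len(outer) < min_boundary_points:
            new_mask |= blob
            continue
        smooth = elliptic_fourier_smooth(outer, n_harmonics)
        rr, cc = draw.polygon(smooth[:, 0], smooth[:, 1], shape=(h, w))
        raster = np.zeros_like(blob)
        raster[rr, cc] = True
        raster &= ~holes
        new_mask |= raster
    out = labels.copy()
    lost = mask & ~new_mask
    gained = new_mask & ~mask
    if lost.any():
        # Nearest non-class pixel donates its label.
        _, (iy, ix) = ndimage.distance_transform_edt(mask, return_indices=True)
        ys, xs = np.nonzero(lost)
        out[ys, xs] = labels[iy[ys, xs], ix[ys, xs]]
    out[gained] = cls
    return out


def detect_surface(
    frame: np.ndarray, median_window: int = 15
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column skin-surface depth (row index) from a grayscale frame.

    The first supra-threshold pixel per column (Otsu threshold over the
    frame) marks the surface; the profile is then median-filtered across
    columns.  Columns with no supra-threshold pixel are set to the frame
    bottom and flagged.

    Returns ``(surface_rows, flagged_columns)``.
    """
    frame = np.asarray(frame, dtype=np.float32)
    h, w = frame.shape
    if float(frame.max()) <= float(frame.min()):
        logger.warning("surface detection: constant frame, all columns flagged")
        return np.full(w, h - 1, dtype=np.int64), np.ones(w, dtype=bool)
    thr = filters.threshold_otsu(frame)
    above = frame > thr
    has = above.any(axis=0)
    first = np.where(has, above.argmax(axis=0), h - 1)
    if (~has).any():
        logger.warning(
            "surface detection: %d/%d columns with no supra-threshold pixel",
            int((~has).sum()), w,
        )
    smoothed = ndimage.median_filter(
        first.astype(np.int64), size=median_window, mode="nearest"
    )
    return smoothed, ~has


def truncate_depth(
    labels: np.ndarray,
    surface: np.ndarray,
    depth_limit: float,
    pixel_pitch: float,
) -> np.ndarray:
    """Set pixels deeper than ``surface + depth_limit`` to NON_TISSUE."""
    labels = np.asarray(labels)
    h, w = labels.shape
    if surface.shape != (w,):
        raise ValueError("surface length must equal frame width")
    cut = surface + depth_limit / pixel_pitch
    rows = np.arange(h)[:, None]
    out = labels.copy()
    out[rows >= cut[None, :]] = TissueClass.NON_TISSUE
    return out


def postprocess_frame(
    raw_labels: np.ndarray,
    intensity: np.ndarray,
    pixel_pitch: float,
    cfg: PostprocessConfig,
) -> np.ndarray:
    out = remove_isolated_pixels(raw_labels, cfg.connectivity)
    out = remove_small_islands(out, cfg.min_island_px(pixel_pitch), cfg.connectivity)
    for cls in WOUND_CLASSES:
        out = smooth_boundary_fourier(
            out, int(cls), cfg.n_fourier_harmonics, cfg.connectivity
        )
    surface, _ = detect_surface(intensity, cfg.surface_median_window)
    return truncate_depth(out, surface, cfg.depth_limit, pixel_pitch)


def postprocess_scan(
    raw: LabelStack, scan: OCTScan, cfg: PostprocessConfig | None = None
) -> LabelStack:
    """Apply the full per-frame cleaning sequence to a predicted stack."""
    cfg = cfg or PostprocessConfig()
    if raw.geometry != scan.geometry:
        raise ValueError("label stack and scan geometries differ")
    out = np.empty_like(raw.labels)
    for i in range(raw.geometry.n_frames):
        out[i] = postprocess_frame(
            raw.labels[i], scan.frames[i], raw.geometry.pixel_pitch, cfg
        )
    return LabelStack(
        geometry=raw.geometry,
        labels=out,
        metadata={**raw.metadata, "postprocessed": True},
    )
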