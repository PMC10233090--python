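"""Synthetic OCT wound phantoms with exact ground-truth labels.

The phantom emulates a 3 mm punch-biopsy wound imaged as a stack of
B-scan frames: an undulating skin surface separates dark non-tissue above
from speckled tissue below; a cylindrical crater centred in the scan is
filled bottom-up with early then late granulation tissue, rimmed by
neo-epidermal tongues advancing from the crater edges and capped by a
central blood clot, with intact tissue everywhere peripheral to the wound.

The wound is carved *voxel-exactly*: each target class volume is converted
to a voxel count and voxels are assigned by sorted depth below the local
surface, so the realised label volumes match the requested targets to
within one voxel.  Intensities follow a first-order OCT image model:
per-class mean reflectivity, exponential depth attenuation, and
multiplicative gamma-distributed speckle with a small spatial correlation.

Default target volumes interpolate a healing trajectory between day-2-like
and day-7-like anchor volumes for the four wound morphologies (early
granulation shrinking, clot and neo-epidermis growing as the wound matures).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import WOUND_CLASSES, LabelStack, OCTScan, ScanGeometry, TissueClass

__all__ = [
    "PhantomSpec",
    "DAY2_ANCHOR_VOLUMES",
    "DAY7_ANCHOR_VOLUMES",
    "DEFAULT_CLASS_INTENSITY",
    "healing_trajectory",
    "generate_phantom",
    "generate_cohort",
    "desk_geometry",
]

# Day-2 / day-7 anchor volumes (mm^3) for the four quantified wound classes.
DAY2_ANCHOR_VOLUMES: dict[TissueClass, float] = {
    TissueClass.EARLY_GRANULATION: 1.56,
    TissueClass.LATE_GRANULATION: 2.12,
    TissueClass.NEO_EPIDERMIS: 0.9,
    TissueClass.BLOOD_CLOT: 1.28,
}
DAY7_ANCHOR_VOLUMES: dict[TissueClass, float] = {
    TissueClass.EARLY_GRANULATION: 0.09,
    TissueClass.LATE_GRANULATION: 0.87,
    TissueClass.NEO_EPIDERMIS: 1.46,
    TissueClass.BLOOD_CLOT: 2.68,
}

# Appearance signatures: each morphology carries a distinct mean
# reflectivity (before attenuation and speckle), mirroring how the tissue
# subtypes present visually in wound OCT: immature granulation is dark and
# disorganised, maturing granulation intermediate and homogeneous, the
# neo-epidermal band bright and smooth, clot/scab bright and strongly
# heterogeneous.
DEFAULT_CLASS_INTENSITY: dict[TissueClass, float] = {
    TissueClass.NON_TISSUE: 0.03,
    TissueClass.INTACT_TISSUE: 0.60,
    TissueClass.EARLY_GRANULATION: 0.25,
    TissueClass.LATE_GRANULATION: 0.42,
    TissueClass.NEO_EPIDERMIS: 0.78,
    TissueClass.BLOOD_CLOT: 0.92,
    TissueClass.ACTIVE_BLEEDING: 0.12,
}


# Per-class speckle heterogeneity (gamma shape; higher = smoother).
# Clot/scab scatters very heterogeneously, immature granulation is
# disorganised, maturing granulation and the neo-epidermal band are
# homogeneous layers.
DEFAULT_CLASS_SPECKLE_SHAPE: dict[TissueClass, float] = {
    TissueClass.EARLY_GRANULATION: 3.0,
    TissueClass.LATE_GRANULATION: 10.0,
    TissueClass.NEO_EPIDERMIS: 12.0,
    TissueClass.BLOOD_CLOT: 2.0,
    TissueClass.ACTIVE_BLEEDING: 3.0,
}


def healing_trajectory(
    stage: float,
    day2_anchors: dict[TissueClass, float] | None = None,
    day7_anchors: dict[TissueClass, float] | None = None,
) -> dict[TissueClass, float]:
    """Target wound-class volumes (mm**3) at a healing stage in [0, 1].

    ``stage=0`` reproduces the day-2-like anchor volumes, ``stage=1`` the
    day-7-like anchors; intermediate stages interpolate linearly.  Early
    granulation volume is therefore non-increasing in stage while clot and
    neo-epidermis volumes are non-decreasing, matching the direction of the
    observed day-2 to day-7 changes.
    """
    if not 0.0 <= stage <= 1.0:
        raise ValueError(f"stage must be in [0, 1], got {stage}")
    a = DAY2_ANCHOR_VOLUMES if day2_anchors is None else day2_anchors
    b = DAY7_ANCHOR_VOLUMES if day7_anchors is None else day7_anchors
    return {c: (1.0 - stage) * a[c] + stage * b[c] for c in WOUND_CLASSES}


def desk_geometry(
    n_frames: int = 12,
    frame_px: int = 64,
    pixel_pitch: float = 0.05,
    frame_spacing: float = 0.5,
) -> ScanGeometry:
    """Small square-frame geometry used for fast experiments and tests.

    The defaults cover the same 6 mm lateral span and a 3.2 mm-wide,
    3.2 mm-deep frame at a coarse 50 um pitch, so a 3 mm crater still fits.
    """
    return ScanGeometry(
        n_frames=n_frames,
        frame_spacing=frame_spacing,
        frame_height_px=frame_px,
        frame_width_px=frame_px,
        pixel_pitch=pixel_pitch,
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic wound scan.

    ``stage`` positions the phantom on the healing trajectory; explicit
    ``target_volumes`` override the trajectory per class.  ``seed`` makes
    the phantom bit-reproducible.
    """

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    wound_diameter: float = 3.0
    stage: float = 0.0
    target_volumes: dict[TissueClass, float] | None = None
    speckle_shape: float = 4.0
    # Texture heterogeneity per class: blood clot is a strongly heterogeneous
    # scatterer (low gamma shape -> high contrast), neo-epidermis a smooth
    # homogeneous layer (high shape -> low contrast).
    class_speckle_shape: dict[TissueClass, float] | None = None
    attenuation_coeff: float = 0.5  # per mm
    class_mean_intensity: dict[TissueClass, float] | None = None
    # Optional volume of pooled fresh blood under the clot cap (rare in
    # practice, off by default; used for class-coverage tests).
    active_bleeding_volume: float = 0.0
    surface_depth: float = 0.35  # mean skin-surface depth below frame top, mm
    surface_undulation_amp: float = 0.05
    max_crater_depth: float = 0.95  # keeps the wound inside the 1 mm analysis depth
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.stage <= 1.0:
            raise ValueError("stage must be in [0, 1]")
        if self.wound_diameter < 0:
            raise ValueError("wound_diameter must be non-negative")
        if self.wound_diameter > self.geometry.span:
            raise ValueError(
                "wound_diameter exceeds the scanned lateral span "
                f"({self.wound_diameter} > {self.geometry.span} mm)"
            )
        if self.target_volumes is not None and any(
            v < 0 for v in self.target_volumes.values()
        ):
            raise ValueError("target_volumes must be non-negative")

    def resolved_targets(self) -> dict[TissueClass, float]:
        """Per-class target volumes, from overrides or the healing trajectory."""
        if self.target_volumes is not None:
            return {c: float(self.target_volumes.get(c, 0.0)) for c in WOUND_CLASSES}
        return healing_trajectory(self.stage)

    def intensities(self) -> dict[TissueClass, float]:
        if self.class_mean_intensity is not None:
            merged = dict(DEFAULT_CLASS_INTENSITY)
            merged.update(self.class_mean_intensity)
            return merged
        return DEFAULT_CLASS_INTENSITY


class PhantomGeometryError(ValueError):
    """Raised when target volumes cannot fit in the crater geometry."""


def _surface_depth_map(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Skin-surface depth (mm below frame top) per (frame, column)."""
    g = spec.geometry
    x = (np.arange(g.frame_width_px) + 0.5) * g.pixel_pitch
    y = (np.arange(g.n_frames) + 0.5) * g.frame_spacing
    yy, xx = np.meshgrid(y, x, indexing="ij")
    # Low-frequency undulation with seeded random phases/frequencies.
    phases = rng.uniform(0, 2 * np.pi, size=4)
    fx = rng.uniform(0.3, 0.9, size=2)  # cycles per mm
    fy = rng.uniform(0.15, 0.5, size=2)
    und = (
        np.sin(2 * np.pi * fx[0] * xx + phases[0])
        + 0.6 * np.sin(2 * np.pi * fx[1] * xx + phases[1])
        + np.sin(2 * np.pi * fy[0] * yy + phases[2])
        + 0.6 * np.sin(2 * np.pi * fy[1] * yy + phases[3])
    )
    und = und / 3.2  # roughly unit amplitude
    return spec.surface_depth + spec.surface_undulation_amp * und


def _carve_wound(
    spec: PhantomSpec, labels: np.ndarray, surface: np.ndarray
) -> None:
    """Assign wound-class voxels inside the crater, voxel-exactly, in place."""
    g = spec.geometry
    targets = spec.resolved_targets()
    voxvol = g.voxel_volume
    n_per_class = {c: int(round(targets[c] / voxvol)) for c in WOUND_CLASSES}
    n_total = sum(n_per_class.values())
    if n_total == 0:
        return

    radius = spec.wound_diameter / 2.0
    x = (np.arange(g.frame_width_px) + 0.5) * g.pixel_pitch
    y = (np.arange(g.n_frames) + 0.5) * g.frame_spacing
    z = (np.arange(g.frame_height_px) + 0.5) * g.pixel_pitch
    xc = g.frame_width_mm / 2.0
    yc = g.span / 2.0
    # Plan-view radial distance of every (frame, column).
    r_plan = np.sqrt((y[:, None] - yc) ** 2 + (x[None, :] - xc) ** 2)
    in_circle = r_plan < radius  # (n_frames, width)

    # Depth below the local skin surface for every voxel in crater columns.
    fi, ci = np.nonzero(in_circle)
    if fi.size == 0:
        raise PhantomGeometryError(
            "crater footprint contains no voxel columns at this geometry"
        )
    zeta = z[None, :] - surface[fi, ci][:, None]  # (n_cols, depth)
    depth_ok = (zeta >= 0.0) & (zeta <= spec.max_crater_depth)
    # Crater must stay inside the frame.
    depth_ok &= (z[None, :] < g.frame_depth_mm - g.pixel_pitch)

    cand = np.nonzero(depth_ok)
    n_cand = cand[0].size
    if n_total > n_cand:
        worst = max(n_per_class, key=n_per_class.get)
        raise PhantomGeometryError(
            f"target volumes need {n_total} voxels but the crater holds only "
            f"{n_cand}; largest offender is {worst.name} "
            f"({targets[worst]:.3g} mm^3)"
        )

    zeta_c = zeta[cand]
    # Region = the n_total shallowest candidate voxels (vertical-walled
    # crater whose floor depth adapts to the requested total volume).
    order = np.argsort(zeta_c, kind="stable")
    sel = order[:n_total]
    col_idx = cand[0][sel]  # index into fi/ci
    row_idx = cand[1][sel]  # depth index
    zeta_sel = zeta_c[sel]
    r_sel = r_plan[fi[col_idx], ci[col_idx]]

    # Bottom-up assignment: EGT deepest, LGT above it.  A mild central
    # bias keeps small residual granulation volumes coherent pockets at
    # the wound centre (healing advances inward from the margins) instead
    # of scattered one-voxel sheets across the crater floor.
    deep_order = np.argsort(-(zeta_sel + 0.3 * (radius - r_sel)), kind="stable")
    n_egt = n_per_class[TissueClass.EARLY_GRANULATION]
    n_lgt = n_per_class[TissueClass.LATE_GRANULATION]
    n_ne = n_per_class[TissueClass.NEO_EPIDERMIS]
    egt_ix = deep_order[:n_egt]
    lgt_ix = deep_order[n_egt : n_egt + n_lgt]
    shell_ix = deep_order[n_egt + n_lgt :]

    # Top shell: neo-epidermal tongues wrap in from the crater rim, clot
    # caps the centre.  Score favours voxels that are shallow and near the
    # rim; the lowest-scoring n_ne voxels become neo-epidermis.
    score = zeta_sel[shell_ix] + (radius - r_sel[shell_ix])
    ne_pick = np.argsort(score, kind="stable")[:n_ne]
    ne_mask = np.zeros(shell_ix.size, dtype=bool)
    ne_mask[ne_pick] = True

    frame_of = fi[col_idx]
    colm_of = ci[col_idx]
    labels[frame_of[egt_ix], row_idx[egt_ix], colm_of[egt_ix]] = (
        TissueClass.EARLY_GRANULATION
    )
    labels[frame_of[lgt_ix], row_idx[lgt_ix], colm_of[lgt_ix]] = (
        TissueClass.LATE_GRANULATION
    )
    ne_all = shell_ix[ne_mask]
    clot_all = shell_ix[~ne_mask]
    labels[frame_of[ne_all], row_idx[ne_all], colm_of[ne_all]] = (
        TissueClass.NEO_EPIDERMIS
    )
    labels[frame_of[clot_all], row_idx[clot_all], colm_of[clot_all]] = (
        TissueClass.BLOOD_CLOT
    )
    if spec.active_bleeding_volume > 0 and clot_all.size:
        # Fresh blood pools at the base of the clot cap.
        n_bld = min(
            int(round(spec.active_bleeding_volume / voxvol)), clot_all.size
        )
        deepest = clot_all[np.argsort(-zeta_sel[clot_all], kind="stable")[:n_bld]]
        labels[frame_of[deepest], row_idx[deepest], colm_of[deepest]] = (
            TissueClass.ACTIVE_BLEEDING
        )


def _render_intensity(
    spec: PhantomSpec,
    labels: np.ndarray,
    surface: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Class mean x depth attenuation x correlated multiplicative speckle."""
    g = spec.geometry
    lut = np.zeros(8, dtype=np.float32)
    for cls, m in spec.intensities().items():
        lut[int(cls)] = m
    mean_img = lut[labels]

    z = (np.arange(g.frame_height_px, dtype=np.float32) + 0.5) * g.pixel_pitch
    depth_below = z[None, :, None] - surface[:, None, :]
    atten = np.exp(
        -spec.attenuation_coeff * np.clip(depth_below, 0.0, None)
    ).astype(np.float32)
    # No attenuation above the surface (non-tissue stays uniformly dark).
    atten[depth_below < 0] = 1.0

    shape_lut = np.full(8, spec.speckle_shape, dtype=np.float32)
    for cls, k in (spec.class_speckle_shape or DEFAULT_CLASS_SPECKLE_SHAPE).items():
        shape_lut[int(cls)] = k
    k_map = shape_lut[labels]
    speckle = rng.gamma(shape=k_map, scale=1.0 / k_map).astype(np.float32)
    img = mean_img * atten * speckle
    # Slight lateral blur per frame emulates the finite speckle grain.
    img = ndimage.gaussian_filter(img, sigma=(0.0, 0.6, 0.6), mode="nearest")
    return np.clip(img, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec) -> tuple[OCTScan, LabelStack]:
    """Generate one paired (scan, ground-truth label stack) phantom.

    The same spec (including seed) always reproduces bit-identical output.
    Raises :class:`PhantomGeometryError` when the requested class volumes
    exceed the crater capacity at this geometry.
    """
    g = spec.geometry
    rng = np.random.default_rng(spec.seed)

    surface = _surface_depth_map(spec, rng)  # (n_frames, width), mm

    labels = np.zeros(g.shape, dtype=np.uint8)
    z = (np.arange(g.frame_height_px) + 0.5) * g.pixel_pitch
    below_surface = z[None, :, None] >= surface[:, None, :]
    labels[below_surface] = TissueClass.INTACT_TISSUE

    _carve_wound(spec, labels, surface)

    frames = _render_intensity(spec, labels, surface, rng)

    meta = {"stage": spec.stage, "seed": spec.seed, "wound_diameter": spec.wound_diameter}
    return (
        OCTScan(geometry=g, frames=frames, metadata=dict(meta)),
        LabelStack(geometry=g, labels=labels, metadata=dict(meta)),
    )


def generate_cohort(
    n_scans: int,
    stage_list: list[float],
    base_seed: int,
    geometry: ScanGeometry | None = None,
    diameter_jitter: float = 0.05,
    undulation_jitter: float = 0.3,
    **spec_kwargs,
) -> list[tuple[OCTScan, LabelStack, PhantomSpec]]:
    """Generate a reproducible, non-degenerate cohort of phantoms.

    Per-scan seeds derive deterministically from ``base_seed``; crater
    diameter and surface undulation are jittered (fractions of their
    defaults) so the cohort is not a single phantom repeated.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if len(stage_list) != n_scans:
        raise ValueError("stage_list length must equal n_scans")
    master = np.random.default_rng(base_seed)
    seeds = master.integers(0, 2**31 - 1, size=n_scans)
    base = PhantomSpec(geometry=geometry or ScanGeometry(), **spec_kwargs)
    out = []
    for i in range(n_scans):
        d = base.wound_diameter * (1.0 + diameter_jitter * master.uniform(-1, 1))
        amp = base.surface_undulation_amp * (
            1.0 + undulation_jitter * master.uniform(-1, 1)
        )
        spec = replace(
            base,
            wound_diameter=float(d),
            surface_undulation_amp=float(amp),
            stage=float(stage_list[i]),
            seed=int(seeds[i]),
        )
        scan, lab = generate_phantom(spec)
        out.append((scan, lab, spec))
    return out
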