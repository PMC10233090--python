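"""Core domain types shared by every pipeline stage.

Physical conventions used throughout the package:

* a 3D OCT scan is an ordered stack of 2D B-scan frames, each frame a
  depth-by-lateral grayscale image; frame ``i`` is centred at lateral
  position ``(i + 0.5) * frame_spacing`` along the stack axis,
* all lengths are millimetres, areas mm**2, volumes mm**3,
* intensities live in ``[0, 1]``,
* tissue labels use the fixed integer code table of :class:`TissueClass`
  with ``NON_TISSUE == 0`` doubling as the background above the skin
  surface (background-as-zero convention for mask tooling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "TissueClass",
    "WOUND_CLASSES",
    "N_CLASSES",
    "ScanGeometry",
    "OCTScan",
    "LabelStack",
]


class TissueClass(IntEnum):
    """The seven tissue morphologies segmented from wound OCT frames.

    The integer codes are stable across the whole package and across all
    serialised label files.  ``NON_TISSUE`` is both the air/gel region above
    the skin surface and the catch-all for pixels excluded from analysis
    (e.g. below the depth limit).
    """

    NON_TISSUE = 0
    INTACT_TISSUE = 1
    EARLY_GRANULATION = 2
    LATE_GRANULATION = 3
    NEO_EPIDERMIS = 4
    BLOOD_CLOT = 5
    ACTIVE_BLEEDING = 6


#: The four wound morphologies that are quantified (areas / volumes).
WOUND_CLASSES: tuple[TissueClass, ...] = (
    TissueClass.EARLY_GRANULATION,
    TissueClass.LATE_GRANULATION,
    TissueClass.NEO_EPIDERMIS,
    TissueClass.BLOOD_CLOT,
)

N_CLASSES = 7


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of a 3D OCT scan.

    Parameters
    ----------
    n_frames
        Number of B-scan frames in the stack.
    frame_spacing
        Distance between consecutive frames in mm.  The scanned lateral
        span is ``n_frames * frame_spacing``.
    frame_height_px, frame_width_px
        Frame size in pixels (depth by lateral).
    pixel_pitch
        In-frame pixel size in mm, isotropic within a frame.
    """

    n_frames: int = 120
    frame_spacing: float = 0.05
    frame_height_px: int = 256
    frame_width_px: int = 700
    pixel_pitch: float = 0.005

    def __post_init__(self) -> None:
        if self.n_frames <= 0 or self.frame_height_px <= 0 or self.frame_width_px <= 0:
            raise ValueError("pixel and frame counts must be strictly positive")
        if self.frame_spacing <= 0 or self.pixel_pitch <= 0:
            raise ValueError("frame_spacing and pixel_pitch must be strictly positive")

    @property
    def span(self) -> float:
        """Lateral span covered by the stack in mm."""
        return self.n_frames * self.frame_spacing

    @property
    def frame_depth_mm(self) -> float:
        return self.frame_height_px * self.pixel_pitch

    @property
    def frame_width_mm(self) -> float:
        return self.frame_width_px * self.pixel_pitch

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm**3 (pitch**2 x frame spacing)."""
        return self.pixel_pitch**2 * self.frame_spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_frames, self.frame_height_px, self.frame_width_px)

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "frame_spacing": self.frame_spacing,
            "frame_height_px": self.frame_height_px,
            "frame_width_px": self.frame_width_px,
            "pixel_pitch": self.pixel_pitch,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(
            n_frames=int(d["n_frames"]),
            frame_spacing=float(d["frame_spacing"]),
            frame_height_px=int(d["frame_height_px"]),
            frame_width_px=int(d["frame_width_px"]),
            pixel_pitch=float(d["pixel_pitch"]),
        )


def _check_stack(geometry: ScanGeometry, arr: np.ndarray, name: str) -> None:
    if arr.ndim != 3:
        raise ValueError(f"{name} must be a 3D (frames, depth, width) array")
    if arr.shape != geometry.shape:
        raise ValueError(
            f"{name} shape {arr.shape} does not match geometry {geometry.shape}"
        )


@dataclass
class OCTScan:
    """An ordered stack of grayscale B-scan frames with physical geometry."""

    geometry: ScanGeometry
    frames: np.ndarray  # float array, (n_frames, H, W), intensities in [0, 1]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        _check_stack(self.geometry, self.frames, "frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("scan intensities must be finite")
        if self.frames.size and (self.frames.min() < 0 or self.frames.max() > 1):
            raise ValueError("scan intensities must lie in [0, 1]")


@dataclass
class LabelStack:
    """Per-pixel tissue-class assignments over the same geometry as a scan."""

    geometry: ScanGeometry
    labels: np.ndarray  # uint8 array, (n_frames, H, W), TissueClass codes
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        _check_stack(self.geometry, self.labels, "labels")
        if self.labels.size:
            lo, hi = int(self.labels.min()), int(self.labels.max())
            if lo < 0 or hi >= N_CLASSES:
                raise ValueError(
                    f"label codes must be in [0, {N_CLASSES - 1}], got [{lo}, {hi}]"
                )
        self.labels = self.labels.astype(np.uint8)

    def class_volumes(self) -> dict[TissueClass, float]:
        """Voxel-count volume of every tissue class in mm**3."""
        counts = np.bincount(self.labels.ravel(), minlength=N_CLASSES)
        vox = self.geometry.voxel_volume
        return {cls: float(counts[cls] * vox) for cls in TissueClass}
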