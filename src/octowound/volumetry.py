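"""Areas, volumes and caliper-style measurements from label stacks.

Per-frame class areas are pixel counts times ``pixel_pitch**2`` (mm**2);
per-scan volumes are the frame areas summed and multiplied by the frame
spacing (mm**3) — the identity ``volume = sum(area) * spacing`` holds to
machine precision by construction.  Only the four wound morphologies are
tabulated.

Two "manual-analogue" measurements mirror the single-frame caliper
measurements used for validation: wound width (largest contiguous lateral
span of early granulation tissue in any single frame) and blood-clot depth
(largest contiguous vertical span of clot in any single column).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LabelStack, ScanGeometry, TissueClass, WOUND_CLASSES

__all__ = [
    "FrameAreaTable",
    "ScanQuantification",
    "frame_areas",
    "scan_volumes",
    "frame_histogram",
    "wound_width",
    "clot_depth",
    "quantify_scan",
    "average_biopsy_pairs",
]

_CLASS_COLUMNS = {
    TissueClass.EARLY_GRANULATION: "egt_mm2",
    TissueClass.LATE_GRANULATION: "lgt_mm2",
    TissueClass.NEO_EPIDERMIS: "ne_mm2",
    TissueClass.BLOOD_CLOT: "clot_mm2",
}


@dataclass
class FrameAreaTable:
    """Per-frame wound-class areas in mm**2 plus the frame spacing."""

    areas: pd.DataFrame  # index frame_index, columns egt/lgt/ne/clot _mm2
    frame_spacing: float

    def series(self, cls: TissueClass) -> np.ndarray:
        return self.areas[_CLASS_COLUMNS[cls]].to_numpy()


@dataclass
class ScanQuantification:
    """Per-scan wound-class volumes and manual-analogue measurements."""

    scan_id: str
    volumes: dict[TissueClass, float]  # mm^3, four wound classes
    wound_width: float  # mm
    clot_depth: float  # mm
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scan_id": self.scan_id,
            "volumes_mm3": {c.name: v for c, v in self.volumes.items()},
            "wound_width_mm": self.wound_width,
            "clot_depth_mm": self.clot_depth,
            "provenance": self.provenance,
        }


def frame_areas(labels: LabelStack, geometry: ScanGeometry | None = None) -> FrameAreaTable:
    """Tabulate the four wound-class areas (mm**2) for every frame."""
    g = geometry or labels.geometry
    px_area = g.pixel_pitch**2
    rows = {}
    flat = labels.labels.reshape(g.n_frames, -1)
    for cls, col in _CLASS_COLUMNS.items():
        rows[col] = (flat == int(cls)).sum(axis=1) * px_area
    df = pd.DataFrame(rows)
    df.index.name = "frame_index"
    return FrameAreaTable(areas=df, frame_spacing=g.frame_spacing)


def scan_volumes(table: FrameAreaTable) -> dict[TissueClass, float]:
    """Per-class volume: sum of frame areas times the scanning interval."""
    return {
        cls: float(table.areas[col].sum() * table.frame_spacing)
        for cls, col in _CLASS_COLUMNS.items()
    }


def frame_histogram(table: FrameAreaTable) -> pd.DataFrame:
    """Ordered per-class area-vs-frame-index series, unsmoothed (plot-ready)."""
    return table.areas.copy()


def _max_contiguous_run(mask_1d: np.ndarray) -> int:
    """Length of the longest run of True values."""
    if not mask_1d.any():
        return 0
    padded = np.concatenate([[0], mask_1d.view(np.int8), [0]])
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return int((ends - starts).max())


def wound_width(
    labels: LabelStack,
    geometry: ScanGeometry | None = None,
    cls: TissueClass = TissueClass.EARLY_GRANULATION,
    method: str = "contiguous",
) -> float:
    """Maximum in-frame lateral extent of a class, in mm.

    Per frame, the class's pixels are projected onto the lateral axis and
    either the longest contiguous column span (``method="contiguous"``,
    the caliper-style default) or the bounding-box span
    (``method="bbox"``) is measured; the maximum over all frames times
    the pixel pitch is returned (0 if the class is absent).
    """
    if method not in ("contiguous", "bbox"):
        raise ValueError("method must be 'contiguous' or 'bbox'")
    g = geometry or labels.geometry
    present = (labels.labels == int(cls)).any(axis=1)  # (n_frames, width)
    if method == "bbox":
        best = 0
        for row in present:
            cols = np.nonzero(row)[0]
            if cols.size:
                best = max(best, int(cols[-1] - cols[0] + 1))
    else:
        best = max((_max_contiguous_run(row) for row in present), default=0)
    return best * g.pixel_pitch


def clot_depth(labels: LabelStack, geometry: ScanGeometry | None = None) -> float:
    """Maximum vertical extent of blood clot (mm), per-column contiguous."""
    g = geometry or labels.geometry
    clot = labels.labels == int(TissueClass.BLOOD_CLOT)
    best = 0
    for f in range(clot.shape[0]):
        cols = clot[f]  # (depth, width)
        if not cols.any():
            continue
        for ci in np.nonzero(cols.any(axis=0))[0]:
            best = max(best, _max_contiguous_run(cols[:, ci]))
    return best * g.pixel_pitch


def quantify_scan(
    labels: LabelStack,
    scan_id: str = "",
    provenance: dict | None = None,
) -> ScanQuantification:
    """Full per-scan quantification: volumes plus width/depth analogues."""
    table = frame_areas(labels)
    return ScanQuantification(
        scan_id=scan_id or str(labels.metadata.get("scan_id", "")),
        volumes=scan_volumes(table),
        wound_width=wound_width(labels),
        clot_depth=clot_depth(labels),
        provenance=provenance or {},
    )


def average_biopsy_pairs(
    quants: list[ScanQuantification],
    pairing: dict[str, list[str]],
) -> list[ScanQuantification]:
    """Average replicate scans of the same biopsy sample.

    ``pairing`` maps sample id -> 1 or 2 scan ids.  Volumes, width and
    depth are averaged arithmetically; singleton samples pass through.
    """
    by_id = {q.scan_id: q for q in quants}
    out = []
    for sample, scan_ids in pairing.items():
        if not scan_ids:
            raise ValueError(f"sample {sample!r} maps to no scans")
        missing = [s for s in scan_ids if s not in by_id]
        if missing:
            raise ValueError(f"sample {sample!r}: unknown scan ids {missing}")
        qs = [by_id[s] for s in scan_ids]
        out.append(
            ScanQuantification(
                scan_id=sample,
                volumes={
                    c: float(np.mean([q.volumes[c] for q in qs]))
                    for c in WOUND_CLASSES
                },
                wound_width=float(np.mean([q.wound_width for q in qs])),
                clot_depth=float(np.mean([q.clot_depth for q in qs])),
                provenance={"averaged_from": list(scan_ids)},
            )
        )
    return out
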