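"""Reading and writing scans, label stacks, quantifications and reports.

Scans and label stacks are multi-page TIFFs (one page per frame) with a
JSON sidecar (``<stem>.json``) carrying the scan geometry and free-form
metadata.  Label TIFFs hold the integer class codes losslessly; intensity
TIFFs are written as 8- or 16-bit grayscale and round-trip to within half
a quantisation step.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import LabelStack, N_CLASSES, OCTScan, ScanGeometry

__all__ = [
    "sidecar_path",
    "write_scan",
    "read_scan",
    "write_labels",
    "read_labels",
    "write_json",
    "read_json",
]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def _write_sidecar(path, geometry: ScanGeometry, metadata: dict, kind: str) -> None:
    payload = {"kind": kind, "geometry": geometry.to_dict(), "metadata": metadata}
    sidecar_path(path).write_text(json.dumps(payload, indent=2, default=str))


def _read_sidecar(path) -> tuple[ScanGeometry, dict]:
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"missing geometry sidecar {sc} for {path}"
        )
    payload = json.loads(sc.read_text())
    return ScanGeometry.from_dict(payload["geometry"]), payload.get("metadata", {})


def _check_pages(arr: np.ndarray, path) -> np.ndarray:
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2D pages, got shape {arr.shape}")
    return arr


def write_scan(scan: OCTScan, path, bit_depth: int = 16) -> None:
    """Write a scan as a multi-page grayscale TIFF plus a JSON sidecar."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    maxval = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    data = np.round(np.clip(scan.frames, 0, 1) * maxval).astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    _write_sidecar(path, scan.geometry, {**scan.metadata, "bit_depth": bit_depth}, "scan")


def read_scan(path) -> OCTScan:
    geometry, metadata = _read_sidecar(path)
    arr = _check_pages(tifffile.imread(path), path)
    maxval = float(np.iinfo(arr.dtype).max) if arr.dtype.kind == "u" else 1.0
    frames = arr.astype(np.float32) / maxval
    return OCTScan(geometry=geometry, frames=frames, metadata=metadata)


def write_labels(labels: LabelStack, path) -> None:
    """Write a label stack as a multi-page integer-coded TIFF + sidecar."""
    tifffile.imwrite(path, labels.labels.astype(np.uint8), photometric="minisblack")
    _write_sidecar(path, labels.geometry, labels.metadata, "labels")


def read_labels(path) -> LabelStack:
    geometry, metadata = _read_sidecar(path)
    arr = _check_pages(tifffile.imread(path), path)
    bad = np.unique(arr[(arr < 0) | (arr >= N_CLASSES)])
    if bad.size:
        raise ValueError(f"{path}: label codes outside the class table: {bad.tolist()}")
    return LabelStack(geometry=geometry, labels=arr, metadata=metadata)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
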