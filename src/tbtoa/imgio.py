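"""Reading and writing texture images and their metadata sidecars.

Images travel as 8- or 16-bit grayscale PNG/TIFF; the physical metadata a
radiograph needs for texture analysis (pixel spacing, tibial bounding box,
optional ROI-layout overrides) travels in a JSON sidecar next to the image.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import DataError
from .texture import ROILayout, TextureImage, build_roi_layout

__all__ = ["write_image", "read_image", "write_sidecar", "read_sidecar", "layout_from_sidecar"]


def write_image(image: TextureImage, path: str | Path) -> None:
    """Write a texture image as 16-bit grayscale PNG (or TIFF by extension)."""
    arr = np.clip(np.rint(image.pixels), 0, 65535).astype(np.uint16)
    Image.fromarray(arr).save(str(path))  # uint16 -> 16-bit grayscale ("I;16")


def read_image(path: str | Path, pixel_spacing_mm: float) -> TextureImage:
    """Read an 8/16-bit grayscale PNG or TIFF into a TextureImage."""
    with Image.open(str(path)) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise DataError(f"{path}: expected single-channel grayscale, got shape {arr.shape}")
    return TextureImage(pixels=arr.astype(float), pixel_spacing_mm=pixel_spacing_mm)


def write_sidecar(
    path: str | Path,
    pixel_spacing_mm: float,
    tibia_bbox: tuple[int, int, int, int],
    roi_layout: dict | None = None,
) -> None:
    """Write the JSON metadata sidecar for one image."""
    payload = {
        "pixel_spacing_mm": pixel_spacing_mm,
        "tibia_bbox": list(tibia_bbox),
        "roi_layout": roi_layout or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_sidecar(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    for key in ("pixel_spacing_mm", "tibia_bbox"):
        if key not in payload:
            raise DataError(f"{path}: sidecar lacks required key {key!r}")
    return payload


def layout_from_sidecar(sidecar: dict) -> ROILayout:
    """Build the ROI layout described by a sidecar (bbox + optional overrides)."""
    overrides = sidecar.get("roi_layout") or {}
    compartment_cols = overrides.get("compartment_cols")
    if compartment_cols is not None:
        compartment_cols = {int(k): v for k, v in compartment_cols.items()}
    return build_roi_layout(
        tuple(sidecar["tibia_bbox"]),
        rows=overrides.get("rows", 2),
        cols=overrides.get("cols", 8),
        compartment_cols=compartment_cols,
    )
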