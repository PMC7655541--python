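"""Data layer of the semi-automatic annotation loop.

The interactive tool itself is out of scope; this module implements its
data exchange: predicted masks become editable contour polygons, corrected
polygons rasterize back to masks, and correction sets (polygons to add,
polygons to remove) merge into predicted masks.  Files use a
LabelMe-compatible JSON dialect (``shapes`` of ``polygon`` type with
``points`` as (x, y) pairs) with a single label class ``nodule``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.measure import find_contours

from .postprocess import label_components

__all__ = [
    "PolygonAnnotation",
    "mask_to_contours",
    "contours_to_mask",
    "apply_corrections",
    "save_labelme",
    "load_labelme",
]

PROVENANCES = ("manual", "predicted", "corrected")


@dataclass
class PolygonAnnotation:
    """Closed nodule outlines for one image, with per-polygon provenance."""

    image_id: str
    polygons: list[np.ndarray] = field(default_factory=list)  # (k>=3, 2) (row, col)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.provenance) != len(self.polygons):
            raise ValueError("one provenance entry per polygon required")
        for poly in self.polygons:
            if np.asarray(poly).ndim != 2 or np.asarray(poly).shape[1] != 2:
                raise ValueError("polygons must be (k, 2) vertex arrays")
        for p in self.provenance:
            if p not in PROVENANCES:
                raise ValueError(f"unknown provenance {p!r}")

    def __len__(self) -> int:
        return len(self.polygons)


def mask_to_contours(mask: np.ndarray, image_id: str = "image", provenance: str = "predicted") -> PolygonAnnotation:
    """Extract one outer contour polygon per connected component.

    Contours are taken at the 0.5 level of the binary mask, so the
    polygons pass between foreground and background pixel centers;
    rasterizing them recovers each component up to boundary pixels.
    """
    labels = label_components(mask, connectivity=8)
    polygons: list[np.ndarray] = []
    n = int(labels.max())
    for lab in range(1, n + 1):
        component = labels == lab
        padded = np.pad(component.astype(float), 1)
        contours = find_contours(padded, 0.5)
        if not contours:
            continue
        poly = max(contours, key=len) - 1.0
        if len(poly) < 3:
            continue
        polygons.append(poly)
    return PolygonAnnotation(
        image_id=image_id,
        polygons=polygons,
        provenance=[provenance] * len(polygons),
    )


def contours_to_mask(annotation: PolygonAnnotation, dims: tuple[int, int]) -> np.ndarray:
    """Rasterize filled polygons; overlapping polygons union."""
    h, w = dims
    mask = np.zeros((h, w), dtype=bool)
    for poly in annotation.polygons:
        poly = np.asarray(poly, dtype=float)
        if len(poly) < 3:
            raise ValueError("degenerate polygon with < 3 vertices")
        rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=(h, w))
        mask[rr, cc] = True
    return mask


def apply_corrections(
    predicted: np.ndarray,
    add: PolygonAnnotation,
    remove: PolygonAnnotation,
) -> np.ndarray:
    """Merge human (or oracle) corrections into a predicted mask.

    Returns ``(predicted UNION rasterize(add)) MINUS rasterize(remove)``;
    removal wins where an added and a removed region overlap.  The result
    is a valid training mask for transfer-learning updates.
    """
    predicted = np.asarray(predicted) > 0
    dims = predicted.shape
    out = predicted | contours_to_mask(add, dims)
    out &= ~contours_to_mask(remove, dims)
    return out


# ---------------------------------------------------------------------------
# LabelMe-compatible JSON files
# ---------------------------------------------------------------------------


def save_labelme(
    annotation: PolygonAnnotation,
    path: str | Path,
    image_height: int,
    image_width: int,
) -> None:
    """Write a LabelMe-dialect JSON file (points are (x, y) = (col, row))."""
    shapes = []
    for poly, prov in zip(annotation.polygons, annotation.provenance):
        pts = [[float(c), float(r)] for r, c in np.asarray(poly)]
        shapes.append(
            {
                "label": "nodule",
                "points": pts,
                "shape_type": "polygon",
                "description": prov,
                "group_id": None,
                "flags": {},
            }
        )
    doc = {
        "version": "5.0.0",
        "flags": {},
        "shapes": shapes,
        "imagePath": f"{annotation.image_id}.png",
        "imageData": None,
        "imageHeight": int(image_height),
        "imageWidth": int(image_width),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_labelme(path: str | Path) -> PolygonAnnotation:
    doc = json.loads(Path(path).read_text())
    polygons, provenance = [], []
    for shape in doc.get("shapes", []):
        if shape.get("shape_type") != "polygon":
            continue
        pts = np.asarray(shape["points"], dtype=float)
        polygons.append(pts[:, ::-1].copy())  # (x, y) -> (row, col)
        prov = shape.get("description") or "manual"
        provenance.append(prov if prov in PROVENANCES else "manual")
    image_id = str(Path(doc.get("imagePath", "image.png")).stem)
    return PolygonAnnotation(image_id=image_id, polygons=polygons, provenance=provenance)
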