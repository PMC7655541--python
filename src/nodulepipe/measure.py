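"""Nodule phenotypes from final masks: counts and areas in physical units.

Each surviving connected component is one nodule; its pixel count times
the squared mm-per-pixel reference scale is its area.  Per-image rows
aggregate the phenotypes that feed the statistical analysis: nodule count
and total area in mm^2 and cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import find_contours, regionprops

__all__ = [
    "NoduleRecord",
    "MeasurementRow",
    "calibrate_scale",
    "measure_components",
    "summarize_image",
    "measurements_to_frame",
]


@dataclass
class NoduleRecord:
    """One detected nodule component."""

    label: int
    pixel_count: int
    area_mm2: float
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (top, left, height, width)
    contour: np.ndarray  # (k, 2) closed polygon, (row, col)


@dataclass
class MeasurementRow:
    """Per-image phenotype summary."""

    image_id: str
    nodule_count: int
    total_area_mm2: float
    total_area_cm2: float
    mean_area_mm2: float | None  # None when no nodules detected


def calibrate_scale(reference_pixel_length: float, reference_mm_length: float) -> float:
    """mm-per-pixel from a physically measured reference object."""
    if reference_pixel_length <= 0 or reference_mm_length <= 0:
        raise ValueError("reference lengths must be positive")
    return reference_mm_length / reference_pixel_length


def _outer_contour(component_mask: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    padded = np.pad(component_mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:  # single-pixel degenerate case
        r, c = np.nonzero(component_mask)
        r0, c0 = float(r[0]) + offset[0], float(c[0]) + offset[1]
        return np.array([[r0 - 0.5, c0 - 0.5], [r0 - 0.5, c0 + 0.5],
                         [r0 + 0.5, c0 + 0.5], [r0 + 0.5, c0 - 0.5]])
    contour = max(contours, key=len)
    return contour - 1.0 + np.asarray(offset, dtype=float)


def measure_components(labels: np.ndarray, mm_per_pixel: float) -> list[NoduleRecord]:
    """One :class:`NoduleRecord` per labeled component.

    Areas are exact: pixel count x mm_per_pixel^2, measured on whatever
    grid ``labels`` lives on (the pipeline measures on the reconstructed
    full-resolution mask).
    """
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    records: list[NoduleRecord] = []
    for rp in regionprops(np.asarray(labels)):
        top, left, bottom, right = rp.bbox
        component = rp.image
        contour = _outer_contour(component, (top, left))
        records.append(
            NoduleRecord(
                label=int(rp.label),
                pixel_count=int(rp.area),
                area_mm2=float(rp.area) * mm_per_pixel**2,
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                bbox=(top, left, bottom - top, right - left),
                contour=contour,
            )
        )
    return records


def summarize_image(records: list[NoduleRecord], image_id: str) -> MeasurementRow:
    """Aggregate one image's records into its phenotype row."""
    count = len(records)
    total_mm2 = float(sum(r.area_mm2 for r in records))
    return MeasurementRow(
        image_id=image_id,
        nodule_count=count,
        total_area_mm2=total_mm2,
        total_area_cm2=total_mm2 / 100.0,
        mean_area_mm2=(total_mm2 / count) if count else None,
    )


def measurements_to_frame(rows: list[MeasurementRow]) -> pd.DataFrame:
    """Measurement rows as a DataFrame (CSV-ready; missing mean left blank)."""
    return pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "nodule_count": r.nodule_count,
                "total_area_mm2": r.total_area_mm2,
                "total_area_cm2": r.total_area_cm2,
                "mean_area_mm2": r.mean_area_mm2,
            }
            for r in rows
        ]
    )
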