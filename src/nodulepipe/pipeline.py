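"""End-to-end wiring: image -> probability -> mask -> components -> phenotypes.

The online path mirrors the measurement workflow: preprocess the
photograph to the network size, predict per-pixel probabilities, refine
with the dense CRF and close/fill at network resolution, reconstruct the
binary mask at the original resolution, optionally merge annotation-based
error corrections, then detect components, drop undersized noise and
measure counts and areas in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import prep, segnet
from .annotation import PolygonAnnotation, apply_corrections
from .measure import MeasurementRow, NoduleRecord, measure_components, summarize_image
from .postprocess import (
    CrfParams,
    PostprocessParams,
    label_components,
    filter_by_size,
    postprocess_probability,
)
from .synth import RootImage

__all__ = ["SegmentationResult", "segment_image", "measure_image"]


@dataclass
class SegmentationResult:
    """All intermediate products of one image's pass through the pipeline."""

    image_id: str
    prob_network: np.ndarray  # probability map at network resolution
    mask_network: np.ndarray  # refined binary mask at network resolution
    mask_full: np.ndarray  # reconstructed binary mask at original resolution
    labels: np.ndarray  # size-filtered component labels, original resolution
    records: list[NoduleRecord] = field(default_factory=list)
    row: MeasurementRow | None = None


def segment_image(
    model: segnet.SegModel,
    image: RootImage | np.ndarray,
    *,
    crf_params: CrfParams | None = None,
    post_params: PostprocessParams | None = None,
    corrections: tuple[PolygonAnnotation, PolygonAnnotation] | None = None,
    mm_per_pixel: float | None = None,
    image_id: str = "image",
) -> SegmentationResult:
    """Run the online pipeline on one RGB image of any size.

    ``corrections`` is an optional (add, remove) annotation pair applied
    to the reconstructed full-resolution mask before component detection,
    exactly where the error-correction step sits in the workflow.
    """
    if isinstance(image, RootImage):
        pixels = image.pixels
        mm_per_pixel = image.mm_per_pixel if mm_per_pixel is None else mm_per_pixel
        image_id = image.image_id
    else:
        pixels = np.asarray(image)
    if mm_per_pixel is None or mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be provided and positive")
    post_params = post_params or PostprocessParams()

    small, record = prep.preprocess(pixels, model.config.input_size)
    prob = segnet.predict(model, small)
    mask_net = postprocess_probability(prob, small, crf_params, post_params)
    mask_full = prep.reconstruct(mask_net, record)
    if corrections is not None:
        add, remove = corrections
        mask_full = apply_corrections(mask_full, add, remove)
    labels = label_components(mask_full, post_params.connectivity)
    labels = filter_by_size(labels, post_params, mm_per_pixel)
    records = measure_components(labels, mm_per_pixel)
    row = summarize_image(records, image_id)
    return SegmentationResult(
        image_id=image_id,
        prob_network=prob,
        mask_network=mask_net,
        mask_full=mask_full,
        labels=labels,
        records=records,
        row=row,
    )


def measure_image(
    model: segnet.SegModel,
    image: RootImage | np.ndarray,
    **kwargs,
) -> MeasurementRow:
    """Convenience wrapper returning only the per-image phenotype row."""
    return segment_image(model, image, **kwargs).row
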