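"""Scale-and-pad preprocessing between camera resolution and network size.

Field photographs (e.g. 6000x4000 pixels) are reduced to the fixed square
network input (a multiple of 32, e.g. 1024x1024) by a single isotropic
scale that preserves aspect ratio, followed by constant padding that
centers the scaled content.  The :class:`TransformRecord` captures the
mapping exactly so that network outputs can be reconstructed at the
original resolution before measurement.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from skimage.transform import resize

__all__ = ["TransformRecord", "preprocess", "reconstruct"]


@dataclass(frozen=True)
class TransformRecord:
    """Geometry of one scale-and-pad transform; sufficient to invert it."""

    original_height: int
    original_width: int
    scale: float
    scaled_height: int
    scaled_width: int
    pad_top: int
    pad_left: int
    target_size: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "TransformRecord":
        return cls(**json.loads(text))


def _check_target(target_size: int) -> None:
    if target_size <= 0 or target_size % 32 != 0:
        raise ValueError(f"target_size must be a positive multiple of 32, got {target_size}")


def preprocess(
    image: np.ndarray,
    target_size: int,
    *,
    is_mask: bool = False,
) -> tuple[np.ndarray, TransformRecord]:
    """Resize ``image`` isotropically into a ``target_size`` square with padding.

    Parameters
    ----------
    image:
        ``(H, W)`` or ``(H, W, 3)`` array.  RGB images are resampled
        bilinearly; pass ``is_mask=True`` for binary masks, which use
        nearest-neighbor resampling and zero padding.
    target_size:
        Side of the square network input; must be a multiple of 32.

    Returns
    -------
    (out, record):
        ``out`` has spatial dims ``(target_size, target_size)`` and the
        input's dtype; ``record`` inverts the mapping.

    Scaled content dims use floor rounding of ``original_dim * scale``
    with ``scale = target_size / max(H, W)``; padding is centered and
    filled with the image mean (masks: zero).
    """
    _check_target(target_size)
    if image.ndim not in (2, 3) or image.size == 0:
        raise ValueError("image must be a nonempty 2-D or 3-D array")
    h, w = image.shape[:2]
    scale = target_size / max(h, w)
    sh = min(target_size, int(np.floor(h * scale)))
    sw = min(target_size, int(np.floor(w * scale)))
    sh, sw = max(sh, 1), max(sw, 1)

    order = 0 if is_mask else 1
    scaled = resize(
        image.astype(np.float64),
        (sh, sw) + image.shape[2:],
        order=order,
        anti_aliasing=(not is_mask and scale < 1.0),
        preserve_range=True,
    )

    pad_top = (target_size - sh) // 2
    pad_left = (target_size - sw) // 2
    fill = 0.0 if is_mask else float(image.mean())
    out = np.full((target_size, target_size) + image.shape[2:], fill, dtype=np.float64)
    out[pad_top : pad_top + sh, pad_left : pad_left + sw] = scaled
    if np.issubdtype(image.dtype, np.integer) or image.dtype == bool:
        out = np.clip(np.rint(out), np.iinfo(np.uint8).min, np.iinfo(np.uint8).max)
    out = out.astype(image.dtype)

    record = TransformRecord(
        original_height=h,
        original_width=w,
        scale=scale,
        scaled_height=sh,
        scaled_width=sw,
        pad_top=pad_top,
        pad_left=pad_left,
        target_size=target_size,
    )
    return out, record


def reconstruct(
    mask_small: np.ndarray,
    record: TransformRecord,
    *,
    is_mask: bool = True,
) -> np.ndarray:
    """Invert :func:`preprocess`: strip padding and rescale to original dims.

    Binary masks are resampled nearest-neighbor; probability maps
    (``is_mask=False``) bilinearly.  Content in the padding region is
    discarded — it corresponds to no original pixel.
    """
    if mask_small.shape[:2] != (record.target_size, record.target_size):
        raise ValueError(
            f"input dims {mask_small.shape[:2]} do not match record target "
            f"{(record.target_size, record.target_size)}"
        )
    core = mask_small[
        record.pad_top : record.pad_top + record.scaled_height,
        record.pad_left : record.pad_left + record.scaled_width,
    ]
    order = 0 if is_mask else 1
    out = resize(
        core.astype(np.float64),
        (record.original_height, record.original_width) + mask_small.shape[2:],
        order=order,
        anti_aliasing=False,
        preserve_range=True,
    )
    if mask_small.dtype == bool:
        return out > 0.5
    return out.astype(mask_small.dtype if is_mask else np.float64)
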