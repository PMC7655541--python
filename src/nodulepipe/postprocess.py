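"""Turn raw probability maps into clean binary nodule masks.

Three stages, in the fixed pipeline order: (1) fully connected CRF
refinement that combines the network's per-pixel probabilities with pixel
color and position; (2) morphological closing plus interior hole filling;
(3) connected-component detection with size-based noise removal.
Instance splitting of merged nodules is deliberately not attempted — a
merged blob is one component.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.morphology import closing as sk_closing
from skimage.morphology import disk

__all__ = [
    "CrfParams",
    "PostprocessParams",
    "crf_refine",
    "close_and_fill",
    "label_components",
    "filter_by_size",
    "binarize",
    "postprocess_probability",
]


@dataclass(frozen=True)
class CrfParams:
    """Dense-CRF energy parameters.

    Defaults are the published defaults of the reference mean-field
    method: an appearance kernel (weight 10, color sd 13 intensity units,
    position sd 80 px) that couples pixels of similar color, and a
    smoothness kernel (weight 3, position sd 3 px) that discourages
    isolated labels.
    """

    n_iterations: int = 5
    appearance_weight: float = 10.0
    appearance_color_sd: float = 13.0
    appearance_position_sd: float = 80.0
    smoothness_weight: float = 3.0
    smoothness_position_sd: float = 3.0

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for name in (
            "appearance_weight",
            "appearance_color_sd",
            "appearance_position_sd",
            "smoothness_weight",
            "smoothness_position_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PostprocessParams:
    """Binarization, closing and size-filter settings.

    ``min_component_mm2`` expresses the noise-removal threshold in
    physical units so it is resolution independent; it is converted to a
    pixel count via ``mm_per_pixel`` at run time.  A pixel threshold may
    be given directly instead.  Size bounds are inclusive.
    """

    prob_threshold: float = 0.5
    closing_radius: int = 2
    min_component_mm2: float | None = 1.0
    min_component_size: int | None = None  # pixels; overrides mm2 when set
    max_component_size: int | None = None
    connectivity: int = 8

    def validate(self) -> None:
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must lie strictly in (0, 1)")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        lo = self.min_component_size
        if lo is not None and self.max_component_size is not None:
            if lo > self.max_component_size:
                raise ValueError("min_component_size exceeds max_component_size")

    def pixel_min_size(self, mm_per_pixel: float | None = None) -> int:
        """Resolve the minimum component size to pixels."""
        if self.min_component_size is not None:
            return int(self.min_component_size)
        if self.min_component_mm2 is None:
            return 0
        if mm_per_pixel is None or mm_per_pixel <= 0:
            raise ValueError(
                "mm_per_pixel required to convert min_component_mm2 to pixels"
            )
        return int(np.ceil(self.min_component_mm2 / mm_per_pixel**2))


# ---------------------------------------------------------------------------
# Fully connected CRF via mean-field inference
# ---------------------------------------------------------------------------


def _gauss_pair_filter(q: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized Gaussian-kernel sums S(q) and S(1) over image positions.

    Truncated-window Gaussian filtering with constant (zero) boundaries
    approximates the pairwise sum over all in-image pixels.
    """
    amp = 2.0 * np.pi * sigma**2  # 2-D Gaussian normalization undone
    sq = ndi.gaussian_filter(q, sigma, mode="constant", cval=0.0) * amp
    s1 = ndi.gaussian_filter(np.ones_like(q), sigma, mode="constant", cval=0.0) * amp
    return sq, s1


class _BilateralGrid:
    """Splat/blur/slice approximation of the joint (position, color) kernel.

    Pixels are embedded at (row/sp, col/sp, r/sc, g/sc, b/sc); a unit-sigma
    Gaussian blur on the 5-D grid then approximates the appearance kernel
    exp(-|dp|^2 / 2sp^2 - |dc|^2 / 2sc^2).  Multilinear splatting/slicing
    over the 2^5 cell corners keeps the approximation smooth.
    """

    def __init__(self, image: np.ndarray, position_sd: float, color_sd: float):
        h, w = image.shape[:2]
        feats = np.empty((h * w, 5), dtype=np.float64)
        rows, cols = np.mgrid[0:h, 0:w]
        feats[:, 0] = rows.ravel() / position_sd
        feats[:, 1] = cols.ravel() / position_sd
        rgb = image.reshape(h * w, -1)[:, :3].astype(np.float64)
        feats[:, 2:] = rgb / color_sd
        mins = feats.min(axis=0) - 2.0
        self.offsets = feats - mins
        self.base = np.floor(self.offsets).astype(np.int64)
        self.frac = self.offsets - self.base
        self.shape = tuple(int(m) + 4 for m in self.base.max(axis=0))
        # precompute the 32 corner indices and multilinear weights
        self._corners = []
        strides = np.array(
            [int(np.prod(self.shape[i + 1 :])) for i in range(5)], dtype=np.int64
        )
        for corner in itertools.product((0, 1), repeat=5):
            c = np.array(corner, dtype=np.int64)
            idx = ((self.base + c) * strides).sum(axis=1)
            wgt = np.prod(
                np.where(c == 1, self.frac, 1.0 - self.frac), axis=1
            )
            self._corners.append((idx, wgt))
        self.size = int(np.prod(self.shape))

    def filter(self, values: np.ndarray) -> np.ndarray:
        """Approximate sum_j k(f_i, f_j) v_j for per-pixel values v."""
        v = values.ravel().astype(np.float64)
        grid = np.zeros(self.size, dtype=np.float64)
        for idx, wgt in self._corners:
            np.add.at(grid, idx, v * wgt)
        grid = grid.reshape(self.shape)
        grid = ndi.gaussian_filter(grid, sigma=1.0, mode="constant", cval=0.0)
        grid *= (2.0 * np.pi) ** 2.5  # undo 5-D Gaussian normalization
        flat = grid.ravel()
        out = np.zeros_like(v)
        for idx, wgt in self._corners:
            out += flat[idx] * wgt
        return out.reshape(values.shape)


def crf_refine(prob: np.ndarray, image: np.ndarray, params: CrfParams) -> np.ndarray:
    """Mean-field refinement of a foreground probability map.

    The unary energy is the negative log of the network probabilities;
    pairwise Potts terms use a Gaussian appearance kernel (color +
    position) and a Gaussian smoothness kernel (position).  With both
    pairwise weights at zero the output equals the input probabilities.
    """
    params.validate()
    prob = np.asarray(prob, dtype=np.float64)
    if prob.shape != image.shape[:2]:
        raise ValueError(
            f"probability map dims {prob.shape} do not match image {image.shape[:2]}"
        )
    p = np.clip(prob, 1e-8, 1.0 - 1e-8)
    unary_fg = -np.log(p)
    unary_bg = -np.log(1.0 - p)

    use_app = params.appearance_weight > 0
    use_smooth = params.smoothness_weight > 0
    grid = (
        _BilateralGrid(image, params.appearance_position_sd, params.appearance_color_sd)
        if use_app
        else None
    )

    q_fg = p.copy()
    for _ in range(params.n_iterations):
        q_bg = 1.0 - q_fg
        msg_fg = np.zeros_like(q_fg)  # aggregated kernel mass voting fg
        msg_bg = np.zeros_like(q_fg)
        if use_app:
            s1 = np.maximum(grid.filter(np.ones_like(q_fg)) - 1.0, 1e-12)
            mf = (np.maximum(grid.filter(q_fg) - q_fg, 0.0)) / s1
            mb = (np.maximum(grid.filter(q_bg) - q_bg, 0.0)) / s1
            msg_fg += params.appearance_weight * mf
            msg_bg += params.appearance_weight * mb
        if use_smooth:
            sq_f, s1s = _gauss_pair_filter(q_fg, params.smoothness_position_sd)
            sq_b, _ = _gauss_pair_filter(q_bg, params.smoothness_position_sd)
            denom = np.maximum(s1s - 1.0, 1e-12)
            msg_fg += params.smoothness_weight * np.maximum(sq_f - q_fg, 0.0) / denom
            msg_bg += params.smoothness_weight * np.maximum(sq_b - q_bg, 0.0) / denom
        # Potts model: a label pays for kernel mass voting the *other* label
        e_fg = unary_fg + msg_bg
        e_bg = unary_bg + msg_fg
        m = np.minimum(e_fg, e_bg)
        ef = np.exp(-(e_fg - m))
        eb = np.exp(-(e_bg - m))
        q_fg = ef / (ef + eb)
    return q_fg


# ---------------------------------------------------------------------------
# Morphology and components
# ---------------------------------------------------------------------------


def binarize(prob: np.ndarray, params: PostprocessParams) -> np.ndarray:
    """Threshold a probability map at ``prob_threshold`` (inclusive)."""
    params.validate()
    return np.asarray(prob) >= params.prob_threshold


def close_and_fill(mask: np.ndarray, params: PostprocessParams) -> np.ndarray:
    """Morphological closing with a disk, then interior hole filling.

    Closing is extensive and hole filling only adds pixels, so the output
    foreground always contains the input foreground.
    """
    params.validate()
    m = np.asarray(mask) > 0
    if params.closing_radius > 0:
        m = sk_closing(m, disk(params.closing_radius))
    m = ndi.binary_fill_holes(m)
    return m


def label_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label maximal connected foreground regions; background stays 0."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    return sk_label(np.asarray(mask) > 0, connectivity=1 if connectivity == 4 else 2)


def filter_by_size(
    labels: np.ndarray,
    params: PostprocessParams,
    mm_per_pixel: float | None = None,
) -> np.ndarray:
    """Remove components outside the inclusive size bounds; keep label ids."""
    params.validate()
    labels = np.asarray(labels)
    if labels.max() == 0:
        return labels.copy()
    counts = np.bincount(labels.ravel())
    lo = params.pixel_min_size(mm_per_pixel)
    hi = params.max_component_size
    keep = counts >= lo
    if hi is not None:
        keep &= counts <= hi
    keep[0] = False
    out = np.where(keep[labels], labels, 0)
    return out


def postprocess_probability(
    prob: np.ndarray,
    image: np.ndarray,
    crf_params: CrfParams | None,
    params: PostprocessParams,
) -> np.ndarray:
    """CRF refinement (optional) -> threshold -> closing/fill: a binary mask.

    Component labeling and size filtering are applied separately, after
    the mask has been reconstructed at the original resolution and any
    annotation-based error corrections have been merged in.
    """
    if crf_params is not None:
        prob = crf_refine(prob, image, crf_params)
    mask = binarize(prob, params)
    return close_and_fill(mask, params)
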