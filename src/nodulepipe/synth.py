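"""Synthetic root-image scenes and phenotype tables with known ground truth.

Real nodule photographs show dark, noisy soil backgrounds, thin branching
root strands, and many small, bright, roundish nodules that frequently
touch or overlap one another.  This module renders that qualitative
structure — not photorealism — so that every downstream stage
(preprocessing, segmentation, post-processing, measurement, statistics)
can be exercised against exact ground truth.

Scenes carry per-instance pixel sets; the binary mask is always the union
of the instance pixel sets, so merged (overlapping) nodules are a *known*
failure mode for component-based counting rather than an accident.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import disk, dilation

__all__ = [
    "SceneParams",
    "NoduleInstance",
    "RootImage",
    "Scene",
    "DesignSpec",
    "PlacementError",
    "generate_scene",
    "generate_dataset",
    "generate_phenotypes",
]


class PlacementError(RuntimeError):
    """Raised when requested objects cannot be placed after bounded retries."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic root scene.

    Defaults describe a desk-scale 512x512 scene; the geometry is fully
    parameterized so smaller (or larger) scenes are a parameter choice.

    ``overlap_fraction`` is the probability that a nodule is deliberately
    placed touching an existing one; the remaining nodules are placed
    pixel-disjoint.  ``min_separation`` additionally keeps those disjoint
    placements at least that many pixels away from existing foreground,
    so instances remain distinct connected components even after
    morphological closing (0 = plain pixel-disjointness, which still
    allows adjacent instances that merge into one component).
    """

    image_height: int = 512
    image_width: int = 512
    n_roots: int = 3
    root_width_range: tuple[int, int] = (3, 7)
    n_nodules: int = 25
    nodule_radius_range: tuple[float, float] = (6.0, 14.0)
    overlap_fraction: float = 0.3
    min_separation: float = 0.0
    background_noise_sd: float = 8.0
    mm_per_pixel: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_roots < 0 or self.n_nodules < 0:
            raise ValueError("object counts must be >= 0")
        lo, hi = self.root_width_range
        if not (0 < lo <= hi):
            raise ValueError("root_width_range must be positive and ordered")
        rlo, rhi = self.nodule_radius_range
        if not (0 < rlo <= rhi):
            raise ValueError("nodule_radius_range must be positive and ordered")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")


@dataclass
class NoduleInstance:
    """One ground-truth nodule: a rotated ellipse attached to a root."""

    center: tuple[float, float]  # (row, col)
    radii: tuple[float, float]  # (r_major, r_minor) in pixels
    rotation: float  # radians
    rows: np.ndarray  # pixel coordinates of the rendered ellipse
    cols: np.ndarray

    @property
    def pixel_count(self) -> int:
        return int(self.rows.size)


@dataclass
class RootImage:
    """An RGB root photograph plus its identity and physical scale."""

    pixels: np.ndarray  # (H, W, 3) uint8
    image_id: str = "image"
    mm_per_pixel: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class Scene:
    """A rendered scene with exact instance-level ground truth."""

    image: RootImage
    mask: np.ndarray  # (H, W) bool; union of instance pixel sets
    instances: list[NoduleInstance]
    params: SceneParams

    @property
    def true_count(self) -> int:
        return len(self.instances)

    @property
    def true_total_area_mm2(self) -> float:
        # area of the *union* of instance pixels, in mm^2
        return float(self.mask.sum()) * self.params.mm_per_pixel**2


def _render_background(rng: np.random.Generator, h: int, w: int, noise_sd: float) -> np.ndarray:
    """Dark soil-like background: base tone + low-frequency blotches + noise."""
    base = np.array([46.0, 36.0, 28.0])
    img = np.tile(base, (h, w, 1))
    # low-frequency blotches: coarse noise, heavily smoothed
    coarse = rng.normal(0.0, 18.0, size=(max(2, h // 32), max(2, w // 32)))
    blotch = ndi.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)
    img += blotch[..., None]
    img += rng.normal(0.0, noise_sd, size=(h, w, 3))
    return img


def _draw_roots(
    rng: np.random.Generator,
    img: np.ndarray,
    params: SceneParams,
) -> np.ndarray:
    """Draw branching root strands; returns a boolean map of root pixels.

    Each root is a downward random-walk polyline with 0-2 side branches,
    thickened by morphological dilation to the sampled width.
    """
    h, w = img.shape[:2]
    root_map = np.zeros((h, w), dtype=bool)
    lo, hi = params.root_width_range
    for _ in range(params.n_roots):
        thin = np.zeros((h, w), dtype=bool)
        r = 0
        c = int(rng.integers(w // 6, w - w // 6))
        angle = rng.normal(0.0, 0.25)
        step = max(6, h // 24)
        pts = [(r, c)]
        while r < h - 1:
            angle += rng.normal(0.0, 0.3)
            angle = float(np.clip(angle, -1.0, 1.0))
            r2 = min(h - 1, r + step)
            c2 = int(np.clip(c + step * np.tan(angle), 0, w - 1))
            rr, cc = draw_line(r, c, r2, c2)
            thin[rr, cc] = True
            r, c = r2, c2
            pts.append((r, c))
        # side branches from random points of the main strand
        for _ in range(int(rng.integers(0, 3))):
            br, bc = pts[int(rng.integers(0, len(pts)))]
            bangle = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.2)
            length = int(rng.integers(h // 8, h // 3))
            er = int(np.clip(br + length * np.cos(bangle), 0, h - 1))
            ec = int(np.clip(bc + length * np.sin(bangle) * rng.choice([-1, 1]), 0, w - 1))
            rr, cc = draw_line(br, bc, er, ec)
            thin[rr, cc] = True
        width = int(rng.integers(lo, hi + 1))
        thick = dilation(thin, disk(max(1, width // 2)))
        root_map |= thick
    # roots are lighter, tan-colored strands
    tone = np.array([128.0, 104.0, 76.0])
    img[root_map] = tone + rng.normal(0.0, 6.0, size=(int(root_map.sum()), 3))
    return root_map


_MAX_TRIES = 200


def _place_nodules(
    rng: np.random.Generator,
    img: np.ndarray,
    root_map: np.ndarray,
    params: SceneParams,
) -> tuple[np.ndarray, list[NoduleInstance]]:
    h, w = img.shape[:2]
    rlo, rhi = params.nodule_radius_range
    mask = np.zeros((h, w), dtype=bool)
    instances: list[NoduleInstance] = []

    anchor_rows, anchor_cols = np.nonzero(root_map)
    if params.n_nodules > 0 and anchor_rows.size == 0:
        raise PlacementError(
            "no root pixels available to attach nodules to "
            f"(n_roots={params.n_roots}, image {h}x{w})"
        )

    for k in range(params.n_nodules):
        placed = False
        for _ in range(_MAX_TRIES):
            r_major = rng.uniform(rlo, rhi)
            r_minor = r_major * rng.uniform(0.7, 1.0)
            rot = rng.uniform(0.0, np.pi)
            want_overlap = bool(instances) and rng.random() < params.overlap_fraction
            if want_overlap:
                other = instances[int(rng.integers(0, len(instances)))]
                ang = rng.uniform(0.0, 2 * np.pi)
                d = rng.uniform(0.3, 1.0) * max(other.radii)
                cr = other.center[0] + d * np.cos(ang)
                cc = other.center[1] + d * np.sin(ang)
            else:
                j = int(rng.integers(0, anchor_rows.size))
                cr = float(anchor_rows[j]) + rng.normal(0.0, 2.0)
                cc = float(anchor_cols[j]) + rng.normal(0.0, 2.0)
            if not (r_major <= cr < h - r_major and r_major <= cc < w - r_major):
                continue
            rr, cc_px = draw_ellipse(cr, cc, r_major, r_minor, shape=(h, w), rotation=rot)
            if rr.size == 0:
                continue
            if not want_overlap:
                sep = int(np.ceil(params.min_separation))
                if sep > 0:
                    # reject candidates closer than min_separation to
                    # existing foreground (so instances stay distinct
                    # components even after closing)
                    r0 = max(0, rr.min() - sep)
                    r1 = min(h, rr.max() + sep + 1)
                    c0 = max(0, cc_px.min() - sep)
                    c1 = min(w, cc_px.max() + sep + 1)
                    cand = np.zeros((r1 - r0, c1 - c0), dtype=bool)
                    cand[rr - r0, cc_px - c0] = True
                    grown = dilation(cand, disk(sep))
                    if (grown & mask[r0:r1, c0:c1]).any():
                        continue
                elif mask[rr, cc_px].any():
                    continue  # disjoint placement requested but would touch
            inst = NoduleInstance(
                center=(float(cr), float(cc)),
                radii=(float(r_major), float(r_minor)),
                rotation=float(rot),
                rows=rr.copy(),
                cols=cc_px.copy(),
            )
            instances.append(inst)
            mask[rr, cc_px] = True
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place nodule {k + 1}/{params.n_nodules} after "
                f"{_MAX_TRIES} tries (image {h}x{w}, radii {params.nodule_radius_range})"
            )

    # nodules render as bright, slightly shaded blobs
    if instances:
        tone = np.array([188.0, 172.0, 138.0])
        for inst in instances:
            shade = rng.normal(0.0, 8.0)
            img[inst.rows, inst.cols] = (
                tone + shade + rng.normal(0.0, 4.0, size=(inst.rows.size, 3))
            )
    return mask, instances


def generate_scene(params: SceneParams) -> Scene:
    """Render one scene deterministically from ``params.seed``.

    Roots are background in the mask; only nodule pixels are foreground.
    Raises :class:`PlacementError` when the image cannot hold the
    requested objects after bounded retries.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width
    img = _render_background(rng, h, w, params.background_noise_sd)
    root_map = _draw_roots(rng, img, params)
    mask, instances = _place_nodules(rng, img, root_map, params)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    image = RootImage(
        pixels=pixels,
        image_id=f"scene_{params.seed:08d}",
        mm_per_pixel=params.mm_per_pixel,
    )
    return Scene(image=image, mask=mask, instances=instances, params=params)


def generate_dataset(n: int, params: SceneParams, seed: int) -> list[Scene]:
    """Generate ``n`` scenes with distinct, reproducible per-scene seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) % (2**31) for s in ss.generate_state(n)]
    scenes = []
    for cs in child_seeds:
        scenes.append(generate_scene(dataclasses.replace(params, seed=cs)))
    return scenes


# ---------------------------------------------------------------------------
# Phenotype tables with the field experiment's design structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """Randomized-complete-block design with subsampling, on the log scale.

    A trait value for subsample k of treatment i in block j is

        y_ijk = mu + beta_j + alpha_i + delta_ij + eps_ijk

    with block effects beta_j ~ N(0, block_sd^2), fixed treatment effects
    alpha_i, plot-level experimental errors delta_ij ~ N(0, plot_sd^2) and
    subsample (sampling) errors eps_ijk ~ N(0, subsample_sd^2).  Values are
    reported on the natural scale, exp(y), emulating traits whose analysis
    requires a log transform.

    Defaults mirror the field layout: 3 blocks x 3 treatments x 30
    subsample plants per plot (270 rows), with block variation exceeding
    the treatment signal.
    """

    n_blocks: int = 3
    n_treatments: int = 3
    n_subsamples: int = 30
    mu: float = 3.0
    block_sd: float = 1.2
    treatment_effects: tuple[float, ...] = (0.0, 0.25, 0.6)
    plot_sd: float = 0.25
    subsample_sd: float = 0.45
    seed: int = 0
    trait_name: str = "trait"

    def validate(self) -> None:
        if self.n_blocks < 1 or self.n_treatments < 1 or self.n_subsamples < 1:
            raise ValueError("design counts must be >= 1")
        if len(self.treatment_effects) != self.n_treatments:
            raise ValueError(
                f"treatment_effects has length {len(self.treatment_effects)}, "
                f"expected n_treatments={self.n_treatments}"
            )
        for name in ("block_sd", "plot_sd", "subsample_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def generate_phenotypes(spec: DesignSpec) -> pd.DataFrame:
    """Simulate a phenotype table: one row per (block, treatment, subsample).

    Returns a DataFrame with columns ``block, treatment, plot, subsample``
    and one trait column named ``spec.trait_name`` (natural scale).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    b, t, s = spec.n_blocks, spec.n_treatments, spec.n_subsamples
    beta = rng.normal(0.0, spec.block_sd, size=b)
    delta = rng.normal(0.0, spec.plot_sd, size=(b, t))
    eps = rng.normal(0.0, spec.subsample_sd, size=(b, t, s))
    rows = []
    for j in range(b):
        for i in range(t):
            plot = f"B{j + 1}:T{i + 1}"
            for k in range(s):
                y = spec.mu + beta[j] + spec.treatment_effects[i] + delta[j, i] + eps[j, i, k]
                rows.append(
                    {
                        "block": f"B{j + 1}",
                        "treatment": f"T{i + 1}",
                        "plot": plot,
                        "subsample": k + 1,
                        spec.trait_name: float(np.exp(y)),
                    }
                )
    return pd.DataFrame(rows)
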