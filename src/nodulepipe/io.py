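"""File formats of the pipeline: paired PNGs, JSON sidecars, CSV tables.

Scenes are exchanged as ``<stem>.png`` (RGB image), ``<stem>_mask.png``
(8-bit binary mask, 0 = background, 255 = nodule foreground) and
``<stem>.json`` (ground-truth instances, seed and mm-per-pixel scale).
Phenotype and measurement tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synth import NoduleInstance, RootImage, Scene, SceneParams

__all__ = [
    "save_mask_png",
    "load_mask_png",
    "save_image_png",
    "load_image_png",
    "save_scene",
    "load_scene",
    "save_phenotypes_csv",
    "load_phenotypes_csv",
]


def save_image_png(pixels: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def load_image_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Binary mask as 8-bit PNG: foreground 255, background 0."""
    arr = np.where(np.asarray(mask) > 0, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_mask_png(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 127


def save_scene(scene: Scene, directory: str | Path, stem: str | None = None) -> Path:
    """Write image/mask/sidecar triple; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or scene.image.image_id
    save_image_png(scene.image.pixels, directory / f"{stem}.png")
    save_mask_png(scene.mask, directory / f"{stem}_mask.png")
    sidecar = {
        "image_id": scene.image.image_id,
        "mm_per_pixel": scene.params.mm_per_pixel,
        "seed": scene.params.seed,
        "true_count": scene.true_count,
        "true_total_area_mm2": scene.true_total_area_mm2,
        "instances": [
            {
                "center": list(inst.center),
                "radii": list(inst.radii),
                "rotation": inst.rotation,
                "rows": inst.rows.tolist(),
                "cols": inst.cols.tolist(),
            }
            for inst in scene.instances
        ],
        "params": {
            "image_height": scene.params.image_height,
            "image_width": scene.params.image_width,
            "n_roots": scene.params.n_roots,
            "root_width_range": list(scene.params.root_width_range),
            "n_nodules": scene.params.n_nodules,
            "nodule_radius_range": list(scene.params.nodule_radius_range),
            "overlap_fraction": scene.params.overlap_fraction,
            "min_separation": scene.params.min_separation,
            "background_noise_sd": scene.params.background_noise_sd,
            "mm_per_pixel": scene.params.mm_per_pixel,
            "seed": scene.params.seed,
        },
    }
    path = directory / f"{stem}.json"
    path.write_text(json.dumps(sidecar))
    return path


def load_scene(sidecar_path: str | Path) -> Scene:
    sidecar_path = Path(sidecar_path)
    doc = json.loads(sidecar_path.read_text())
    stem = sidecar_path.stem
    pixels = load_image_png(sidecar_path.with_name(f"{stem}.png"))
    mask = load_mask_png(sidecar_path.with_name(f"{stem}_mask.png"))
    p = doc["params"]
    params = SceneParams(
        image_height=p["image_height"],
        image_width=p["image_width"],
        n_roots=p["n_roots"],
        root_width_range=tuple(p["root_width_range"]),
        n_nodules=p["n_nodules"],
        nodule_radius_range=tuple(p["nodule_radius_range"]),
        overlap_fraction=p["overlap_fraction"],
        min_separation=p.get("min_separation", 0.0),
        background_noise_sd=p["background_noise_sd"],
        mm_per_pixel=p["mm_per_pixel"],
        seed=p["seed"],
    )
    instances = [
        NoduleInstance(
            center=tuple(d["center"]),
            radii=tuple(d["radii"]),
            rotation=d["rotation"],
            rows=np.asarray(d["rows"], dtype=np.int64),
            cols=np.asarray(d["cols"], dtype=np.int64),
        )
        for d in doc["instances"]
    ]
    image = RootImage(
        pixels=pixels, image_id=doc["image_id"], mm_per_pixel=doc["mm_per_pixel"]
    )
    return Scene(image=image, mask=mask, instances=instances, params=params)


def save_phenotypes_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def load_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
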