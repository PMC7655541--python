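"""Pixel-level segmentation evaluation and experiment harnesses.

Metrics follow the standard confusion-count definitions: precision
P = TP/(TP+FP), recall R = TP/(TP+FN) and F1 = 2PR/(P+R), where TP counts
true foreground pixels predicted foreground, FP background pixels
predicted foreground, and FN foreground pixels predicted background.
An F1 of 1.0 means the predicted and actual masks match exactly.

Zero-denominator conventions (documented and tested): a component with
TP = 0 scores P = R = F1 = 0 unless both masks are empty, in which case
the prediction is perfect and all three metrics are 1.

The harnesses reproduce, at desk scale, the two experiments that justify
the semi-automatic annotation loop: F1 as a function of training-set size
and F1 across predict -> correct -> update rounds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import segnet as sn
from .annotation import apply_corrections, mask_to_contours
from .synth import SceneParams, Scene, generate_dataset

__all__ = [
    "PixelMetrics",
    "confusion",
    "f1_score",
    "evaluate_pairs",
    "learning_curve",
    "correction_loop",
]


@dataclass(frozen=True)
class PixelMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def confusion(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int]:
    """Pixelwise (TP, FP, FN) between two binary masks of equal dims."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask dims differ: {pred.shape} vs {truth.shape}")
    p = pred > 0
    t = truth > 0
    tp = int(np.logical_and(p, t).sum())
    fp = int(np.logical_and(p, ~t).sum())
    fn = int(np.logical_and(~p, t).sum())
    return tp, fp, fn


def f1_score(tp: int, fp: int, fn: int) -> PixelMetrics:
    """Precision/recall/F1 from confusion counts, with documented conventions."""
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be >= 0")
    if tp == 0 and fp == 0 and fn == 0:
        # both masks empty: the prediction is perfect
        return PixelMetrics(tp, fp, fn, 1.0, 1.0, 1.0)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return PixelMetrics(tp, fp, fn, precision, recall, f1)


def evaluate_pairs(
    preds: list[np.ndarray],
    truths: list[np.ndarray],
    *,
    average: str = "macro",
) -> PixelMetrics | float:
    """Aggregate F1 over images.

    ``macro`` (the reported default) computes F1 per image and averages
    the scores; ``micro`` pools the confusion counts over all images
    first.  Macro returns a float; micro returns full PixelMetrics.
    """
    if len(preds) != len(truths) or not preds:
        raise ValueError("need equal-length, nonempty prediction/truth lists")
    if average == "macro":
        return float(
            np.mean([f1_score(*confusion(p, t)).f1 for p, t in zip(preds, truths)])
        )
    if average == "micro":
        tot = np.sum([confusion(p, t) for p, t in zip(preds, truths)], axis=0)
        return f1_score(int(tot[0]), int(tot[1]), int(tot[2]))
    raise ValueError("average must be 'macro' or 'micro'")


# ---------------------------------------------------------------------------
# Harnesses
# ---------------------------------------------------------------------------


def _pairs(scenes: list[Scene]) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(s.image.pixels, s.mask) for s in scenes]


def _holdout_f1(model: sn.SegModel, scenes: list[Scene], threshold: float = 0.5) -> float:
    preds = [sn.predict(model, s.image.pixels) >= threshold for s in scenes]
    return float(evaluate_pairs(preds, [s.mask for s in scenes], average="macro"))


def learning_curve(
    dataset_sizes: list[int],
    scene_params: SceneParams,
    model_config: sn.SegModelConfig,
    seeds: list[int],
    *,
    n_holdout: int = 6,
    holdout_seed: int = 987_001,
) -> pd.DataFrame:
    """Held-out F1 as a function of training-set size.

    For each seed and size a fresh model is trained from scratch on that
    many synthetic scenes; all runs are scored on one fixed held-out set.
    Returns a tidy frame (size, seed, f1) plus mean/sd per size.
    """
    if sorted(dataset_sizes) != list(dataset_sizes):
        raise ValueError("dataset_sizes must be increasing")
    if not seeds:
        raise ValueError("need at least one seed")
    holdout = generate_dataset(n_holdout, scene_params, seed=holdout_seed)
    rows = []
    for seed in seeds:
        pool = generate_dataset(max(dataset_sizes), scene_params, seed=seed)
        for size in dataset_sizes:
            cfg = dataclasses.replace(model_config, seed=model_config.seed + seed)
            model = sn.build_model(cfg)
            model, _ = sn.train(model, _pairs(pool[:size]), cfg)
            rows.append({"size": size, "seed": seed, "f1": _holdout_f1(model, holdout)})
    tidy = pd.DataFrame(rows)
    summary = (
        tidy.groupby("size")["f1"].agg(mean_f1="mean", sd_f1="std").reset_index()
    )
    return tidy.merge(summary, on="size")


def correction_loop(
    initial_n: int,
    rounds: int,
    k_corrected_per_round: int,
    scene_params: SceneParams,
    model_config: sn.SegModelConfig,
    *,
    seed: int = 0,
    n_new_per_round: int | None = None,
    n_holdout: int = 6,
    holdout_seed: int = 987_001,
    update_epochs: int | None = None,
) -> pd.DataFrame:
    """The semi-automatic annotation / transfer-learning loop at desk scale.

    Round r: predict on a batch of new scenes, score each prediction,
    oracle-correct the ``k`` worst (replace their predicted polygons with
    ground-truth polygons through the annotation layer, exactly as a human
    would through the GUI), update the model with the corrected pairs, and
    record held-out macro F1.  With ``k = 0`` no update happens and the
    recorded F1 stays constant.

    Returns a frame with one row per round: (round, f1, n_train_pairs);
    round 0 is the freshly trained model before any correction.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if n_new_per_round is None:
        n_new_per_round = max(2 * k_corrected_per_round, 2)
    holdout = generate_dataset(n_holdout, scene_params, seed=holdout_seed)
    cfg = dataclasses.replace(model_config, seed=model_config.seed + seed)
    model = sn.build_model(cfg)
    model, _ = sn.train(model, _pairs(generate_dataset(initial_n, scene_params, seed=seed)), cfg)
    upd_cfg = (
        dataclasses.replace(cfg, epochs=update_epochs) if update_epochs else cfg
    )
    rows = [
        {
            "round": 0,
            "f1": _holdout_f1(model, holdout),
            "n_train_pairs": len(model.train_pairs),
        }
    ]
    for rnd in range(1, rounds + 1):
        batch = generate_dataset(n_new_per_round, scene_params, seed=seed + 10_000 * rnd)
        if k_corrected_per_round > 0:
            scored = []
            for s in batch:
                pred = sn.predict(model, s.image.pixels) >= 0.5
                m = f1_score(*confusion(pred, s.mask))
                scored.append((m.f1, s, pred))
            scored.sort(key=lambda t: t[0])
            corrected_pairs = []
            for _, s, pred in scored[:k_corrected_per_round]:
                # oracle corrector: add missed ground-truth outlines, remove
                # the false-positive regions (removal wins on conflict, so
                # only the spurious area may be deleted)
                add = mask_to_contours(s.mask, s.image.image_id, provenance="corrected")
                remove = mask_to_contours(pred & ~s.mask, s.image.image_id)
                corrected = apply_corrections(pred, add=add, remove=remove)
                corrected_pairs.append((s.image.pixels, corrected))
            model, _ = sn.update(model, corrected_pairs, upd_cfg)
        rows.append(
            {
                "round": rnd,
                "f1": _holdout_f1(model, holdout),
                "n_train_pairs": len(model.train_pairs),
            }
        )
    return pd.DataFrame(rows)
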