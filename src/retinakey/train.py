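"""Training loop and the scaled-down experimental protocol.

Training follows the reference optimisation regime: plain stochastic gradient
descent with momentum 0.9, weight decay 1e-3 and batch size 1 — one image pair
per step, the same network weights applied to both images (siamese).  The
location losses supervise the probability map against disk targets around the
ground-truth keypoints; the matching loss reads embeddings from the embedding
maps at the ground-truth keypoint locations (bilinear interpolation).

``run_protocol`` is the end-to-end study unit used by the tests and the
benchmark harness: generate a synthetic dataset, train a small model, and
measure loss reduction, detection F1, matching precision and registration AUC
on held-out pairs against the untrained initialisation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .evaluation import evaluate_model
from .losses import (build_pair_sets, keypoint_target_mask,
                     sample_embeddings_at, total_loss)
from .network import KeypointNet, ModelConfig
from .nn import SGD
from .registration import register_pair
from .synth import ImagePairSample, generate_dataset

__all__ = ["TrainConfig", "train", "run_protocol", "detection_scores",
           "matching_precision"]


@dataclass
class TrainConfig:
    """Optimisation settings (batch size is fixed at 1 image pair)."""

    learning_rate: float = 0.02
    momentum: float = 0.9
    weight_decay: float = 1e-3
    iterations: int = 300
    seed: int = 0
    margin: float = 1.0
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    match_loss: str = "structured"
    mask_radius: float = 2.0
    exclusion_radius: float = 0.0
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if self.learning_rate <= 0 or self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")


def _pair_targets(sample: ImagePairSample, radius: float):
    yf = keypoint_target_mask(sample.fixed_keypoints.points,
                              sample.fixed_image.shape[:2], radius)
    ym = keypoint_target_mask(sample.moving_keypoints.points,
                              sample.moving_image.shape[:2], radius)
    return yf, ym


def train_step(model: KeypointNet, optimizer: SGD, sample: ImagePairSample,
               config: TrainConfig, targets=None) -> dict[str, float]:
    """One SGD step on one image pair; returns the loss breakdown."""
    yf, ym = targets if targets is not None else _pair_targets(sample, config.mask_radius)
    out_f = model(sample.fixed_image)
    out_m = model(sample.moving_image)
    emb_f = sample_embeddings_at(out_f.embedding_map, sample.fixed_keypoints.points)
    emb_m = sample_embeddings_at(out_m.embedding_map, sample.moving_keypoints.points)
    pair_sets = build_pair_sets(sample.gt_matches, sample.fixed_keypoints.points,
                                sample.moving_keypoints.points,
                                exclusion_radius=config.exclusion_radius,
                                margin=config.margin)
    loss, breakdown = total_loss((out_f.prob_map, out_m.prob_map), (yf, ym),
                                 emb_f, emb_m, pair_sets,
                                 weights=config.loss_weights,
                                 match_kind=config.match_loss)
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return breakdown


def train(config: TrainConfig, samples: list[ImagePairSample],
          model: KeypointNet | None = None, log_path=None
          ) -> tuple[KeypointNet, pd.DataFrame]:
    """Train a model on in-memory samples; returns it with the per-iteration
    loss log (written as CSV when ``log_path`` is given)."""
    if not samples:
        raise ValueError("no training samples")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = KeypointNet(config.model, seed=int(rng.integers(2 ** 31)))
    model.train()
    optimizer = SGD(model.parameters(), lr=config.learning_rate,
                    momentum=config.momentum, weight_decay=config.weight_decay)
    targets = [_pair_targets(s, config.mask_radius) for s in samples]
    rows = []
    for it in range(config.iterations):
        k = int(rng.integers(len(samples)))
        breakdown = train_step(model, optimizer, samples[k], config, targets[k])
        breakdown["iteration"] = it
        rows.append(breakdown)
    log = pd.DataFrame(rows)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    model.eval()
    return model, log


# ------------------------------------------------------------------ metrics
def detection_scores(model: KeypointNet, samples, tol: float = 3.0,
                     threshold: float = 0.5, min_separation: float = 2.0
                     ) -> dict[str, float]:
    """Precision/recall/F1 of detected vs ground-truth keypoints.

    A detection is a true positive if it lies within ``tol`` px of an unclaimed
    ground-truth keypoint (greedy nearest-first assignment); both images of
    every pair are scored.
    """
    tp = fp = fn = 0
    for s in samples:
        for image, kps in ((s.fixed_image, s.fixed_keypoints),
                           (s.moving_image, s.moving_keypoints)):
            out = model(image)
            from .registration import extract_keypoints
            det = extract_keypoints(out.prob_map.data, threshold, min_separation)
            gt = np.asarray(kps.points).reshape(-1, 2)
            matched = _greedy_match(det.points, gt, tol)
            tp += len(matched)
            fp += len(det.points) - len(matched)
            fn += len(gt) - len(matched)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn}


def _greedy_match(det: np.ndarray, gt: np.ndarray, tol: float) -> list[tuple[int, int]]:
    det = np.asarray(det).reshape(-1, 2)
    gt = np.asarray(gt).reshape(-1, 2)
    if len(det) == 0 or len(gt) == 0:
        return []
    D = cdist(det, gt)
    pairs = []
    used_d: set[int] = set()
    used_g: set[int] = set()
    for flat in np.argsort(D, axis=None):
        i, j = np.unravel_index(flat, D.shape)
        if D[i, j] > tol:
            break
        if i in used_d or j in used_g:
            continue
        used_d.add(i)
        used_g.add(j)
        pairs.append((int(i), int(j)))
    return pairs


def matching_precision(model: KeypointNet, samples, tol: float = 3.0,
                       threshold: float = 0.5, min_separation: float = 2.0,
                       max_distance: float = np.inf) -> float:
    """Fraction of predicted correspondences that agree with ground truth,
    restricted to matches whose two endpoints were each correctly detected
    (within ``tol`` px of some ground-truth keypoint)."""
    correct = considered = 0
    for s in samples:
        kps_f, kps_m, matches, _ = register_pair(
            s.fixed_image, s.moving_image, model, threshold=threshold,
            min_separation=min_separation, max_distance=max_distance,
        )
        gt_f = np.asarray(s.fixed_keypoints.points).reshape(-1, 2)
        gt_m = np.asarray(s.moving_keypoints.points).reshape(-1, 2)
        assign_f = dict(_greedy_match(kps_f.points, gt_f, tol))
        assign_m = dict(_greedy_match(kps_m.points, gt_m, tol))
        gt_pairs = {(int(i), int(j)) for i, j in s.gt_matches}
        for i, j, _ in matches.pairs:
            if i not in assign_f or j not in assign_m:
                continue  # an endpoint is not a correctly detected keypoint
            considered += 1
            if (assign_f[i], assign_m[j]) in gt_pairs:
                correct += 1
    return correct / considered if considered else 0.0


# ------------------------------------------------------------------ protocol
def run_protocol(context_mode: str = "sapca", match_loss: str = "structured",
                 learning_rate: float = 0.02,
                 dataset_seed: int = 0, seed: int = 0, n_pairs: int = 20,
                 n_heldout: int = 5, train_steps: int = 300,
                 canvas_size: int = 64, num_levels: int = 2,
                 base_channels: int = 8, embedding_dim: int = 32,
                 t_max: float = 25.0, transform_model: str = "similarity",
                 robust: bool = True, quality: str = "high",
                 dtype: str = "float32") -> dict:
    """The scaled-down end-to-end study unit.

    Generates ``n_pairs + n_heldout`` synthetic pairs (shared across
    configurations through ``dataset_seed``), trains a small model for
    ``train_steps`` SGD iterations, and evaluates on the held-out pairs:
    loss reduction, detection F1, matching precision among correctly detected
    keypoints, and registration AUC for the trained and untrained model.
    """
    from .autodiff import default_dtype, set_default_dtype

    data = generate_dataset(n_pairs + n_heldout, canvas_size=canvas_size,
                            quality=quality, seed=dataset_seed)
    train_set, heldout = data[:n_pairs], data[n_pairs:]
    cfg = TrainConfig(
        iterations=train_steps, seed=seed, match_loss=match_loss,
        learning_rate=learning_rate,
        model=ModelConfig(num_levels=num_levels, base_channels=base_channels,
                          embedding_dim=embedding_dim, context_mode=context_mode),
    )
    rng = np.random.default_rng(seed)
    old_dtype = default_dtype()
    set_default_dtype(dtype)
    try:
        init_model = KeypointNet(cfg.model, seed=int(rng.integers(2 ** 31)))
        untrained = copy.deepcopy(init_model)
        reg_kwargs = dict(transform_model=transform_model, robust=robust)
        model, log = train(cfg, train_set, model=init_model)
        k = max(1, min(10, len(log) // 10))
        loss_initial = float(log["total"].iloc[:k].mean())
        loss_final = float(log["total"].iloc[-k:].mean())
        det = detection_scores(model, heldout)
        prec = matching_precision(model, heldout)
        curve_trained, _ = evaluate_model(model, heldout, t_max=t_max, **reg_kwargs)
        curve_untrained, _ = evaluate_model(untrained, heldout, t_max=t_max,
                                            **reg_kwargs)
    finally:
        set_default_dtype(old_dtype)
    return {
        "loss_initial": loss_initial,
        "loss_final": loss_final,
        "loss_reduction": 1.0 - loss_final / loss_initial if loss_initial else 0.0,
        "detection_f1": det["f1"],
        "detection_precision": det["precision"],
        "detection_recall": det["recall"],
        "matching_precision": prec,
        "auc_trained": curve_trained.auc,
        "auc_untrained": curve_untrained.auc,
        "curve_trained": curve_trained,
        "curve_untrained": curve_untrained,
        "log": log,
    }
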