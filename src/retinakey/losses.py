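"""Keypoint location and matching losses.

Location losses treat keypoint detection as pixel-level binary classification:
mean binary cross-entropy plus a Dice overlap loss against a disk-shaped
target mask around each ground-truth keypoint.

Matching losses act on per-keypoint embedding vectors compared by Euclidean
distance: a pair-wise (contrastive) ranking loss, a triplet ranking loss, and
a structured triplet ranking loss that, for every positive pair, pushes both
anchors away from *all* their negatives through a log-sum-exp:

    L = 1/(2|P|) * sum over positives (i, j) of
        [ d(f_i, f_j) + log( sum over negatives p of i: exp(m - d(f_i, f_p))
                           + sum over negatives l of j: exp(m - d(f_j, f_l)) ) ]_+
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, bilinear_sample, concat, logsumexp

__all__ = [
    "PairSets",
    "keypoint_target_mask",
    "cross_entropy_loss",
    "dice_loss",
    "euclidean_distance",
    "pairwise_ranking_loss",
    "triplet_ranking_loss",
    "structured_triplet_loss",
    "build_pair_sets",
    "sample_embeddings_at",
    "matching_loss",
    "total_loss",
]

_EPS_PROB = 1e-7
_EPS_DIST = 1e-16


@dataclass
class PairSets:
    """Positive matches and per-anchor negatives for one image pair.

    positives: (i, j) index pairs — fixed keypoint i matches moving keypoint j.
    negatives_fixed: (i, k) pairs — fixed anchor i vs non-matching moving k.
    negatives_moving: (j, k) pairs — moving anchor j vs non-matching fixed k.
    """

    positives: list[tuple[int, int]] = field(default_factory=list)
    negatives_fixed: list[tuple[int, int]] = field(default_factory=list)
    negatives_moving: list[tuple[int, int]] = field(default_factory=list)
    margin: float = 1.0

    @property
    def num_negatives(self) -> int:
        return len(self.negatives_fixed) + len(self.negatives_moving)


# ----------------------------------------------------------------- location
def keypoint_target_mask(points: np.ndarray, shape: tuple[int, int],
                         radius: float = 2.0) -> np.ndarray:
    """Binary (H, W) mask: 1 within ``radius`` pixels of any keypoint.

    ``points`` holds (x, y) coordinates; radius 0 marks the single nearest
    pixel (rounded coordinate).
    """
    H, W = shape
    mask = np.zeros((H, W), dtype=np.float64)
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    if pts.size == 0:
        return mask
    if radius <= 0:
        for x, y in pts:
            r, c = int(round(y)), int(round(x))
            if 0 <= r < H and 0 <= c < W:
                mask[r, c] = 1.0
        return mask
    yy, xx = np.mgrid[0:H, 0:W]
    for x, y in pts:
        mask[(xx - x) ** 2 + (yy - y) ** 2 <= radius ** 2] = 1.0
    return mask


def cross_entropy_loss(P, Y) -> Tensor:
    """Mean per-pixel binary cross-entropy; predictions clipped to
    [1e-7, 1 - 1e-7]."""
    P, Y = as_tensor(P), as_tensor(Y)
    if P.shape != Y.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {Y.shape}")
    p = P.clip(_EPS_PROB, 1.0 - _EPS_PROB)
    return -(Y * p.log() + (1.0 - Y) * (1.0 - p).log()).mean()


def dice_loss(P, Y, smooth: float = 1.0) -> Tensor:
    """1 - 2|P.Y| / (|P| + |Y|), with an additive smoothing constant guarding
    empty masks."""
    P, Y = as_tensor(P), as_tensor(Y)
    if P.shape != Y.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {Y.shape}")
    inter = (P * Y).sum()
    denom = P.sum() + Y.sum()
    return 1.0 - (inter * 2.0 + smooth) / (denom + smooth)


# ----------------------------------------------------------------- matching
def euclidean_distance(a: Tensor, b: Tensor) -> Tensor:
    """Euclidean distance between two embedding vectors (differentiable)."""
    d = as_tensor(a) - as_tensor(b)
    return ((d * d).sum() + _EPS_DIST) ** 0.5


def _distance_matrix(A: Tensor, B: Tensor) -> Tensor:
    """Pairwise Euclidean distances between rows of A (n, D) and B (m, D)."""
    a2 = (A * A).sum(axis=1, keepdims=True)  # (n, 1)
    b2 = (B * B).sum(axis=1, keepdims=True)  # (m, 1)
    cross = A @ B.T  # (n, m)
    sq = a2 + b2.T - cross * 2.0
    return (sq.clip(0.0, np.inf) + _EPS_DIST) ** 0.5


def pairwise_ranking_loss(f_a, f_other, is_positive: bool, margin: float = 1.0) -> Tensor:
    """Contrastive loss: d(a, p) for positives, hinge max(0, m - d(a, n))
    for negatives."""
    d = euclidean_distance(f_a, f_other)
    if is_positive:
        return d
    return (margin - d).relu()


def triplet_ranking_loss(f_a, f_p, f_n, margin: float = 1.0) -> Tensor:
    """max(0, m + d(a, p) - d(a, n))."""
    return (euclidean_distance(f_a, f_p) - euclidean_distance(f_a, f_n) + margin).relu()


def structured_triplet_loss(emb_fixed: Tensor, emb_moving: Tensor,
                            pair_sets: PairSets) -> Tensor:
    """Structured triplet ranking loss over all positives and their negative
    sets (stable log-sum-exp; hinged per positive pair)."""
    if not pair_sets.positives:
        warnings.warn("structured_triplet_loss: empty positive set, loss is 0")
        return Tensor(0.0)
    A, B = as_tensor(emb_fixed), as_tensor(emb_moving)
    m = pair_sets.margin
    D_ab = _distance_matrix(A, B)
    neg_f: dict[int, list[int]] = {}
    for i, k in pair_sets.negatives_fixed:
        neg_f.setdefault(i, []).append(k)
    neg_m: dict[int, list[int]] = {}
    for j, k in pair_sets.negatives_moving:
        neg_m.setdefault(j, []).append(k)
    total = Tensor(0.0)
    for i, j in pair_sets.positives:
        scores = []
        ks = neg_f.get(i, [])
        if ks:
            scores.append(m - D_ab[i, np.asarray(ks)])
        ls = neg_m.get(j, [])
        if ls:
            scores.append(m - D_ab[np.asarray(ls), j])
        if not scores:
            # no negatives for this positive: only the attractive term remains
            term = D_ab[i, j].reshape(())
        else:
            term = D_ab[i, j].reshape(()) + logsumexp(concat(scores, axis=0))
        total = total + term.relu()
    return total / (2.0 * len(pair_sets.positives))


def build_pair_sets(gt_matches, fixed_points, moving_points,
                    exclusion_radius: float = 0.0, margin: float = 1.0) -> PairSets:
    """Construct positives and per-anchor negatives from ground truth.

    Positives are the ground-truth match index pairs.  For a fixed anchor i
    matched to moving j, every other moving keypoint k is a negative unless
    its ground-truth location lies within ``exclusion_radius`` of j's (which
    would make the pair ambiguous); symmetrically for moving anchors.
    """
    fixed_points = np.asarray(fixed_points, dtype=np.float64).reshape(-1, 2)
    moving_points = np.asarray(moving_points, dtype=np.float64).reshape(-1, 2)
    ps = PairSets(margin=margin)
    ps.positives = [(int(i), int(j)) for i, j in gt_matches]
    for i, j in ps.positives:
        for k in range(len(moving_points)):
            if k == j:
                continue
            if exclusion_radius > 0 and np.hypot(
                *(moving_points[k] - moving_points[j])
            ) < exclusion_radius:
                continue
            ps.negatives_fixed.append((i, k))
        for k in range(len(fixed_points)):
            if k == i:
                continue
            if exclusion_radius > 0 and np.hypot(
                *(fixed_points[k] - fixed_points[i])
            ) < exclusion_radius:
                continue
            ps.negatives_moving.append((j, k))
    return ps


def sample_embeddings_at(embedding_map: Tensor, points: np.ndarray) -> Tensor:
    """Bilinearly sample the (D, H, W) embedding map at (x, y) keypoints,
    returning an (n, D) embedding matrix (differentiable w.r.t. the map)."""
    return bilinear_sample(embedding_map, points)


def matching_loss(emb_fixed: Tensor, emb_moving: Tensor, pair_sets: PairSets,
                  kind: str = "structured") -> Tensor:
    """Dispatch the configured matching loss over a pair's embedding sets.

    'pairwise' averages the contrastive loss over all positive and negative
    pairs; 'triplet' averages the triplet loss over every (positive, negative)
    combination sharing an anchor; 'structured' is the structured triplet
    ranking loss.
    """
    if kind == "structured":
        return structured_triplet_loss(emb_fixed, emb_moving, pair_sets)
    A, B = as_tensor(emb_fixed), as_tensor(emb_moving)
    m = pair_sets.margin
    D_ab = _distance_matrix(A, B)
    if kind == "pairwise":
        terms = []
        for i, j in pair_sets.positives:
            terms.append(D_ab[i, j].reshape(()))
        for i, k in pair_sets.negatives_fixed:
            terms.append((m - D_ab[i, k].reshape(())).relu())
        for j, k in pair_sets.negatives_moving:
            terms.append((m - D_ab[k, j].reshape(())).relu())
        if not terms:
            return Tensor(0.0)
        return sum(terms[1:], terms[0]) / float(len(terms))
    if kind == "triplet":
        neg_f: dict[int, list[int]] = {}
        for i, k in pair_sets.negatives_fixed:
            neg_f.setdefault(i, []).append(k)
        neg_m: dict[int, list[int]] = {}
        for j, k in pair_sets.negatives_moving:
            neg_m.setdefault(j, []).append(k)
        terms = []
        for i, j in pair_sets.positives:
            d_pos = D_ab[i, j].reshape(())
            for k in neg_f.get(i, []):
                terms.append((d_pos - D_ab[i, k].reshape(()) + m).relu())
            for k in neg_m.get(j, []):
                terms.append((d_pos - D_ab[np.asarray([k]), j].reshape(()) + m).relu())
        if not terms:
            return Tensor(0.0)
        return sum(terms[1:], terms[0]) / float(len(terms))
    raise ValueError(f"unknown matching loss kind {kind!r}")


def total_loss(prob_maps, target_masks, emb_fixed, emb_moving, pair_sets: PairSets,
               weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
               match_kind: str = "structured") -> tuple[Tensor, dict[str, float]]:
    """Weighted sum w_ce*CE + w_dice*Dice + w_match*Match over an image pair.

    ``prob_maps`` / ``target_masks`` are sequences (one entry per image of the
    pair).  Returns the scalar loss tensor and a per-term float breakdown.
    """
    w_ce, w_dice, w_match = weights
    ce = sum((cross_entropy_loss(p, y) for p, y in zip(prob_maps, target_masks)),
             Tensor(0.0)) / float(len(prob_maps))
    dce = sum((dice_loss(p, y) for p, y in zip(prob_maps, target_masks)),
              Tensor(0.0)) / float(len(prob_maps))
    match = matching_loss(emb_fixed, emb_moving, pair_sets, kind=match_kind)
    loss = ce * w_ce + dce * w_dice + match * w_match
    breakdown = {
        "cross_entropy": float(ce.data),
        "dice": float(dce.data),
        "matching": float(match.data),
        "total": float(loss.data),
    }
    return loss, breakdown
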