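"""Inference pipeline: decode keypoints, match embeddings, fit the transform.

The trained network gives each image a keypoint probability map and a dense
embedding map.  Registration proceeds by decoding probability peaks into
sub-pixel keypoints, bilinearly sampling the embedding map at each keypoint,
matching keypoints
across the pair by mutual nearest neighbours in embedding space, and fitting a
geometric transform to the matched coordinates by (optionally robust) least
squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max
from skimage.measure import ransac
from skimage.transform import (AffineTransform, ProjectiveTransform,
                               SimilarityTransform)

from .network import KeypointNet, load_checkpoint
from .synth import KeypointSet, merge_close_points

__all__ = [
    "MatchSet",
    "Transform",
    "RegistrationFailure",
    "TooFewMatchesError",
    "DegenerateTransformError",
    "extract_keypoints",
    "sample_embeddings",
    "match_embeddings",
    "estimate_transform",
    "register_pair",
]

_MIN_CORRESPONDENCES = {"similarity": 2, "affine": 3, "homography": 4}
_TFORM_CLS = {
    "similarity": SimilarityTransform,
    "affine": AffineTransform,
    "homography": ProjectiveTransform,
}


class TooFewMatchesError(RuntimeError):
    """Not enough correspondences to determine the transform."""


class DegenerateTransformError(RuntimeError):
    """The correspondence configuration does not determine the model
    (e.g. collinear points for a homography)."""


@dataclass
class MatchSet:
    """One-to-one cross-image correspondences with embedding distances."""

    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    method: str = "mutual_nn"

    def __len__(self) -> int:
        return len(self.pairs)

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
        arr = np.array([(i, j) for i, j, _ in self.pairs], dtype=int)
        return arr[:, 0], arr[:, 1]


@dataclass
class Transform:
    model: str
    matrix: np.ndarray  # 3x3, bottom-right normalised to 1
    inlier_mask: np.ndarray | None = None

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
        hom = np.hstack([pts, np.ones((len(pts), 1))]) @ self.matrix.T
        return hom[:, :2] / hom[:, 2:3]


@dataclass
class RegistrationFailure:
    reason: str


def extract_keypoints(prob_map: np.ndarray, threshold: float = 0.5,
                      min_separation: float = 2.0) -> KeypointSet:
    """Decode a probability map into sub-pixel keypoints.

    Local maxima above ``threshold`` (non-maximum suppression radius
    ``min_separation``) are refined to probability-weighted centroids over a
    5x5 window of supra-threshold pixels; refined points closer than
    ``min_separation`` are merged.  Peak decoding (rather than connected
    components) keeps adjacent keypoints separate: annotations guarantee a
    3 px spacing, so the suppression radius defaults just below it.
    """
    pm = np.asarray(prob_map, dtype=np.float64)
    peaks = peak_local_max(pm, min_distance=max(1, int(np.ceil(min_separation))),
                           threshold_abs=threshold, exclude_border=False)
    if len(peaks) == 0:
        return KeypointSet(points=np.zeros((0, 2)), labels=[])
    H, W = pm.shape
    pts = []
    for y, x in peaks:
        y0, y1 = max(0, y - 2), min(H, y + 3)
        x0, x1 = max(0, x - 2), min(W, x + 3)
        w = pm[y0:y1, x0:x1].copy()
        w[w < threshold] = 0.0
        yy, xx = np.mgrid[y0:y1, x0:x1]
        pts.append(((w * xx).sum() / w.sum(), (w * yy).sum() / w.sum()))
    pts, labs = merge_close_points(np.array(pts), ["detected"] * len(pts),
                                   min_separation)
    return KeypointSet(points=pts, labels=labs)


def sample_embeddings(embedding_map: np.ndarray, keypoints: KeypointSet) -> np.ndarray:
    """Bilinearly interpolate the (D, H, W) embedding map at each (x, y)
    keypoint; returns an (n, D) array.  Out-of-bounds keypoints raise."""
    emb = np.asarray(embedding_map, dtype=np.float64)
    D, H, W = emb.shape
    pts = np.asarray(keypoints.points, dtype=np.float64).reshape(-1, 2)
    if len(pts) == 0:
        return np.zeros((0, D))
    xs, ys = pts[:, 0], pts[:, 1]
    if xs.min() < 0 or xs.max() > W - 1 or ys.min() < 0 or ys.max() > H - 1:
        raise ValueError("keypoint outside embedding map bounds")
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    fx = (xs - x0)[None, :]
    fy = (ys - y0)[None, :]
    out = (
        emb[:, y0, x0] * (1 - fx) * (1 - fy)
        + emb[:, y0, x1] * fx * (1 - fy)
        + emb[:, y1, x0] * (1 - fx) * fy
        + emb[:, y1, x1] * fx * fy
    )
    return out.T


def match_embeddings(emb_fixed: np.ndarray, emb_moving: np.ndarray,
                     max_distance: float = np.inf) -> MatchSet:
    """Mutual nearest neighbours under Euclidean distance, filtered by an
    absolute distance cutoff; one-to-one by construction."""
    ms = MatchSet()
    if len(emb_fixed) == 0 or len(emb_moving) == 0:
        return ms
    D = cdist(emb_fixed, emb_moving)
    nn_fm = D.argmin(axis=1)
    nn_mf = D.argmin(axis=0)
    for i, j in enumerate(nn_fm):
        if nn_mf[j] == i and D[i, j] <= max_distance:
            ms.pairs.append((int(i), int(j), float(D[i, j])))
    return ms


def estimate_transform(matches: MatchSet, fixed_kps: KeypointSet,
                       moving_kps: KeypointSet, model: str = "homography",
                       robust: bool = False, inlier_threshold: float = 3.0,
                       rng: np.random.Generator | int | None = 0) -> Transform:
    """Least-squares fit of the fixed->moving transform to matched keypoints.

    The homography uses the normalised direct linear transform.  With
    ``robust`` a random-consensus loop discards outlier matches before the
    final fit.
    """
    if model not in _TFORM_CLS:
        raise ValueError(f"unknown transform model {model!r}")
    need = _MIN_CORRESPONDENCES[model]
    fi, mi = matches.indices()
    if len(fi) < need:
        raise TooFewMatchesError(
            f"{model} needs >= {need} correspondences, got {len(fi)}"
        )
    src = np.asarray(fixed_kps.points, dtype=np.float64)[fi]
    dst = np.asarray(moving_kps.points, dtype=np.float64)[mi]
    cls = _TFORM_CLS[model]
    inliers = None
    if robust and len(src) > need:
        try:
            tf, inliers = ransac(
                (src, dst), cls, min_samples=need,
                residual_threshold=inlier_threshold, max_trials=200,
                rng=rng,
            )
        except Exception as exc:
            raise DegenerateTransformError(str(exc)) from exc
        if tf is None or inliers is None or inliers.sum() < need:
            raise DegenerateTransformError("consensus failed to find a model")
        tf = cls.from_estimate(src[inliers], dst[inliers])
        if not tf:
            raise DegenerateTransformError("degenerate inlier configuration")
    else:
        tf = cls.from_estimate(src, dst)
        if not tf:
            raise DegenerateTransformError("degenerate correspondence configuration")
    M = np.asarray(tf.params, dtype=np.float64)
    if not np.all(np.isfinite(M)) or abs(M[2, 2]) < 1e-12 or \
            abs(np.linalg.det(M)) < 1e-12:
        raise DegenerateTransformError("estimated matrix is singular")
    M = M / M[2, 2]
    return Transform(model=model, matrix=M, inlier_mask=inliers)


def register_pair(image_fixed: np.ndarray, image_moving: np.ndarray,
                  model: KeypointNet | str, threshold: float = 0.5,
                  min_separation: float = 2.0, max_distance: float = np.inf,
                  transform_model: str = "homography", robust: bool = False,
                  inlier_threshold: float = 3.0, rng=0):
    """End-to-end registration of one image pair.

    Returns ``(fixed_kps, moving_kps, match_set, transform_or_failure)``;
    an unregistrable pair yields a :class:`RegistrationFailure` record rather
    than raising.
    """
    if isinstance(model, (str,)) or hasattr(model, "__fspath__"):
        model = load_checkpoint(model)
    model.eval()
    out_f = model(image_fixed)
    out_m = model(image_moving)
    kps_f = extract_keypoints(out_f.prob_map.data, threshold, min_separation)
    kps_m = extract_keypoints(out_m.prob_map.data, threshold, min_separation)
    emb_f = sample_embeddings(out_f.embedding_map.data, kps_f)
    emb_m = sample_embeddings(out_m.embedding_map.data, kps_m)
    matches = match_embeddings(emb_f, emb_m, max_distance)
    try:
        tform = estimate_transform(matches, kps_f, kps_m, transform_model,
                                   robust=robust,
                                   inlier_threshold=inlier_threshold, rng=rng)
    except TooFewMatchesError:
        tform = RegistrationFailure(reason="too few matches")
    except DegenerateTransformError as exc:
        tform = RegistrationFailure(reason=f"degenerate: {exc}")
    return kps_f, kps_m, matches, tform
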