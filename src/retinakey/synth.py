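"""Synthetic fundus-like image pairs with ground-truth keypoints.

Real training data for this task consists of fundus photographs whose vessel
branching and crossing points are annotated, with image pairs taken under
different angles and lighting.  This module emulates that *structure*: random
binary-branching vessel trees are rendered as dark anti-aliased curvilinear
strokes on a bright textured disc; every degree->=3 tree node is a "branching"
keypoint and every stroke intersection between distinct trees a "crossing"
keypoint; the second image of a pair is a known geometric warp of the first
plus photometric perturbation.  Two quality presets mirror a mild
(adult-camera-like) and a harsh (neonatal-camera-like) imaging condition.

Coordinates are continuous and 0-based with x = column (rightward) and
y = row (downward); homographies act on homogeneous (x, y, 1) columns and map
fixed-image coordinates to moving-image coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import ProjectiveTransform, warp

__all__ = [
    "InvalidParameterError",
    "GrowthParams",
    "PhotometricParams",
    "TransformSpec",
    "VesselTree",
    "KeypointSet",
    "ImagePairSample",
    "HIGH_QUALITY",
    "LOW_QUALITY",
    "generate_tree",
    "rasterize_and_annotate",
    "make_pair",
    "generate_sample",
    "generate_dataset",
    "apply_homography",
    "overlap_fraction",
]


class InvalidParameterError(ValueError):
    """A generator parameter is outside its documented domain."""


# --------------------------------------------------------------------- types
@dataclass
class GrowthParams:
    """Stochastic vessel-tree growth settings (units: pixels, degrees)."""

    branch_prob: float = 0.4
    branch_angle_range: tuple[float, float] = (25.0, 55.0)
    segment_length_range: tuple[float, float] = (6.0, 12.0)
    initial_radius: float = 1.6
    radius_decay: float = 0.9
    max_depth: int = 6
    direction_jitter: float = 12.0  # degrees, per segment


@dataclass
class PhotometricParams:
    """Rendering and perturbation settings for one quality regime."""

    texture_amplitude: float = 8.0
    vessel_contrast: float = 0.65
    illumination_strength: float = 15.0
    noise_sigma: float = 2.0
    gamma: float = 1.0
    blur_sigma: float = 0.5
    # pair-perturbation ranges (applied to the moving image)
    brightness_jitter: float = 8.0
    contrast_jitter: float = 0.08
    gamma_jitter: float = 0.08


HIGH_QUALITY = PhotometricParams()
LOW_QUALITY = PhotometricParams(
    texture_amplitude=14.0, vessel_contrast=0.5, illumination_strength=35.0,
    noise_sigma=5.0, blur_sigma=1.0, brightness_jitter=15.0,
    contrast_jitter=0.15, gamma_jitter=0.15,
)


@dataclass
class TransformSpec:
    """Family and parameter ranges of the fixed->moving geometric transform.

    kind: identity | translation | similarity | affine | homography.
    Ranges are symmetric: rotation in +-rotation_deg, translation components in
    +-translation_frac * canvas, log-scale in +-log(scale_span), affine shear
    entries in +-shear, projective entries in +-perspective.
    """

    kind: str = "similarity"
    rotation_deg: float = 15.0
    translation_frac: float = 0.10
    scale_span: float = 1.1
    shear: float = 0.08
    perspective: float = 1e-4

    def sample(self, rng: np.random.Generator, canvas_size: int) -> np.ndarray:
        if self.kind not in ("identity", "translation", "similarity", "affine",
                             "homography"):
            raise InvalidParameterError(f"unknown transform kind {self.kind!r}")
        H = np.eye(3)
        c = (canvas_size - 1) / 2.0
        if self.kind == "identity":
            return H
        tx, ty = rng.uniform(-1, 1, 2) * self.translation_frac * canvas_size
        if self.kind == "translation":
            H[0, 2], H[1, 2] = tx, ty
            return H
        theta = np.deg2rad(rng.uniform(-self.rotation_deg, self.rotation_deg))
        scale = np.exp(rng.uniform(-np.log(self.scale_span), np.log(self.scale_span)))
        A = scale * np.array([[np.cos(theta), -np.sin(theta)],
                              [np.sin(theta), np.cos(theta)]])
        if self.kind in ("affine", "homography"):
            A = A @ (np.eye(2) + rng.uniform(-self.shear, self.shear, (2, 2)))
        # rotate/scale about the canvas centre, then translate
        H[:2, :2] = A
        H[:2, 2] = np.array([c, c]) - A @ np.array([c, c]) + [tx, ty]
        if self.kind == "homography":
            H[2, :2] = rng.uniform(-self.perspective, self.perspective, 2)
        if abs(np.linalg.det(H)) < 1e-8:
            raise InvalidParameterError("sampled transform is degenerate")
        return H


@dataclass
class VesselTree:
    """Acyclic vessel skeleton: node coordinates and radius-carrying edges."""

    nodes: np.ndarray  # (n, 2) continuous (x, y)
    edges: list[tuple[int, int, float]]  # (parent, child, radius)
    tree_id: int = 0

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=int)
        for a, b, _ in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def branching_nodes(self) -> np.ndarray:
        deg = self.degrees()
        return np.flatnonzero(deg >= 3)


@dataclass
class KeypointSet:
    """Sub-pixel keypoints with class labels."""

    points: np.ndarray  # (n, 2) of (x, y)
    labels: list[str] = field(default_factory=list)  # 'branching' | 'crossing'

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ImagePairSample:
    fixed_image: np.ndarray
    moving_image: np.ndarray
    gt_transform: np.ndarray  # 3x3, maps fixed (x, y, 1) -> moving
    fixed_keypoints: KeypointSet
    moving_keypoints: KeypointSet
    gt_matches: list[tuple[int, int]]
    overlap_fraction: float
    quality_tag: str = "high"


# ----------------------------------------------------------------- tree growth
def generate_tree(canvas_size: int, growth_params: GrowthParams | None = None,
                  seed: int = 0, tree_id: int = 0,
                  root: tuple[float, float] | None = None,
                  initial_direction_deg: float | None = None) -> VesselTree:
    """Grow one seeded random binary-branching vessel tree on the canvas.

    The root sits near the canvas border with the initial direction pointing
    inward (like vessels radiating from the optic disc); growth stops at the
    canvas edge, at ``max_depth``, or when the radius decays below 0.4 px.
    """
    if canvas_size < 32:
        raise InvalidParameterError("canvas_size must be >= 32")
    gp = growth_params or GrowthParams()
    rng = np.random.default_rng(seed)
    margin = max(2.0, gp.initial_radius)
    if root is None:
        side = rng.uniform(0, 2 * np.pi)
        r0 = canvas_size * 0.42
        c = (canvas_size - 1) / 2.0
        root = (c + r0 * np.cos(side), c + r0 * np.sin(side))
        heading = np.rad2deg(np.arctan2(c - root[1], c - root[0]))
    else:
        heading = 0.0
    if initial_direction_deg is not None:
        heading = initial_direction_deg
    if not (margin - gp.initial_radius <= root[0] <= canvas_size - 1 + gp.initial_radius
            and margin - gp.initial_radius <= root[1] <= canvas_size - 1 + gp.initial_radius):
        raise InvalidParameterError("root lies outside the canvas")

    nodes = [np.array(root, dtype=np.float64)]
    edges: list[tuple[int, int, float]] = []
    # active tips: (node index, heading degrees, radius, depth)
    tips = [(0, heading, gp.initial_radius, 0)]
    lo, hi = 0.0, canvas_size - 1.0
    while tips:
        idx, ang, rad, depth = tips.pop()
        if depth >= gp.max_depth or rad < 0.4:
            continue
        do_branch = rng.uniform() < gp.branch_prob
        if do_branch:
            split = rng.uniform(*gp.branch_angle_range)
            child_angles = (ang - split / 2 + rng.normal(0, gp.direction_jitter / 2),
                           ang + split / 2 + rng.normal(0, gp.direction_jitter / 2))
        else:
            child_angles = (ang + rng.normal(0, gp.direction_jitter),)
        for ca in child_angles:
            length = rng.uniform(*gp.segment_length_range)
            new = nodes[idx] + length * np.array(
                [np.cos(np.deg2rad(ca)), np.sin(np.deg2rad(ca))]
            )
            if not (lo <= new[0] <= hi and lo <= new[1] <= hi):
                continue  # tip left the canvas; stop this lineage
            nodes.append(new)
            nid = len(nodes) - 1
            edges.append((idx, nid, rad))
            tips.append((nid, ca, rad * gp.radius_decay, depth + 1))
    return VesselTree(nodes=np.array(nodes), edges=edges, tree_id=tree_id)


# ----------------------------------------------------------------- rasterise
def _segment_intersection(p1, p2, p3, p4) -> np.ndarray | None:
    """Proper intersection point of open segments p1-p2 and p3-p4, or None."""
    d1 = p2 - p1
    d2 = p4 - p3
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-12:
        return None
    t = ((p3[0] - p1[0]) * d2[1] - (p3[1] - p1[1]) * d2[0]) / denom
    u = ((p3[0] - p1[0]) * d1[1] - (p3[1] - p1[1]) * d1[0]) / denom
    if 0.0 <= t <= 1.0 and 0.0 <= u <= 1.0:
        return p1 + t * d1
    return None


def merge_close_points(points: np.ndarray, labels: list[str],
                       min_separation: float = 3.0) -> tuple[np.ndarray, list[str]]:
    """Greedy agglomeration: any two points closer than ``min_separation`` are
    replaced by their centroid ('crossing' wins on mixed labels)."""
    pts = [np.asarray(p, dtype=np.float64) for p in points]
    labs = list(labels)
    changed = True
    while changed and len(pts) > 1:
        changed = False
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.hypot(*(pts[i] - pts[j])) < min_separation:
                    pts[i] = (pts[i] + pts[j]) / 2.0
                    labs[i] = "crossing" if "crossing" in (labs[i], labs[j]) else "branching"
                    del pts[j], labs[j]
                    changed = True
                    break
            if changed:
                break
    return (np.array(pts).reshape(-1, 2), labs)


def _vesselness(trees, canvas_size: int) -> np.ndarray:
    """Soft vessel-stroke occupancy in [0, 1] (anti-aliased distance profile)."""
    V = np.zeros((canvas_size, canvas_size))
    yy, xx = np.mgrid[0:canvas_size, 0:canvas_size].astype(np.float64)
    for tree in trees:
        for a, b, rad in tree.edges:
            p, q = tree.nodes[a], tree.nodes[b]
            x0 = max(int(np.floor(min(p[0], q[0]) - rad - 2)), 0)
            x1 = min(int(np.ceil(max(p[0], q[0]) + rad + 2)), canvas_size - 1)
            y0 = max(int(np.floor(min(p[1], q[1]) - rad - 2)), 0)
            y1 = min(int(np.ceil(max(p[1], q[1]) + rad + 2)), canvas_size - 1)
            if x1 < x0 or y1 < y0:
                continue
            gx = xx[y0 : y1 + 1, x0 : x1 + 1]
            gy = yy[y0 : y1 + 1, x0 : x1 + 1]
            d = q - p
            L2 = d @ d
            if L2 < 1e-12:
                dist = np.hypot(gx - p[0], gy - p[1])
            else:
                t = np.clip(((gx - p[0]) * d[0] + (gy - p[1]) * d[1]) / L2, 0, 1)
                dist = np.hypot(gx - (p[0] + t * d[0]), gy - (p[1] + t * d[1]))
            alpha = np.clip(rad / 2.0 + 0.7 - dist, 0.0, 1.0)
            patch = V[y0 : y1 + 1, x0 : x1 + 1]
            np.maximum(patch, alpha, out=patch)
    return V


def rasterize_and_annotate(trees, canvas_size: int,
                           photometric_params: PhotometricParams | None = None,
                           seed: int = 0, min_separation: float = 3.0
                           ) -> tuple[np.ndarray, KeypointSet]:
    """Render vessel trees to an 8-bit-range grayscale image and list its
    ground-truth keypoints.

    Keypoints are every degree->=3 tree node (branching) plus every stroke
    intersection between *distinct* trees (crossing), merged under the minimum
    separation rule.
    """
    if not trees:
        raise InvalidParameterError("at least one tree is required")
    pp = photometric_params or HIGH_QUALITY
    rng = np.random.default_rng(seed)
    n = canvas_size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    c = (n - 1) / 2.0
    r = np.hypot(xx - c, yy - c) / (0.52 * n)
    disc = np.clip(1.0 - np.clip(r - 0.92, 0, None) * 8.0, 0.0, 1.0)
    background = 40.0 + 170.0 * disc
    texture = gaussian_filter(rng.normal(0, 1, (n, n)), n / 16.0)
    texture *= pp.texture_amplitude / max(texture.std(), 1e-9)
    grad_dir = rng.uniform(0, 2 * np.pi)
    ramp = ((xx - c) * np.cos(grad_dir) + (yy - c) * np.sin(grad_dir)) / n
    background = background + texture + pp.illumination_strength * ramp
    V = _vesselness(trees, n)
    img = background * (1.0 - pp.vessel_contrast * V)
    if pp.blur_sigma > 0:
        img = gaussian_filter(img, pp.blur_sigma)
    img = img + rng.normal(0, pp.noise_sigma, (n, n))
    img = np.clip(img, 0, 255)
    img = 255.0 * (img / 255.0) ** pp.gamma

    points: list[np.ndarray] = []
    labels: list[str] = []
    for tree in trees:
        for i in tree.branching_nodes():
            points.append(tree.nodes[i])
            labels.append("branching")
    for ti in range(len(trees)):
        for tj in range(ti + 1, len(trees)):
            for a, b, _ in trees[ti].edges:
                for a2, b2, _ in trees[tj].edges:
                    hit = _segment_intersection(
                        trees[ti].nodes[a], trees[ti].nodes[b],
                        trees[tj].nodes[a2], trees[tj].nodes[b2],
                    )
                    if hit is not None:
                        points.append(hit)
                        labels.append("crossing")
    pts, labs = merge_close_points(np.array(points).reshape(-1, 2), labels,
                                   min_separation)
    inside = [i for i, p in enumerate(pts)
              if 0 <= p[0] <= n - 1 and 0 <= p[1] <= n - 1]
    pts = pts[inside] if len(pts) else pts.reshape(0, 2)
    labs = [labs[i] for i in inside]
    return img, KeypointSet(points=pts, labels=labs)


# ----------------------------------------------------------------- pairing
def apply_homography(H: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 3x3 homogeneous transform to (n, 2) points in (x, y) order."""
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    hom = np.hstack([pts, np.ones((len(pts), 1))]) @ np.asarray(H).T
    return hom[:, :2] / hom[:, 2:3]


def overlap_fraction(H: np.ndarray, fixed_shape, moving_shape) -> float:
    """Fraction of fixed-image pixels whose transform lands on the moving
    canvas (vectorised per-pixel count)."""
    Hh, Ww = fixed_shape[:2]
    mh, mw = moving_shape[:2]
    yy, xx = np.mgrid[0:Hh, 0:Ww]
    pts = apply_homography(H, np.column_stack([xx.ravel(), yy.ravel()]))
    ok = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= mw - 1)
        & (pts[:, 1] >= 0) & (pts[:, 1] <= mh - 1)
    )
    return float(ok.mean())


def _photometric_perturb(img: np.ndarray, pp: PhotometricParams,
                         rng: np.random.Generator) -> np.ndarray:
    gain = 1.0 + rng.uniform(-pp.contrast_jitter, pp.contrast_jitter)
    bias = rng.uniform(-pp.brightness_jitter, pp.brightness_jitter)
    gamma = 1.0 + rng.uniform(-pp.gamma_jitter, pp.gamma_jitter)
    out = np.clip(img * gain + bias, 0, 255)
    out = 255.0 * (out / 255.0) ** gamma
    return out + rng.normal(0, pp.noise_sigma, img.shape)


def make_pair(image: np.ndarray, keypoints: KeypointSet,
              transform_spec: TransformSpec | None = None,
              photometric_params: PhotometricParams | None = None,
              seed: int = 0, quality_tag: str = "high",
              perturb: bool = True) -> ImagePairSample:
    """Warp an annotated image into a registered pair with known ground truth.

    The moving image is the fixed image resampled through the sampled
    homography (inverse map + bilinear interpolation) and photometrically
    perturbed.  Ground-truth matches link every fixed keypoint whose
    transformed location stays on the moving canvas.
    """
    spec = transform_spec or TransformSpec()
    pp = photometric_params or HIGH_QUALITY
    rng = np.random.default_rng(seed)
    n = image.shape[0]
    H = spec.sample(rng, n)
    if abs(np.linalg.det(H)) < 1e-8:
        raise InvalidParameterError("degenerate transform")
    # moving(p) = fixed(H^-1 p): warp with the inverse map
    tform = ProjectiveTransform(matrix=np.linalg.inv(H))
    moving = warp(image.astype(np.float64), tform, order=1, mode="constant",
                  cval=0.0, preserve_range=True)
    if perturb:
        moving = np.clip(_photometric_perturb(moving, pp, rng), 0, 255)
    warped = apply_homography(H, keypoints.points) if len(keypoints) else \
        np.zeros((0, 2))
    matches: list[tuple[int, int]] = []
    mv_pts: list[np.ndarray] = []
    mv_labs: list[str] = []
    Hh, Ww = moving.shape[:2]
    for i, p in enumerate(warped):
        if 0 <= p[0] <= Ww - 1 and 0 <= p[1] <= Hh - 1:
            matches.append((i, len(mv_pts)))
            mv_pts.append(p)
            mv_labs.append(keypoints.labels[i])
    return ImagePairSample(
        fixed_image=image,
        moving_image=moving,
        gt_transform=H,
        fixed_keypoints=keypoints,
        moving_keypoints=KeypointSet(points=np.array(mv_pts).reshape(-1, 2),
                                     labels=mv_labs),
        gt_matches=matches,
        overlap_fraction=overlap_fraction(H, image.shape, moving.shape),
        quality_tag=quality_tag,
    )


# ----------------------------------------------------------------- datasets
def generate_sample(canvas_size: int = 64, quality: str = "high",
                    transform_spec: TransformSpec | None = None,
                    growth_params: GrowthParams | None = None,
                    n_trees: int = 3, seed: int = 0,
                    min_keypoints: int = 4) -> ImagePairSample:
    """Generate one complete synthetic registration sample.

    Scenes are re-drawn (with a shifted seed) until at least ``min_keypoints``
    ground-truth matches exist, so downstream transform estimation is
    well-posed.
    """
    pp = HIGH_QUALITY if quality == "high" else LOW_QUALITY
    for attempt in range(20):
        s = (seed + 1000003 * attempt) % (2 ** 31)
        rng = np.random.default_rng(s)
        trees = [
            generate_tree(canvas_size, growth_params, seed=int(rng.integers(2 ** 31)),
                          tree_id=t)
            for t in range(n_trees)
        ]
        img, kps = rasterize_and_annotate(trees, canvas_size, pp,
                                          seed=int(rng.integers(2 ** 31)))
        sample = make_pair(img, kps, transform_spec, pp,
                           seed=int(rng.integers(2 ** 31)), quality_tag=quality)
        if len(sample.gt_matches) >= min_keypoints:
            return sample
    raise RuntimeError("could not generate a scene with enough keypoints")


def generate_dataset(n_pairs: int, canvas_size: int = 64, quality: str = "high",
                     transform_spec: TransformSpec | None = None,
                     seed: int = 0) -> list[ImagePairSample]:
    """A reproducible list of synthetic registration samples."""
    rng = np.random.default_rng(seed)
    return [
        generate_sample(canvas_size, quality, transform_spec,
                        seed=int(rng.integers(2 ** 31)))
        for _ in range(n_pairs)
    ]
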