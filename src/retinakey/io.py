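"""On-disk formats: PNG images, keypoint/match CSVs, transform JSON.

A dataset directory holds one sub-directory per pair::

    pair_0000/
      fixed.png            8-bit grayscale
      moving.png
      transform.json       {"H": 3x3 row-major nested list}
      fixed_keypoints.csv  columns x,y,label
      moving_keypoints.csv
      matches.csv          columns fixed_idx,moving_idx
      meta.json            {"overlap_fraction": ..., "quality_tag": ...}
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synth import ImagePairSample, KeypointSet

__all__ = [
    "save_image", "load_image", "save_keypoints", "load_keypoints",
    "save_matches", "load_matches", "save_transform", "load_transform",
    "save_sample", "load_sample", "save_dataset", "load_dataset",
    "DataFormatError",
]


class DataFormatError(ValueError):
    """A dataset file does not follow the documented layout."""


def save_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.clip(np.round(np.asarray(image)), 0, 255).astype(np.uint8))


def load_image(path) -> np.ndarray:
    return np.asarray(iio.imread(path), dtype=np.float64)


def save_keypoints(path, kps: KeypointSet) -> None:
    pts = np.asarray(kps.points).reshape(-1, 2)
    labels = kps.labels if kps.labels else ["unlabeled"] * len(pts)
    pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "label": labels}).to_csv(
        path, index=False)


def load_keypoints(path) -> KeypointSet:
    df = pd.read_csv(path)
    if not {"x", "y", "label"} <= set(df.columns):
        raise DataFormatError(f"{path}: expected columns x,y,label")
    return KeypointSet(points=df[["x", "y"]].to_numpy(dtype=np.float64),
                       labels=df["label"].astype(str).tolist())


def save_matches(path, matches) -> None:
    rows = [(int(i), int(j)) for i, j in matches]
    pd.DataFrame(rows, columns=["fixed_idx", "moving_idx"]).to_csv(path, index=False)


def load_matches(path) -> list[tuple[int, int]]:
    df = pd.read_csv(path)
    if not {"fixed_idx", "moving_idx"} <= set(df.columns):
        raise DataFormatError(f"{path}: expected columns fixed_idx,moving_idx")
    return [(int(i), int(j)) for i, j in df.itertuples(index=False)]


def save_transform(path, H: np.ndarray) -> None:
    with open(path, "w") as fh:
        json.dump({"H": np.asarray(H, dtype=float).reshape(3, 3).tolist()}, fh)


def load_transform(path) -> np.ndarray:
    with open(path) as fh:
        obj = json.load(fh)
    if "H" not in obj:
        raise DataFormatError(f"{path}: missing key 'H'")
    H = np.asarray(obj["H"], dtype=np.float64)
    if H.shape != (3, 3):
        raise DataFormatError(f"{path}: 'H' must be 3x3")
    return H


def save_sample(dir_path, sample: ImagePairSample) -> None:
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    save_image(d / "fixed.png", sample.fixed_image)
    save_image(d / "moving.png", sample.moving_image)
    save_transform(d / "transform.json", sample.gt_transform)
    save_keypoints(d / "fixed_keypoints.csv", sample.fixed_keypoints)
    save_keypoints(d / "moving_keypoints.csv", sample.moving_keypoints)
    save_matches(d / "matches.csv", sample.gt_matches)
    with open(d / "meta.json", "w") as fh:
        json.dump({"overlap_fraction": sample.overlap_fraction,
                   "quality_tag": sample.quality_tag}, fh)


def load_sample(dir_path) -> ImagePairSample:
    d = Path(dir_path)
    try:
        with open(d / "meta.json") as fh:
            meta = json.load(fh)
        return ImagePairSample(
            fixed_image=load_image(d / "fixed.png"),
            moving_image=load_image(d / "moving.png"),
            gt_transform=load_transform(d / "transform.json"),
            fixed_keypoints=load_keypoints(d / "fixed_keypoints.csv"),
            moving_keypoints=load_keypoints(d / "moving_keypoints.csv"),
            gt_matches=load_matches(d / "matches.csv"),
            overlap_fraction=float(meta.get("overlap_fraction", np.nan)),
            quality_tag=str(meta.get("quality_tag", "high")),
        )
    except (OSError, json.JSONDecodeError) as exc:
        raise DataFormatError(f"malformed sample directory {d}: {exc}") from exc


def save_dataset(dir_path, samples) -> None:
    d = Path(dir_path)
    for k, s in enumerate(samples):
        save_sample(d / f"pair_{k:04d}", s)


def load_dataset(dir_path, max_bad: int = 5) -> list[ImagePairSample]:
    """Load every pair_* sub-directory; malformed samples are skipped with a
    warning, up to ``max_bad`` before aborting."""
    import warnings

    d = Path(dir_path)
    dirs = sorted(p for p in d.iterdir() if p.is_dir() and p.name.startswith("pair_"))
    if not dirs:
        raise DataFormatError(f"no pair_* directories under {d}")
    out, bad = [], 0
    for p in dirs:
        try:
            out.append(load_sample(p))
        except DataFormatError as exc:
            bad += 1
            warnings.warn(str(exc))
            if bad > max_bad:
                raise
    return out
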