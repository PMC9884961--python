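"""Encoder-decoder keypoint network with optional context aggregation.

A U-Net-style encoder-decoder is applied independently to each image of a pair
(shared weights).  It outputs, at full input resolution,

* a keypoint probability map (sigmoid head) — a pixel-level binary classifier
  for vessel branching/crossing points, and
* a dense embedding map (1x1-conv head) whose vectors are compared with
  Euclidean distance to match keypoints across images.

``context_mode`` selects the bottleneck: ``none`` is the plain encoder-decoder
baseline, ``sca`` inserts single-scale spatially-varying context aggregation
over the deepest encoder feature, and ``sapca`` inserts the dilation-pyramid
variant.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, concat, maxpool2x2, upsample_bilinear
from .context import SAPCAModule, SCAModule
from .nn import Conv2d, ConvBlock, Module

__all__ = [
    "ModelConfig",
    "NetworkOutput",
    "KeypointNet",
    "decoder_fuse",
    "save_checkpoint",
    "load_checkpoint",
    "CheckpointError",
]

CHECKPOINT_VERSION = 1


class CheckpointError(RuntimeError):
    """Raised when a checkpoint file cannot be read back."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    num_levels: number of encoder downsamplings (input size must divide 2**n).
    base_channels: channels of the first encoder block; doubled per level.
    embedding_dim: length of per-keypoint descriptor vectors.
    context_kernel_size: odd size s of the predicted context kernel.
    dilations: dilation rates of the pyramid branches.
    context_mode: 'none' (plain U-Net), 'sca', or 'sapca'.
    in_channels: 1 for grayscale, 3 for RGB input.
    """

    num_levels: int = 4
    base_channels: int = 32
    embedding_dim: int = 512
    context_kernel_size: int = 5
    dilations: tuple[int, ...] = (1, 3, 5)
    context_mode: str = "sapca"
    in_channels: int = 1

    def __post_init__(self):
        self.dilations = tuple(int(d) for d in self.dilations)
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.context_mode not in ("none", "sca", "sapca"):
            raise ValueError(f"unknown context_mode {self.context_mode!r}")
        if self.context_kernel_size % 2 == 0 or self.context_kernel_size < 1:
            raise ValueError("context_kernel_size must be odd and positive")
        if any(d < 1 for d in self.dilations):
            raise ValueError("dilations must be positive")


@dataclass
class NetworkOutput:
    """Full-resolution predictions for one image."""

    prob_map: Tensor  # (H, W) in [0, 1]
    embedding_map: Tensor  # (D, H, W)
    logits: Tensor = None  # (H, W), pre-sigmoid detection scores


def decoder_fuse(f_hat_i: Tensor, f_im1: Tensor, conv: Module) -> Tensor:
    """One decoder fusion step: upsample the deeper feature to the skip
    feature's size, concatenate along channels, convolve."""
    _, H, W = f_im1.shape
    _, h, w = f_hat_i.shape
    if (2 * h, 2 * w) != (H, W):
        raise ValueError(f"decoder level mismatch: deep {h}x{w} vs skip {H}x{W}")
    up = upsample_bilinear(f_hat_i, (H, W))
    return conv(concat([up, f_im1], axis=0))


class KeypointNet(Module):
    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        chans = [cfg.base_channels * 2 ** i for i in range(cfg.num_levels + 1)]
        self.enc_blocks = [
            ConvBlock(cfg.in_channels if i == 0 else chans[i - 1], chans[i], rng)
            for i in range(cfg.num_levels + 1)
        ]
        if cfg.context_mode == "sca":
            self.context = SCAModule(chans[-1], cfg.context_kernel_size, rng)
        elif cfg.context_mode == "sapca":
            self.context = SAPCAModule(chans[-1], cfg.context_kernel_size,
                                       cfg.dilations, rng)
        else:
            self.context = None
        self.dec_blocks = [
            ConvBlock(chans[i + 1] + chans[i], chans[i], rng)
            for i in reversed(range(cfg.num_levels))
        ]
        self.det_head = Conv2d(chans[0], 1, 1, rng)
        # keypoints are rare (a few % of pixels): start the detector at a low
        # prior so early training is not dominated by background suppression
        self.det_head.bias.data[:] = -3.0
        self.emb_head = Conv2d(chans[0], cfg.embedding_dim, 1, rng)

    # ------------------------------------------------------------------ forward
    def forward(self, image: np.ndarray) -> NetworkOutput:
        """Run the network on one image.

        ``image`` is (H, W) or (H, W, 3) with values in [0, 255] or [0, 1];
        it is scaled to [0, 1].  H and W must be divisible by 2**num_levels.
        """
        x = self._prepare(image)
        cfg = self.config
        skips = []
        for i, block in enumerate(self.enc_blocks):
            x = block(x)
            if i < cfg.num_levels:
                skips.append(x)
                x = maxpool2x2(x)
        if self.context is not None:
            x = self.context(x)
        for block, skip in zip(self.dec_blocks, reversed(skips)):
            x = decoder_fuse(x, skip, block)
        logits = self.det_head(x).reshape(x.shape[1], x.shape[2])
        prob = logits.sigmoid()
        emb = self.emb_head(x)
        return NetworkOutput(prob_map=prob, embedding_map=emb, logits=logits)

    __call__ = forward

    def _prepare(self, image: np.ndarray) -> Tensor:
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        elif arr.ndim == 3:
            arr = arr.transpose(2, 0, 1)
        else:
            raise ValueError("image must be (H, W) or (H, W, channels)")
        if arr.shape[0] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} channel(s), got {arr.shape[0]}"
            )
        if arr.max() > 1.0:
            arr = arr / 255.0
        div = 2 ** self.config.num_levels
        _, H, W = arr.shape
        if H % div or W % div:
            raise ValueError(
                f"spatial size {H}x{W} not divisible by 2**num_levels={div}"
            )
        return Tensor(arr)


# ------------------------------------------------------------------ checkpoints
def save_checkpoint(model: KeypointNet, path) -> None:
    """Write weights + config as a zip archive (.npz weights + config JSON)."""
    buf = io.BytesIO()
    np.savez(buf, **model.state_dict())
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(model.config)}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path) -> KeypointNet:
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("version") != CHECKPOINT_VERSION:
                raise CheckpointError(
                    f"unsupported checkpoint version {meta.get('version')!r}"
                )
            weights = dict(np.load(io.BytesIO(zf.read("weights.npz"))))
    except CheckpointError:
        raise
    except Exception as exc:  # corrupt zip / missing members / bad npz
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    cfg = meta["config"]
    cfg["dilations"] = tuple(cfg["dilations"])
    model = KeypointNet(ModelConfig(**cfg))
    try:
        model.load_state_dict(weights)
    except ValueError as exc:
        raise CheckpointError(str(exc)) from exc
    return model
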