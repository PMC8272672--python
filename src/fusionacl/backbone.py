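"""Frozen convolutional backbone and top-down pyramid fusion.

Five VGG-style convolution blocks (3x3 convolutions + ReLU, 2x2 max pool
between blocks) produce one feature map H(g) per block — the output of the
block's last convolution, so map g has spatial side input_size / 2^(g-1).
The maps from a contiguous block range (default 2..5) form a feature
pyramid that is merged top-down: the coarser fused map is upsampled 2x
(nearest neighbour), a 2x2 lateral convolution projects the finer raw map
to the common channel width, the two are summed pixelwise, and a 5x5
convolution smooths the sum to suppress upsampling aliasing.

The backbone is a fixed feature extractor: weights are either drawn from a
seeded initialization or loaded from a checkpoint, and are never updated
by downstream training.  All convolutions are plain numpy (im2col +
einsum); no autograd is needed for a frozen extractor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, SizeError
from .phantom import LabeledImage

logger = logging.getLogger(__name__)

#: channel widths and conv counts of the five blocks, full-size profile
FULL_CHANNELS = (64, 128, 256, 512, 512)
#: reduced profile for desk-scale runs; same topology, narrower blocks
REDUCED_CHANNELS = (4, 8, 16, 32, 32)
CONVS_PER_BLOCK = (2, 2, 3, 3, 3)


@dataclass(frozen=True)
class BackboneConfig:
    weights_mode: str = "seeded_random"  # "seeded_random" | "pretrained"
    block_range: tuple[int, int] = (2, 5)
    input_size: int = 64
    seed: int = 0
    channels: tuple[int, ...] = REDUCED_CHANNELS
    fused_channels: int = 32
    checkpoint: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.block_range
        if not (1 <= lo <= hi <= 5):
            raise ConfigurationError(
                f"backbone.block_range must be contiguous within 1..5, got {self.block_range}"
            )
        if self.weights_mode not in ("seeded_random", "pretrained"):
            raise ConfigurationError(
                f"backbone.weights_mode must be 'seeded_random' or 'pretrained', "
                f"got {self.weights_mode!r}"
            )
        if self.input_size < 32:
            raise ConfigurationError("backbone.input_size must be >= 32")
        if len(self.channels) != 5:
            raise ConfigurationError("backbone.channels must list 5 block widths")
        if self.fused_channels < 1:
            raise ConfigurationError("backbone.fused_channels must be >= 1")

    @property
    def blocks(self) -> range:
        return range(self.block_range[0], self.block_range[1] + 1)


@dataclass
class FeatureMap:
    """One multi-channel map (channels x height x width) from block g."""

    values: np.ndarray
    block_index: int

    @property
    def spatial_side(self) -> int:
        return self.values.shape[-1]


@dataclass
class FeaturePyramid:
    raw_maps: dict[int, FeatureMap]
    fused_maps: dict[int, FeatureMap] = field(default_factory=dict)
    upsampled: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def levels(self) -> list[int]:
        return sorted(self.raw_maps)

    def bottom_fused(self) -> FeatureMap:
        if not self.fused_maps:
            raise ConfigurationError("pyramid has no fused maps; call fuse_pyramid")
        return self.fused_maps[min(self.fused_maps)]


# ---------------------------------------------------------------------------
# numpy convolution primitives
# ---------------------------------------------------------------------------

def conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None = None,
           pad: tuple[tuple[int, int], tuple[int, int]] = ((1, 1), (1, 1))) -> np.ndarray:
    """Cross-correlation of x (C,H,W) with weight (O,C,kh,kw)."""
    kh, kw = weight.shape[-2:]
    xp = np.pad(x, ((0, 0), pad[0], pad[1]))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (C, H', W', kh, kw)
    out = np.einsum("chwij,ocij->ohw", win, weight, optimize=True)
    if bias is not None:
        out = out + bias[:, None, None]
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def max_pool2(x: np.ndarray) -> np.ndarray:
    """2x2 max pooling with stride 2 (trailing odd row/column dropped)."""
    c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    return x[:, : h2 * 2, : w2 * 2].reshape(c, h2, 2, w2, 2).max(axis=(2, 4))


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x upsampling."""
    return np.repeat(np.repeat(x, 2, axis=-2), 2, axis=-1)


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

@dataclass
class BackboneWeights:
    """Conv kernels per block: list over blocks of list of (weight, bias)."""

    blocks: list[list[tuple[np.ndarray, np.ndarray]]]


@dataclass
class FusionWeights:
    """Per-level lateral 2x2 and anti-aliasing 5x5 kernels."""

    lateral: dict[int, tuple[np.ndarray, np.ndarray]]
    smooth: dict[int, tuple[np.ndarray, np.ndarray]]


def _he_kernel(rng: np.random.Generator, out_c: int, in_c: int, k: int) -> np.ndarray:
    std = np.sqrt(2.0 / (in_c * k * k))
    return rng.normal(0.0, std, size=(out_c, in_c, k, k))


def init_backbone_weights(config: BackboneConfig) -> BackboneWeights:
    """Seeded random conv kernels (He-scaled normals, zero biases)."""
    if config.weights_mode == "pretrained":
        if config.checkpoint is None:
            raise ConfigurationError(
                "backbone.weights_mode='pretrained' requires backbone.checkpoint "
                "(a .npz file with arrays block{g}_conv{i}_w / _b)"
            )
        return load_checkpoint(config.checkpoint)
    rng = np.random.default_rng(config.seed)
    blocks = []
    in_c = 1
    for g in range(1, 6):
        out_c = config.channels[g - 1]
        layers = []
        for _ in range(CONVS_PER_BLOCK[g - 1]):
            layers.append((_he_kernel(rng, out_c, in_c, 3), np.zeros(out_c)))
            in_c = out_c
        blocks.append(layers)
    return BackboneWeights(blocks)


def init_fusion_weights(config: BackboneConfig) -> FusionWeights:
    """Seeded lateral/smoothing kernels for the configured block range."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lateral, smooth = {}, {}
    fc = config.fused_channels
    for g in config.blocks:
        in_c = config.channels[g - 1]
        lateral[g] = (_he_kernel(rng, fc, in_c, 2), np.zeros(fc))
        if g != max(config.blocks):
            smooth[g] = (_he_kernel(rng, fc, fc, 5), np.zeros(fc))
    return FusionWeights(lateral, smooth)


def save_checkpoint(weights: BackboneWeights, path: str) -> None:
    arrays = {}
    for g, layers in enumerate(weights.blocks, start=1):
        for i, (w, b) in enumerate(layers):
            arrays[f"block{g}_conv{i}_w"] = w
            arrays[f"block{g}_conv{i}_b"] = b
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> BackboneWeights:
    with np.load(path) as data:
        blocks = []
        for g in range(1, 6):
            layers = []
            i = 0
            while f"block{g}_conv{i}_w" in data:
                layers.append((data[f"block{g}_conv{i}_w"], data[f"block{g}_conv{i}_b"]))
                i += 1
            if not layers:
                raise ConfigurationError(f"checkpoint {path!r} lacks block {g}")
            blocks.append(layers)
    return BackboneWeights(blocks)


# ---------------------------------------------------------------------------
# Pyramid extraction and fusion
# ---------------------------------------------------------------------------

def _to_input_array(image, input_size: int) -> np.ndarray:
    arr = image.pixels if isinstance(image, LabeledImage) else np.asarray(image, float)
    if arr.ndim != 2:
        raise SizeError("input image must be 2-D grayscale")
    if min(arr.shape) < 32:
        raise SizeError(f"input side must be >= 32 pixels, got {arr.shape}")
    if arr.shape != (input_size, input_size):
        from skimage.transform import resize

        arr = resize(arr, (input_size, input_size), anti_aliasing=True,
                     preserve_range=True)
    return arr[None, :, :]


def extract_pyramid(image, config: BackboneConfig,
                    weights: BackboneWeights | None = None) -> FeaturePyramid:
    """Run the conv blocks and collect the raw maps for the block range.

    H(g) is the last conv output of block g (before that block's pool), so
    its spatial side is input_size / 2^(g-1).
    """
    if weights is None:
        weights = init_backbone_weights(config)
    x = _to_input_array(image, config.input_size)
    raw: dict[int, FeatureMap] = {}
    for g in range(1, max(config.blocks) + 1):
        for w, b in weights.blocks[g - 1]:
            x = relu(conv2d(x, w, b))
        if g in config.blocks:
            raw[g] = FeatureMap(values=x.copy(), block_index=g)
        x = max_pool2(x)
    return FeaturePyramid(raw_maps=raw)


def _match_size(up: np.ndarray, target_hw: tuple[int, int]) -> np.ndarray:
    """Crop/pad the upsampled map by at most one pixel per side."""
    th, tw = target_hw
    dh, dw = up.shape[-2] - th, up.shape[-1] - tw
    if dh == 0 and dw == 0:
        return up
    if abs(dh) > 1 or abs(dw) > 1:
        raise ConfigurationError(
            f"upsampled map size {up.shape[-2:]} is inconsistent with target {target_hw}"
        )
    logger.debug("adjusting upsampled map %s -> %s", up.shape[-2:], target_hw)
    if dh > 0:
        up = up[:, :th, :]
    if dw > 0:
        up = up[:, :, :tw]
    if dh < 0:
        up = np.pad(up, ((0, 0), (0, -dh), (0, 0)), mode="edge")
    if dw < 0:
        up = np.pad(up, ((0, 0), (0, 0), (0, -dw)), mode="edge")
    return up


def fuse_pyramid(pyramid: FeaturePyramid, fusion_weights: FusionWeights) -> FeaturePyramid:
    """Top-down merge of the raw pyramid.

    Top level: fused map = 2x2 lateral convolution of its raw map.
    Each lower level g: fused = 5x5 conv( upsample2(fused at g+1)
    + 2x2 lateral conv(raw at g) ).  The 2x2 kernel uses asymmetric padding
    (0 top/left, 1 bottom/right) so sizes are preserved and the pixelwise
    sum is well defined.
    """
    levels = pyramid.levels
    if not levels:
        raise ConfigurationError("pyramid has no raw maps")
    top = levels[-1]
    lw, lb = fusion_weights.lateral[top]
    pyramid.fused_maps[top] = FeatureMap(
        conv2d(pyramid.raw_maps[top].values, lw, lb, pad=((0, 1), (0, 1))), top)
    for g in reversed(levels[:-1]):
        up = upsample2(pyramid.fused_maps[g + 1].values)
        target = pyramid.raw_maps[g].values.shape[-2:]
        up = _match_size(up, target)
        pyramid.upsampled[g] = up
        lw, lb = fusion_weights.lateral[g]
        lat = conv2d(pyramid.raw_maps[g].values, lw, lb, pad=((0, 1), (0, 1)))
        sw, sb = fusion_weights.smooth[g]
        pyramid.fused_maps[g] = FeatureMap(
            conv2d(up + lat, sw, sb, pad=((2, 2), (2, 2))), g)
    return pyramid
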