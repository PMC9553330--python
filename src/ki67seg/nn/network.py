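"""Improved attention U-Net for tumor segmentation.

Architecture (2D, single-output sigmoid head):

* encoder: ``depth`` groups of a recurrent-residual atrous convolution
  block followed by 2x downsampling through two parallel branches
  (2x2 max-pool and a stride-2 convolution) that are summed;
* bottleneck: a recurrent-residual block and a residual multiscale
  pyramid pooling module (adaptive pooling at several grid scales, 1x1
  channel reduction, bilinear upsampling, concatenation with the input
  features);
* decoder: ``depth`` groups of bilinear 2x upsampling, an additive
  attention gate on the matching skip connection, and a 3x3 convolution;
* head: 1x1 convolution + sigmoid, yielding a per-pixel tumor
  probability at the input resolution.

The attention gate computes alpha = sigmoid(phi(SeLU(Wx x + Wg g + bg)) +
b_phi), multiplies the skip feature by alpha, and merges with the
upsampling-path feature (additive by default; concatenation available).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ..exceptions import ConfigurationError, ParameterError, ShapeError
from .autograd import Tensor
from .modules import Conv2d, DropBlock2d, Module, ModuleList

__all__ = [
    "NetworkConfig",
    "AttentionGate",
    "attention_gate",
    "PyramidPool",
    "pyramid_pool",
    "RRAtrousBlock",
    "SegmentationModel",
    "build_network",
    "forward",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the segmentation network."""

    depth: int = 4
    in_channels: int = 2
    base_channels: int = 16
    recurrence_steps: int = 2
    dilation_rates: tuple[int, ...] = (1, 2)
    dropblock_size: int = 5
    dropblock_keep_prob: float = 0.9
    pyramid_scales: tuple[int, ...] = (2, 4, 8, 16)
    pyramid_reduce: int | None = None  # channels per branch; default C/4
    pool_mode: str = "mean"
    gate_merge: str = "add"
    out_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.recurrence_steps < 1:
            raise ConfigurationError("recurrence_steps must be >= 1")
        if any(s2 <= s1 for s1, s2 in zip(self.pyramid_scales, self.pyramid_scales[1:])):
            raise ConfigurationError("pyramid_scales must be strictly increasing")
        if not 0 < self.dropblock_keep_prob <= 1:
            raise ConfigurationError("dropblock_keep_prob must be in (0, 1]")
        if not 0 < self.out_threshold < 1:
            raise ConfigurationError("out_threshold must be in (0, 1)")
        if self.gate_merge not in ("add", "concat"):
            raise ConfigurationError("gate_merge must be 'add' or 'concat'")
        if self.pool_mode not in ("mean", "max"):
            raise ConfigurationError("pool_mode must be 'mean' or 'max'")


class AttentionGate(Module):
    """Additive attention gate on a skip connection.

    ``w_x`` and ``w_g`` are 1x1 linear maps into a common intermediate
    channel space; ``b_g`` rides on ``w_g``; ``phi`` is a 1x1 map to a
    single channel with bias ``b_phi``.  Activations are fixed: SeLU
    inside, sigmoid outside, so every attention coefficient lies strictly
    in (0, 1).
    """

    def __init__(self, x_channels: int, g_channels: int, inter_channels: int,
                 merge: str = "add", rng: np.random.Generator | None = None):
        super().__init__()
        if merge == "add" and g_channels != x_channels:
            raise ConfigurationError(
                "additive merge requires g and x to share a channel count; "
                f"got {g_channels} vs {x_channels}"
            )
        self.merge = merge
        self.w_x = Conv2d(x_channels, inter_channels, k=1, bias=False, rng=rng)
        self.w_g = Conv2d(g_channels, inter_channels, k=1, bias=True, rng=rng)
        self.phi = Conv2d(inter_channels, 1, k=1, bias=True, rng=rng)

    def forward(self, x: Tensor, g: Tensor) -> tuple[Tensor, Tensor]:
        _, cx, h, w = x.shape
        if g.shape[2:] != (h, w):  # resample the coarser gating signal
            g = g.bilinear_resize(h, w)
        q = (self.w_x(x) + self.w_g(g)).selu()
        alpha = self.phi(q).sigmoid()
        x_hat = alpha * x
        if self.merge == "add":
            x_out = x_hat + g
        else:
            x_out = x_hat.concat_channels(g)
        return alpha, x_out

    def zero_parameters(self) -> None:
        """Force all weights/biases to zero (alpha becomes exactly 0.5)."""
        for p in self.parameters():
            p.data[...] = 0.0


def attention_gate(x_l, g_l, params: AttentionGate):
    """Functional form: returns (alpha grid, gated output feature map)."""
    x = x_l if isinstance(x_l, Tensor) else Tensor(x_l)
    g = g_l if isinstance(g_l, Tensor) else Tensor(g_l)
    return params(x, g)


class PyramidPool(Module):
    """Residual multiscale pyramid pooling.

    For each scale s the features are adaptively pooled to an s x s grid,
    reduced to ``reduce_channels`` by a 1x1 convolution, bilinearly
    upsampled back, and all branches are concatenated with the original
    features: output channels = C + len(scales) * reduce_channels.
    """

    def __init__(self, channels: int, scales: tuple[int, ...] = (2, 4, 8, 16),
                 reduce_channels: int | None = None, pool_mode: str = "mean",
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.scales = tuple(scales)
        self.pool_mode = pool_mode
        self.reduce_channels = reduce_channels or max(1, channels // len(self.scales))
        self.convs = ModuleList(
            Conv2d(channels, self.reduce_channels, k=1, rng=rng) for _ in self.scales
        )
        self.out_channels = channels + len(self.scales) * self.reduce_channels

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        for s in self.scales:
            if h < s or w < s:
                raise ConfigurationError(
                    f"pyramid scale {s} exceeds feature size {h}x{w}"
                )
            if h % s or w % s:
                raise ConfigurationError(
                    f"feature size {h}x{w} not divisible by pyramid scale {s}"
                )
        branches = []
        for s, conv in zip(self.scales, self.convs):
            pooled = x.avgpool_to(s) if self.pool_mode == "mean" else x.maxpool_to(s)
            branches.append(conv(pooled).bilinear_resize(h, w))
        return x.concat_channels(*branches)


def pyramid_pool(features, scales=(2, 4, 8, 16), reduce_channels=None,
                 module: PyramidPool | None = None):
    """Functional form of :class:`PyramidPool` (builds a module if needed)."""
    x = features if isinstance(features, Tensor) else Tensor(features)
    if module is None:
        module = PyramidPool(x.shape[1], tuple(scales), reduce_channels)
    return module(x)


class RRAtrousBlock(Module):
    """Recurrent-residual atrous convolution block with DropBlock.

    A 1x1 identity-mapping shortcut carries the input (channel-mapped) past
    the main branch.  The main branch applies one recurrent unit per
    dilation rate: each unit re-feeds its own output additively into the
    same convolution for ``t`` steps (weight sharing across steps), with
    SeLU activations.  DropBlock regularizes the branch during training
    only; with all convolution weights zeroed the block reduces to its
    shortcut.
    """

    def __init__(self, cin: int, cout: int, *, t: int = 2,
                 dilations: tuple[int, ...] = (1, 2), dropblock_size: int = 5,
                 keep_prob: float = 0.9, rng: np.random.Generator | None = None,
                 drop_rng: np.random.Generator | None = None):
        super().__init__()
        if t < 1:
            raise ConfigurationError("recurrence_steps must be >= 1")
        self.t = t
        self.shortcut = Conv2d(cin, cout, k=1, bias=True, rng=rng)
        self.units = ModuleList(
            Conv2d(cout, cout, k=3, dilation=d, bias=True, rng=rng)
            for d in dilations
        )
        self.dropblock = DropBlock2d(dropblock_size, keep_prob, rng=drop_rng)

    def forward(self, x: Tensor) -> Tensor:
        s = self.shortcut(x)
        h = s
        for conv in self.units:
            z = conv(h).selu()
            for _ in range(self.t - 1):
                z = conv(h + z).selu()
            h = z
        h = self.dropblock(h)
        return s + h


def rr_atrous_block(features, block: RRAtrousBlock):
    """Functional form: apply a recurrent-residual atrous block."""
    x = features if isinstance(features, Tensor) else Tensor(features)
    return block(x)


class _DownSample(Module):
    """2x downsampling via summed parallel max-pool and stride-2 conv branches."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(channels, channels, k=3, stride=2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool2() + self.conv(x)


class SegmentationModel(Module):
    """The full encoder / pyramid bottleneck / attention decoder network."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None,
                 drop_seed: int = 0):
        super().__init__()
        self.config = config
        rng = rng or np.random.default_rng(0)
        drop_ss = np.random.SeedSequence(drop_seed)
        cfg = config
        chans = [cfg.base_channels * 2**i for i in range(cfg.depth)]
        c_bot = cfg.base_channels * 2**cfg.depth

        def rr(cin, cout):
            return RRAtrousBlock(
                cin, cout, t=cfg.recurrence_steps, dilations=cfg.dilation_rates,
                dropblock_size=cfg.dropblock_size, keep_prob=cfg.dropblock_keep_prob,
                rng=rng, drop_rng=np.random.default_rng(drop_ss.spawn(1)[0]),
            )

        self.enc_blocks = ModuleList()
        self.downs = ModuleList()
        cin = cfg.in_channels
        for c in chans:
            self.enc_blocks.append(rr(cin, c))
            self.downs.append(_DownSample(c, rng=rng))
            cin = c
        self.bottleneck = rr(cin, c_bot)
        self.pyramid = PyramidPool(
            c_bot, cfg.pyramid_scales, cfg.pyramid_reduce, cfg.pool_mode, rng=rng
        )

        self.up_convs = ModuleList()
        self.gates = ModuleList()
        self.dec_convs = ModuleList()
        cur = self.pyramid.out_channels
        for c in reversed(chans):
            self.up_convs.append(Conv2d(cur, c, k=1, rng=rng))
            self.gates.append(
                AttentionGate(c, c, max(1, c // 2), merge=cfg.gate_merge, rng=rng)
            )
            self.dec_convs.append(
                Conv2d(2 * c if cfg.gate_merge == "concat" else c, c, k=3, rng=rng)
            )
            cur = c
        self.head = Conv2d(cur, 1, k=1, rng=rng)

    # -- forward ----------------------------------------------------------
    def forward_logits(self, x: Tensor) -> Tensor:
        cfg = self.config
        _, _, h, w = x.shape
        mult = 2**cfg.depth
        if h % mult or w % mult:
            raise ShapeError(
                f"input spatial dims ({h}x{w}) must be multiples of {mult} "
                f"for depth {cfg.depth}"
            )
        skips = []
        for block, down in zip(self.enc_blocks, self.downs):
            x = block(x)
            skips.append(x)
            x = down(x)
        x = self.pyramid(self.bottleneck(x))
        for up, gate, conv, skip in zip(
            self.up_convs, self.gates, self.dec_convs, reversed(skips)
        ):
            g = up(x.bilinear_resize(*skip.shape[2:]))
            _, x = gate(skip, g)
            x = conv(x).selu()
        return self.head(x)

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_logits(x).sigmoid()

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_network(config: NetworkConfig, seed: int = 0) -> SegmentationModel:
    """Instantiate a network with seeded LeCun-normal initialization."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    return SegmentationModel(config, rng=rng, drop_seed=seed)


def _as_batch(image) -> Tensor:
    arr = image.data if isinstance(image, Tensor) else np.asarray(image, np.float32)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None]
    elif arr.ndim != 4:
        raise ShapeError("image must be 2D, (C,H,W) or (N,C,H,W)")
    return Tensor(arr)


def forward(model: SegmentationModel, image) -> np.ndarray:
    """Run the network in evaluation mode; returns per-pixel probabilities."""
    was_training = model.training
    model.eval()
    try:
        prob = model(_as_batch(image)).data
    finally:
        model.train(was_training)
    return prob.squeeze(axis=(0, 1)) if prob.shape[0] == 1 else prob[:, 0]


def predict_mask(model: SegmentationModel, image, threshold: float | None = None
                 ) -> np.ndarray:
    """Binarize the probability map at ``threshold`` (default from config)."""
    threshold = model.config.out_threshold if threshold is None else threshold
    if not 0 < threshold < 1:
        raise ParameterError("threshold must be in (0, 1)")
    return (forward(model, image) >= threshold).astype(np.uint8)


def save_checkpoint(model: SegmentationModel, path) -> Path:
    """Serialized weights (.npz) plus a JSON config side-car."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    cfg = asdict(model.config)
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))
    return path


def load_checkpoint(path) -> SegmentationModel:
    path = Path(path)
    if not path.exists():
        raise IOError(f"checkpoint not found: {path}")
    cfg_raw = json.loads(path.with_suffix(".json").read_text())
    for key in ("dilation_rates", "pyramid_scales"):
        cfg_raw[key] = tuple(cfg_raw[key])
    model = SegmentationModel(NetworkConfig(**cfg_raw))
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    model.eval()
    return model
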