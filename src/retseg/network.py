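"""Segmentation architecture: residual blocks, ASPP, residual attention,
deep supervision, and the encoder-decoder assembly.

The network takes a 64x64x1 contrast-enhanced patch and emits a 64x64x1
vessel-probability map, plus three auxiliary probability maps from deep
supervision heads that tap the encoder stages.  Building blocks:

* residual block — H(x) = F(x) + g(x): a two-conv residual path (3x3 conv,
  batch norm, ReLU, dropout, 3x3 conv, batch norm, ReLU) plus a 1x1
  projection g on the identity path so channel counts always match.
* ASPP — four parallel branches (1x1 conv, and 3x3 atrous convolutions at
  dilation 2, 3, 4), 128 kernels each, concatenated to 512 channels; the
  dilations enlarge the receptive field at no parameter cost.
* residual attention — H(x) = (1 + M(x)) * T(x): a two-conv trunk with a
  jump connection, reweighted by a sigmoid mask M from a small
  down/up-sampling branch (two poolings, two transposed-conv upsamplings).
* deep supervision heads — transposed-conv chains back to full resolution,
  1x1 conv, sigmoid; their losses are added to the main loss with a weight
  that decays over training.

Encoder stages apply the residual block (with attention at the middle stage
and ASPP at the deepest) and then 2x2 max-pool; decoder stages upsample by
transposed convolution, concatenate the encoder skip, and apply a residual
block, ending in a 64x64x64 feature map; a final residual block, 1x1 conv
and sigmoid produce the output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ParameterError, ShapeError
from .nn import layers as L
from .nn import tensor as T
from .nn.tensor import Tensor


@dataclass
class ModelSpec:
    """Architecture description from which the network is built."""

    in_channels: int = 1
    stage_channels: tuple[int, ...] = (64, 128, 256)
    aspp_rates: tuple[int, ...] = (1, 2, 3, 4)
    aspp_kernels_per_branch: int = 128
    dropout_rate: float = 0.2
    l2_coeff: float = 1e-4
    n_supervision: int = 3
    window: int = 64
    attention_stage: int = 1  # middle encoder stage (0-based)
    aspp_stage: int = 2  # deepest encoder stage

    def __post_init__(self) -> None:
        self.stage_channels = tuple(self.stage_channels)
        self.aspp_rates = tuple(self.aspp_rates)
        if not self.stage_channels:
            raise ParameterError("stage_channels must be nonempty")
        if 1 not in self.aspp_rates:
            raise ParameterError("aspp_rates must contain 1 (plain convolution)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if any(r < 1 for r in self.aspp_rates):
            raise ParameterError("dilation rates must be >= 1")
        n = len(self.stage_channels)
        if self.window % (2**n) != 0:
            raise ParameterError(
                f"window {self.window} must be divisible by 2^{n} for {n} poolings"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls(**json.loads(s))


class ResidualBlock(L.Layer):
    """H(x) = F(x) + g(x) with a 1x1 projection on the identity path."""

    def __init__(self, in_ch: int, out_ch: int, dropout: float, rng: np.random.Generator):
        self.conv1 = L.Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = L.BatchNorm2d(out_ch)
        self.conv2 = L.Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = L.BatchNorm2d(out_ch)
        self.proj = L.Conv2d(in_ch, out_ch, 1, rng)
        self.dropout = dropout
        self._rng = rng

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        f = T.relu(self.bn1(self.conv1(x), training))
        if training and self.dropout > 0:
            f = T.dropout(f, self.dropout, self._rng)
        f = T.relu(self.bn2(self.conv2(f), training))
        return f + self.proj(x)


class ASPP(L.Layer):
    """Atrous spatial pyramid pooling: parallel dilated branches, concatenated."""

    def __init__(
        self,
        in_ch: int,
        rates: tuple[int, ...],
        kernels_per_branch: int,
        rng: np.random.Generator,
    ):
        if any(r < 1 for r in rates):
            raise ParameterError("dilation rates must be >= 1")
        self.branches = [
            L.ConvBNReLU(
                in_ch,
                kernels_per_branch,
                rng,
                kernel=1 if r == 1 else 3,
                dilation=r,
            )
            for r in rates
        ]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return T.concat([b(x, training) for b in self.branches], axis=1)


class ResidualAttention(L.Layer):
    """H(x) = (1 + M(x)) * T(x); mask branch downsamples twice, upsamples twice."""

    def __init__(self, channels: int, rng: np.random.Generator):
        # trunk: two 3x3 conv-bn-relu layers plus a 1x1 jump connection
        self.trunk1 = L.ConvBNReLU(channels, channels, rng)
        self.trunk2 = L.ConvBNReLU(channels, channels, rng)
        self.trunk_proj = L.Conv2d(channels, channels, 1, rng)
        self.mask_down1 = L.ConvBNReLU(channels, channels, rng)
        self.mask_down2 = L.ConvBNReLU(channels, channels, rng)
        self.mask_up1 = L.ConvTranspose2x2(channels, channels, rng)
        self.mask_up2 = L.ConvTranspose2x2(channels, channels, rng)
        self.mask_out = L.Conv2d(channels, channels, 1, rng, bias=True)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % 4 or w % 4:
            raise ShapeError(
                f"attention block needs spatial dims divisible by 4, got {(h, w)}"
            )
        t = self.trunk2(self.trunk1(x, training), training) + self.trunk_proj(x)
        m = self.mask_down1(T.maxpool2x2(x), training)
        m = self.mask_down2(T.maxpool2x2(m), training)
        m = self.mask_up1(m)
        m = self.mask_up2(m)
        m = T.sigmoid(self.mask_out(m))
        return t + m * t  # (1 + M) .* T


class SupervisionHead(L.Layer):
    """Upsample an encoder tap back to the window size; 1x1 conv; sigmoid."""

    def __init__(self, in_ch: int, scale: int, rng: np.random.Generator):
        ups = []
        ch = in_ch
        s = scale
        while s > 1:
            nxt = max(ch // 2, 8)
            ups.append(L.ConvTranspose2x2(ch, nxt, rng))
            ch = nxt
            s //= 2
        self.ups = ups
        self.out_conv = L.Conv2d(ch, 1, 1, rng, bias=True, weight_decay=False)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        for up in self.ups:
            x = T.relu(up(x))
        return T.sigmoid(self.out_conv(x))


class UpsampleBlock(L.Layer):
    """Transposed-conv x2 upsampling with batch norm and ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.up = L.ConvTranspose2x2(in_ch, out_ch, rng)
        self.bn = L.BatchNorm2d(out_ch)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return T.relu(self.bn(self.up(x), training))


class VesselSegNet(L.Layer):
    """Encoder-decoder with skip connections and three supervision heads."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self._rng = rng
        chans = spec.stage_channels
        n_stages = len(chans)

        self.enc_blocks: list[L.Layer] = []
        self.extras: list[L.Layer | None] = []
        skip_channels: list[int] = []
        in_ch = spec.in_channels
        for i, ch in enumerate(chans):
            self.enc_blocks.append(ResidualBlock(in_ch, ch, spec.dropout_rate, rng))
            out_ch = ch
            extra: L.Layer | None = None
            if i == spec.aspp_stage:
                extra = ASPP(ch, spec.aspp_rates, spec.aspp_kernels_per_branch, rng)
                out_ch = len(spec.aspp_rates) * spec.aspp_kernels_per_branch
            elif i == spec.attention_stage:
                extra = ResidualAttention(ch, rng)
            self.extras.append(extra)
            skip_channels.append(out_ch)
            in_ch = out_ch

        self.sup_heads = [
            SupervisionHead(skip_channels[i], 2**i, rng)
            for i in range(min(spec.n_supervision, n_stages))
        ]

        # decoder: upsample, concat encoder skip, residual block down to the
        # mirrored stage width; last stage ends at stage_channels[0] channels
        self.dec_ups: list[UpsampleBlock] = []
        self.dec_blocks: list[ResidualBlock] = []
        ch_in = skip_channels[-1]  # bottleneck channels after last pool
        for i in range(n_stages - 1, -1, -1):
            up_out = chans[i]
            self.dec_ups.append(UpsampleBlock(ch_in, up_out, rng))
            merged = up_out + skip_channels[i]
            self.dec_blocks.append(
                ResidualBlock(merged, chans[max(i - 1, 0)], spec.dropout_rate, rng)
            )
            ch_in = chans[max(i - 1, 0)]

        self.final_block = ResidualBlock(ch_in, ch_in, spec.dropout_rate, rng)
        self.final_conv = L.Conv2d(ch_in, 1, 1, rng, bias=True, weight_decay=False)

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray | Tensor, training: bool = False):
        """Run a batch (N,1,H,W); returns (main, [sup1, sup2, sup3]) Tensors."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.data.ndim != 4 or x.data.shape[1] != self.spec.in_channels:
            raise ShapeError(f"expected (N,{self.spec.in_channels},H,W), got {x.shape}")
        skips: list[Tensor] = []
        h = x
        for block, extra in zip(self.enc_blocks, self.extras):
            h = block(h, training)
            if extra is not None:
                h = extra(h, training)
            skips.append(h)
            h = T.maxpool2x2(h)
        sups = [head(skips[i], training) for i, head in enumerate(self.sup_heads)]
        for j, (up, dec) in enumerate(zip(self.dec_ups, self.dec_blocks)):
            h = up(h, training)
            skip = skips[len(skips) - 1 - j]
            h = T.concat([h, skip], axis=1)
            h = dec(h, training)
        self._pre_head_shape = h.shape  # (N, C, H, W) before the output head
        h = self.final_block(h, training)
        main = T.sigmoid(self.final_conv(h))
        return main, sups

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Eval-mode forward over batches; main output only, (N,H,W) floats."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None, :, :]
        outs = []
        for i in range(0, x.shape[0], batch_size):
            main, _ = self.forward(x[i : i + batch_size], training=False)
            outs.append(main.data[:, 0])
        return np.concatenate(outs, axis=0)

    def decay_parameters(self) -> list[Tensor]:
        """Convolution kernels subject to L2 regularization."""
        out: list[Tensor] = []

        def collect(layer: L.Layer) -> None:
            if isinstance(layer, (L.Conv2d, L.ConvTranspose2x2)):
                if getattr(layer, "weight_decay", False):
                    out.append(layer.weight)
                return
            for v in vars(layer).values():
                if isinstance(v, L.Layer):
                    collect(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, L.Layer):
                            collect(item)

        collect(self)
        return out


def build_model(spec: ModelSpec, seed: int = 0) -> VesselSegNet:
    """Construct the full segmentation network from its spec."""
    return VesselSegNet(spec, seed=seed)


# -- functional views of the blocks (fresh random weights, eval mode) -------


def residual_block(x: np.ndarray, out_channels: int, seed: int = 0) -> np.ndarray:
    """Apply a freshly initialized residual block to (N,C,H,W); returns array."""
    rng = np.random.default_rng(seed)
    blk = ResidualBlock(x.shape[1], out_channels, 0.0, rng)
    return blk(Tensor(np.asarray(x, np.float32)), training=False).data


def aspp_block(
    x: np.ndarray,
    rates: tuple[int, ...] = (1, 2, 3, 4),
    kernels_per_branch: int = 128,
    seed: int = 0,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    blk = ASPP(x.shape[1], tuple(rates), kernels_per_branch, rng)
    return blk(Tensor(np.asarray(x, np.float32)), training=False).data


def residual_attention_block(x: np.ndarray, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    blk = ResidualAttention(x.shape[1], rng)
    return blk(Tensor(np.asarray(x, np.float32)), training=False).data


def deep_supervision_head(x: np.ndarray, target_size: int, seed: int = 0) -> np.ndarray:
    scale = target_size // x.shape[2]
    if scale * x.shape[2] != target_size:
        raise ShapeError("target_size must be an integer multiple of input size")
    rng = np.random.default_rng(seed)
    head = SupervisionHead(x.shape[1], scale, rng)
    return head(Tensor(np.asarray(x, np.float32)), training=False).data
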