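"""U-Net segmentation networks with pretrained-style backbones.

Five encoder families are provided — a plain U-Net encoder and four
ImageNet-lineage backbones (ResNet-34, ResNeXt-50 32x4d, an
Inception-V3-style multi-branch encoder, EfficientNet-B2) — all wrapped
in the same encoder/decoder contract:

* the encoder exposes exactly five pyramid levels (one feature map per
  down-sampling stage), grouped into five freezable stages;
* the decoder is exactly four up-sampling blocks with skip
  concatenation; a 1x1 head maps to the three tissue classes
  (stroma / benign / cancer) at the input resolution.

The proposed model is a three-head EfficientNet-B2 U-Net ensemble: each
head gets a different encoder-freezing strategy, the heads' per-pixel
class-probability maps are channel-concatenated (3 heads x 3 classes =
9 channels) and fused by a trainable 1x1 convolution followed by a
per-pixel softmax.

Every structural claim (block censuses, stage resolutions, parameter
counts) is recoverable by traversal via :func:`summarize` — nothing is
hard-coded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .labels import N_CLASSES
from .nn import (AvgPool3x3, BatchNorm2d, Conv2d, Identity, MaxPool2d,
                 Module, ModuleList, ReLU, Sequential, SiLU, Tensor,
                 UpsampleNearest2d, concat, relu, softmax)

BACKBONES = ("unet_plain", "resnet34", "resnext50", "inceptionv3",
             "efficientnetb2")


def _scale(ch: int, width: float) -> int:
    return max(4, int(round(ch * width)))


# ---------------------------------------------------------------------------
# Freezing strategies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FreezingStrategy:
    """Which encoder stages (1-based) are excluded from gradient updates.

    The decoder is never frozen.
    """

    name: str
    frozen_stage_indices: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "frozen_stage_indices",
                           frozenset(self.frozen_stage_indices))


FREEZE_ALL_ENCODER = FreezingStrategy("freeze_all_encoder", frozenset({1, 2, 3, 4, 5}))
FREEZE_EARLY_STAGES = FreezingStrategy("freeze_early_stages", frozenset({1, 2, 3}))
FREEZE_NONE = FreezingStrategy("freeze_none", frozenset())

#: The three-head default spanning the freezing spectrum.
DEFAULT_STRATEGIES = (FREEZE_ALL_ENCODER, FREEZE_EARLY_STAGES, FREEZE_NONE)


def apply_freezing(net: "UNet", strategy: FreezingStrategy) -> "UNet":
    """Freeze the parameters of the selected encoder stages in place.

    Frozen parameters are excluded from optimiser updates and from the
    backward sweep; decoder and head parameters are never touched.
    """
    stages = net.encoder.stages
    bad = [i for i in strategy.frozen_stage_indices
           if not (1 <= i <= len(stages))]
    if bad:
        raise ValueError(
            f"freezing strategy {strategy.name!r} references missing encoder "
            f"stage(s) {sorted(bad)}; valid stages are 1..{len(stages)}")
    for i in strategy.frozen_stage_indices:
        stages[i - 1].freeze()
    net.freezing = strategy
    return net


# ---------------------------------------------------------------------------
# Shared building blocks
# ---------------------------------------------------------------------------

class ConvBnAct(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, groups=1,
                 act="relu", rng=None, role="conv"):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride=stride,
                           groups=groups, bias=False, rng=rng, role=role)
        self.bn = BatchNorm2d(out_ch)
        self.act = {"relu": ReLU, "silu": SiLU, "none": Identity}[act]()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class SqueezeExcite(Module):
    """Channel attention of the MBConv block (squeeze ratio on the block
    input channels, as in the EfficientNet family)."""

    def __init__(self, ch, se_ch, rng):
        super().__init__()
        self.reduce = Conv2d(ch, se_ch, 1, bias=True, rng=rng, role="se")
        self.expand = Conv2d(se_ch, ch, 1, bias=True, rng=rng, role="se")

    def forward(self, x):
        s = nn.global_avg_pool(x)
        s = nn.silu(self.reduce(s))
        s = nn.sigmoid(self.expand(s))
        return nn.mul(x, s)


class MBConv(Module):
    """Mobile inverted bottleneck: 1x1 expand -> k x k depthwise ->
    squeeze-excite -> 1x1 project, residual when shape-preserving."""

    is_mbconv = True

    def __init__(self, in_ch, out_ch, kernel, stride, expand, rng,
                 se_ratio=0.25):
        super().__init__()
        mid = in_ch * expand
        self.expand_ratio = expand
        self.kernel, self.stride = kernel, stride
        self.pre = (ConvBnAct(in_ch, mid, 1, act="silu", rng=rng)
                    if expand != 1 else Identity())
        self.dw = ConvBnAct(mid, mid, kernel, stride=stride, groups=mid,
                            act="silu", rng=rng, role="depthwise")
        self.se = SqueezeExcite(mid, max(1, int(in_ch * se_ratio)), rng)
        self.project = ConvBnAct(mid, out_ch, 1, act="none", rng=rng)
        self.residual = stride == 1 and in_ch == out_ch

    def forward(self, x):
        h = self.project(self.se(self.dw(self.pre(x))))
        return nn.add(h, x) if self.residual else h


# ---------------------------------------------------------------------------
# EfficientNet-B2 encoder
# ---------------------------------------------------------------------------

#: Per-row layout of the B2 encoder: (operator, out_channels, kernel,
#: stride, repeats). Channels follow the EfficientNet width schedule for
#: coefficient 1.1 (divisor 8). The MBConv1 stage is kept at its
#: unscaled depth of 1, giving a 22-MBConv encoder; pass a custom
#: ``repeats`` to :func:`build_network` for other depth schedules.
EFFICIENTNET_B2_ROWS = (
    ("Conv3x3_s2", 32, 3, 2, 1),
    ("MBConv1_3x3", 16, 3, 1, 1),
    ("MBConv6_3x3", 24, 3, 2, 3),
    ("MBConv6_5x5", 48, 5, 2, 3),
    ("MBConv6_3x3", 88, 3, 2, 4),
    ("MBConv6_5x5", 120, 5, 1, 4),
    ("MBConv6_5x5", 208, 5, 2, 5),
    ("MBConv6_3x3", 352, 3, 1, 2),
    ("Conv1x1", 1408, 1, 1, 1),
)


class EfficientNetB2Encoder(Module):
    """Staged MBConv feature extractor exposing 5 pyramid levels.

    The five freezable stages follow the encoder's five down-sampling
    groups; their outputs are the skip features (strides 2..32).
    """

    def __init__(self, width=1.0, rng=None, repeats=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        rows = EFFICIENTNET_B2_ROWS
        if repeats is not None:
            if len(repeats) != len(rows):
                raise ValueError(f"repeats must have {len(rows)} entries")
            rows = tuple((op, ch, k, s, r)
                         for (op, ch, k, s, _), r in zip(rows, repeats))
        self.rows = rows
        ch = [_scale(c, width) for (_, c, _, _, _) in rows]

        stem = ConvBnAct(3, ch[0], 3, stride=2, act="silu", rng=rng)
        groups: list[list[Module]] = [[stem], [], [], [], []]
        # Table rows -> down-sampling groups (stride-2 boundaries at
        # rows 2, 3, 4 and 6; the head conv stays with the deepest group)
        row_to_group = (0, 0, 1, 2, 3, 3, 4, 4, 4)
        in_ch = ch[0]
        for r, (op, _, k, s, rep) in enumerate(rows):
            if op.startswith("Conv") and r == 0:
                continue
            g = row_to_group[r]
            if op == "Conv1x1":
                groups[g].append(ConvBnAct(in_ch, ch[r], 1, act="silu", rng=rng))
                in_ch = ch[r]
                continue
            expand = 1 if op == "MBConv1_3x3" else 6
            for j in range(rep):
                groups[g].append(MBConv(in_ch, ch[r], k,
                                        s if j == 0 else 1, expand, rng))
                in_ch = ch[r]
        self.stage1 = Sequential(*groups[0])
        self.stage2 = Sequential(*groups[1])
        self.stage3 = Sequential(*groups[2])
        self.stage4 = Sequential(*groups[3])
        self.stage5 = Sequential(*groups[4])
        self.feature_channels = [ch[1], ch[2], ch[3], ch[5], ch[8]]
        self.deepest_reduction = 32

    @property
    def stages(self):
        return [self.stage1, self.stage2, self.stage3, self.stage4,
                self.stage5]

    def stage_table(self, input_size: int = 256):
        """Reproduce the encoder-specification table (operator, output
        resolution for ``input_size``, repeat count) by walking the
        built rows and accumulating their strides."""
        res = input_size
        table = []
        for op, _, _, s, rep in self.rows:
            res //= s
            table.append((op, res, rep))
        return table

    def forward(self, x):
        f1 = self.stage1(x)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        f4 = self.stage4(f3)
        f5 = self.stage5(f4)
        return [f1, f2, f3, f4, f5]


# ---------------------------------------------------------------------------
# ResNet-34 / ResNeXt-50 encoders
# ---------------------------------------------------------------------------

class BasicBlock(Module):
    def __init__(self, in_ch, out_ch, stride, rng):
        super().__init__()
        self.conv1 = ConvBnAct(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.conv2 = ConvBnAct(out_ch, out_ch, 3, act="none", rng=rng)
        if stride != 1 or in_ch != out_ch:
            self.shortcut = ConvBnAct(in_ch, out_ch, 1, stride=stride,
                                      act="none", rng=rng, role="projection")
        else:
            self.shortcut = Identity()

    def forward(self, x):
        return relu(nn.add(self.conv2(self.conv1(x)), self.shortcut(x)))


class BottleneckX(Module):
    """ResNeXt bottleneck: 1x1 reduce, grouped 3x3 (cardinality 32),
    1x1 expand."""

    def __init__(self, in_ch, mid_ch, out_ch, stride, cardinality, rng):
        super().__init__()
        self.conv1 = ConvBnAct(in_ch, mid_ch, 1, rng=rng)
        self.conv2 = ConvBnAct(mid_ch, mid_ch, 3, stride=stride,
                               groups=cardinality, rng=rng)
        self.conv3 = ConvBnAct(mid_ch, out_ch, 1, act="none", rng=rng)
        if stride != 1 or in_ch != out_ch:
            self.shortcut = ConvBnAct(in_ch, out_ch, 1, stride=stride,
                                      act="none", rng=rng, role="projection")
        else:
            self.shortcut = Identity()

    def forward(self, x):
        return relu(nn.add(self.conv3(self.conv2(self.conv1(x))),
                           self.shortcut(x)))


class ResNet34Encoder(Module):
    """16 basic blocks in a 3/4/6/3 layout behind a 7x7 stem: 33
    main-path convolutions (projection shortcuts tallied separately)."""

    def __init__(self, width=1.0, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        ch = [_scale(c, width) for c in (64, 128, 256, 512)]
        self.stage1 = ConvBnAct(3, ch[0], 7, stride=2, rng=rng)
        layers = (3, 4, 6, 3)

        def make_layer(in_ch, out_ch, n, stride):
            blocks = [BasicBlock(in_ch, out_ch, stride, rng)]
            blocks += [BasicBlock(out_ch, out_ch, 1, rng) for _ in range(n - 1)]
            return blocks

        self.stage2 = Sequential(MaxPool2d(3, 2, 1),
                                 *make_layer(ch[0], ch[0], layers[0], 1))
        self.stage3 = Sequential(*make_layer(ch[0], ch[1], layers[1], 2))
        self.stage4 = Sequential(*make_layer(ch[1], ch[2], layers[2], 2))
        self.stage5 = Sequential(*make_layer(ch[2], ch[3], layers[3], 2))
        self.feature_channels = [ch[0], ch[0], ch[1], ch[2], ch[3]]
        self.deepest_reduction = 32

    @property
    def stages(self):
        return [self.stage1, self.stage2, self.stage3, self.stage4,
                self.stage5]

    def forward(self, x):
        f1 = self.stage1(x)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        f4 = self.stage4(f3)
        f5 = self.stage5(f4)
        return [f1, f2, f3, f4, f5]


class ResNeXt50Encoder(Module):
    def __init__(self, width=1.0, cardinality=32, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        stem_ch = _scale(64, width)
        out_chs = [_scale(c, width) for c in (256, 512, 1024, 2048)]
        mid_chs = [_scale(c, width) for c in (128, 256, 512, 1024)]
        layers = (3, 4, 6, 3)
        self.cardinality = cardinality
        self.stage1 = ConvBnAct(3, stem_ch, 7, stride=2, rng=rng)

        def make_layer(in_ch, mid_ch, out_ch, n, stride):
            card = min(cardinality, mid_ch)
            mid_ch = max(card, (mid_ch // card) * card)
            blocks = [BottleneckX(in_ch, mid_ch, out_ch, stride, card, rng)]
            blocks += [BottleneckX(out_ch, mid_ch, out_ch, 1, card, rng)
                       for _ in range(n - 1)]
            return blocks

        self.stage2 = Sequential(MaxPool2d(3, 2, 1),
                                 *make_layer(stem_ch, mid_chs[0], out_chs[0],
                                             layers[0], 1))
        self.stage3 = Sequential(*make_layer(out_chs[0], mid_chs[1],
                                             out_chs[1], layers[1], 2))
        self.stage4 = Sequential(*make_layer(out_chs[1], mid_chs[2],
                                             out_chs[2], layers[2], 2))
        self.stage5 = Sequential(*make_layer(out_chs[2], mid_chs[3],
                                             out_chs[3], layers[3], 2))
        self.feature_channels = [stem_ch] + out_chs
        self.deepest_reduction = 32

    @property
    def stages(self):
        return [self.stage1, self.stage2, self.stage3, self.stage4,
                self.stage5]

    forward = ResNet34Encoder.forward


# ---------------------------------------------------------------------------
# Inception-style encoder
# ---------------------------------------------------------------------------

class InceptionBlock(Module):
    """Multi-branch block with 1x1, 3x3 (double) and 5x5 filters plus a
    pooled projection, concatenated on channels."""

    def __init__(self, in_ch, b1, b5red, b5, b3red, b3, pool_proj, rng):
        super().__init__()
        self.branch1 = ConvBnAct(in_ch, b1, 1, rng=rng)
        self.branch5 = Sequential(ConvBnAct(in_ch, b5red, 1, rng=rng),
                                  ConvBnAct(b5red, b5, 5, rng=rng))
        self.branch3 = Sequential(ConvBnAct(in_ch, b3red, 1, rng=rng),
                                  ConvBnAct(b3red, b3, 3, rng=rng),
                                  ConvBnAct(b3, b3, 3, rng=rng))
        self.branch_pool = Sequential(AvgPool3x3(),
                                      ConvBnAct(in_ch, pool_proj, 1, rng=rng))
        self.out_channels = b1 + b5 + b3 + pool_proj

    def forward(self, x):
        return concat([self.branch1(x), self.branch5(x), self.branch3(x),
                       self.branch_pool(x)], axis=1)


class ReductionBlock(Module):
    """Stride-2 inception block; pooled branch passes channels through."""

    def __init__(self, in_ch, a, b, rng):
        super().__init__()
        self.branch_a = ConvBnAct(in_ch, a, 3, stride=2, rng=rng)
        self.branch_b = Sequential(ConvBnAct(in_ch, max(4, b // 2), 1, rng=rng),
                                   ConvBnAct(max(4, b // 2), b, 3, stride=2,
                                             rng=rng))
        self.branch_pool = MaxPool2d(3, 2, 1)
        self.out_channels = a + b + in_ch

    def forward(self, x):
        return concat([self.branch_a(x), self.branch_b(x),
                       self.branch_pool(x)], axis=1)


class InceptionV3Encoder(Module):
    def __init__(self, width=1.0, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        s = lambda c: _scale(c, width)  # noqa: E731
        self.stage1 = Sequential(ConvBnAct(3, s(32), 3, stride=2, rng=rng),
                                 ConvBnAct(s(32), s(32), 3, rng=rng),
                                 ConvBnAct(s(32), s(64), 3, rng=rng))
        self.stage2 = Sequential(MaxPool2d(3, 2, 1),
                                 ConvBnAct(s(64), s(80), 1, rng=rng),
                                 ConvBnAct(s(80), s(192), 3, rng=rng))
        blocks_a = []
        in_ch = s(192)
        for _ in range(3):
            blk = InceptionBlock(in_ch, s(64), s(48), s(64), s(64), s(96),
                                 s(32), rng)
            blocks_a.append(blk)
            in_ch = blk.out_channels
        self.stage3 = Sequential(MaxPool2d(3, 2, 1), *blocks_a)
        red_a = ReductionBlock(in_ch, s(128), s(128), rng)
        blocks_b = []
        in_ch = red_a.out_channels
        for _ in range(4):
            blk = InceptionBlock(in_ch, s(128), s(96), s(128), s(128), s(192),
                                 s(64), rng)
            blocks_b.append(blk)
            in_ch = blk.out_channels
        self.stage4 = Sequential(red_a, *blocks_b)
        red_b = ReductionBlock(in_ch, s(128), s(128), rng)
        blocks_c = []
        in_ch = red_b.out_channels
        for _ in range(2):
            blk = InceptionBlock(in_ch, s(192), s(128), s(192), s(160), s(288),
                                 s(96), rng)
            blocks_c.append(blk)
            in_ch = blk.out_channels
        self.stage5 = Sequential(red_b, *blocks_c)
        self.feature_channels = [s(64), s(192), blocks_a[-1].out_channels,
                                 blocks_b[-1].out_channels,
                                 blocks_c[-1].out_channels]
        self.deepest_reduction = 32

    @property
    def stages(self):
        return [self.stage1, self.stage2, self.stage3, self.stage4,
                self.stage5]

    forward = ResNet34Encoder.forward


# ---------------------------------------------------------------------------
# Plain U-Net encoder
# ---------------------------------------------------------------------------

class DoubleConv(Module):
    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.block = Sequential(ConvBnAct(in_ch, out_ch, 3, rng=rng),
                                ConvBnAct(out_ch, out_ch, 3, rng=rng))

    def forward(self, x):
        return self.block(x)


class PlainUNetEncoder(Module):
    """Classic contracting path: double 3x3 conv + 2x2 max-pool per
    level; deepest feature at stride 16 (256 -> 16)."""

    def __init__(self, width=1.0, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        ch = [_scale(c, width) for c in (64, 128, 256, 512, 1024)]
        self.stage1 = DoubleConv(3, ch[0], rng)
        self.stage2 = Sequential(MaxPool2d(2), DoubleConv(ch[0], ch[1], rng))
        self.stage3 = Sequential(MaxPool2d(2), DoubleConv(ch[1], ch[2], rng))
        self.stage4 = Sequential(MaxPool2d(2), DoubleConv(ch[2], ch[3], rng))
        self.stage5 = Sequential(MaxPool2d(2), DoubleConv(ch[3], ch[4], rng))
        self.feature_channels = ch
        self.deepest_reduction = 16

    @property
    def stages(self):
        return [self.stage1, self.stage2, self.stage3, self.stage4,
                self.stage5]

    forward = ResNet34Encoder.forward


# ---------------------------------------------------------------------------
# Decoder, head, full networks
# ---------------------------------------------------------------------------

class DecoderBlock(Module):
    """One expanding step: 2x nearest upsample, skip concatenation, two
    3x3 conv-BN-ReLU layers."""

    is_decoder_block = True

    def __init__(self, in_ch, skip_ch, out_ch, rng):
        super().__init__()
        self.up = UpsampleNearest2d()
        self.conv1 = ConvBnAct(in_ch + skip_ch, out_ch, 3, rng=rng)
        self.conv2 = ConvBnAct(out_ch, out_ch, 3, rng=rng)

    def forward(self, x, skip):
        x = self.up(x)
        x = concat([x, skip], axis=1)
        return self.conv2(self.conv1(x))


class SegmentationHead(Module):
    def __init__(self, in_ch, n_classes, final_upsample, rng):
        super().__init__()
        self.conv = Conv2d(in_ch, n_classes, 1, bias=True, rng=rng)
        self.final_upsample = final_upsample

    def forward(self, x):
        x = self.conv(x)
        if self.final_upsample:
            x = nn.upsample_nearest2x(x)
        return x


_ENCODERS = {
    "unet_plain": PlainUNetEncoder,
    "resnet34": ResNet34Encoder,
    "resnext50": ResNeXt50Encoder,
    "inceptionv3": InceptionV3Encoder,
    "efficientnetb2": EfficientNetB2Encoder,
}


class UNet(Module):
    """Encoder-decoder segmentation network: 5 encoder levels, 4 decoder
    up-sampling blocks, per-pixel ``n_classes`` score map at input size."""

    def __init__(self, backbone_name: str, n_classes: int = N_CLASSES,
                 width: float = 1.0, seed: int = 0,
                 decoder_channels=(256, 128, 64, 32), **enc_kwargs):
        super().__init__()
        if backbone_name not in _ENCODERS:
            raise ValueError(
                f"unknown backbone {backbone_name!r}; valid names: "
                f"{', '.join(BACKBONES)}")
        rng = np.random.default_rng(seed)
        self.backbone_name = backbone_name
        self.n_classes = n_classes
        self.build_width = width
        self.encoder = _ENCODERS[backbone_name](width=width, rng=rng,
                                                **enc_kwargs)
        enc_ch = self.encoder.feature_channels
        dec_ch = [_scale(c, width) for c in decoder_channels]
        blocks = []
        in_ch = enc_ch[-1]
        for skip_ch, out_ch in zip(enc_ch[-2::-1], dec_ch):
            blocks.append(DecoderBlock(in_ch, skip_ch, out_ch, rng))
            in_ch = out_ch
        self.decoder = ModuleList(blocks)
        self.head = SegmentationHead(
            in_ch, n_classes,
            final_upsample=self.encoder.deepest_reduction == 32, rng=rng)
        self.freezing: FreezingStrategy | None = None

    def forward(self, x) -> Tensor:
        feats = self.encoder(x)
        d = feats[-1]
        for block, skip in zip(self.decoder, feats[-2::-1]):
            d = block(d, skip)
        return self.head(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch of RGB patches.

        ``x``: (B, H, W, 3) floats in [0, 1]. Returns (B, H, W, C).
        """
        was_training = self.training
        self.eval()
        try:
            t = Tensor(np.ascontiguousarray(
                np.asarray(x, dtype=np.float32).transpose(0, 3, 1, 2)))
            p = softmax(self.forward(t), axis=1)
        finally:
            self.train(was_training)
        return p.data.transpose(0, 2, 3, 1)


class EnsembleNetwork(Module):
    """Three EfficientNet-B2 U-Net heads (one freezing strategy each)
    whose probability maps are concatenated and fused by a 1x1 conv."""

    def __init__(self, strategies=DEFAULT_STRATEGIES, n_classes: int = N_CLASSES,
                 width: float = 1.0, seed: int = 0, **head_kwargs):
        super().__init__()
        strategies = tuple(strategies)
        if len(strategies) != 3:
            raise ValueError("an ensemble takes exactly 3 freezing strategies")
        if len({s.frozen_stage_indices for s in strategies}) != 3:
            raise ValueError("freezing strategies must be pairwise distinct")
        self.strategies = strategies
        self.n_classes = n_classes
        self.build_width = width
        heads = []
        for i, strat in enumerate(strategies):
            head = UNet("efficientnetb2", n_classes=n_classes, width=width,
                        seed=seed + i, **head_kwargs)
            apply_freezing(head, strat)
            heads.append(head)
        self.heads = ModuleList(heads)
        rng = np.random.default_rng(seed + 1000)
        self.fusion = Conv2d(3 * n_classes, n_classes, 1, bias=True, rng=rng)

    def forward(self, x) -> Tensor:
        probs = [softmax(h(x), axis=1) for h in self.heads]
        return self.fusion(concat(probs, axis=1))

    predict_proba = UNet.predict_proba


# ---------------------------------------------------------------------------
# Construction and introspection
# ---------------------------------------------------------------------------

def build_network(backbone_name: str, input_size: int = 256,
                  n_classes: int = N_CLASSES, width: float = 1.0,
                  seed: int = 0, **enc_kwargs) -> UNet:
    """Build a seeded, randomly initialised segmentation network.

    ``input_size`` is validated against the encoder's deepest reduction
    (the network itself is fully convolutional and accepts any input
    whose sides are divisible by that reduction).
    """
    net = UNet(backbone_name, n_classes=n_classes, width=width, seed=seed,
               **enc_kwargs)
    if input_size % net.encoder.deepest_reduction:
        raise ValueError(
            f"input_size {input_size} not divisible by the encoder "
            f"reduction {net.encoder.deepest_reduction}")
    return net


def build_ensemble(strategies=DEFAULT_STRATEGIES, seed: int = 0,
                   n_classes: int = N_CLASSES, width: float = 1.0,
                   **head_kwargs) -> EnsembleNetwork:
    return EnsembleNetwork(strategies=strategies, n_classes=n_classes,
                           width=width, seed=seed, **head_kwargs)


def set_bn_momentum(net: Module, momentum: float) -> Module:
    """Adjust every batch-norm running-average momentum in place.

    Short training runs (few optimiser steps) need a larger momentum so
    the running statistics used at evaluation time track the batch
    statistics quickly."""
    for m in net.modules():
        if isinstance(m, BatchNorm2d):
            m.momentum = momentum
    return net


def load_pretrained_encoder(net: UNet, state_path) -> UNet:
    """Optional plug-in hook: load encoder weights from an ``.npz`` file
    whose keys match ``net.encoder`` parameter names."""
    state = dict(np.load(state_path))
    net.encoder.load_state_dict(state)
    return net


@dataclass
class ArchitectureSummary:
    """Structural census of a built network, computed by traversal."""

    backbone_name: str
    conv_layer_count: int
    encoder_conv_layer_count: int
    projection_conv_count: int
    mbconv_block_count: int
    stage_resolutions: list
    upsampling_block_count: int
    trainable_parameter_count: int
    total_parameter_count: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=list, indent=2)


def _census(module: Module, role: str) -> int:
    return sum(1 for m in module.modules()
               if isinstance(m, Conv2d) and m.role == role)


def summarize(net: Module, input_size: int = 256) -> ArchitectureSummary:
    """Walk the module tree (and probe one forward pass) to produce the
    architecture census; no count is hard-coded."""
    if isinstance(net, EnsembleNetwork):
        inner = net.heads[0]
    else:
        inner = net
    enc = inner.encoder
    was_training = net.training
    net.eval()
    try:
        feats = enc(Tensor(np.zeros((1, 3, input_size, input_size),
                                    dtype=np.float32)))
    finally:
        net.train(was_training)
    resolutions = [f.data.shape[2] for f in feats]
    params = net.parameters()
    return ArchitectureSummary(
        backbone_name=getattr(inner, "backbone_name", "ensemble"),
        conv_layer_count=_census(net, "conv"),
        encoder_conv_layer_count=_census(enc, "conv"),
        projection_conv_count=_census(enc, "projection"),
        mbconv_block_count=sum(
            1 for m in enc.modules() if getattr(m, "is_mbconv", False)),
        stage_resolutions=resolutions,
        upsampling_block_count=sum(
            1 for m in inner.modules()
            if getattr(m, "is_decoder_block", False)),
        trainable_parameter_count=int(sum(
            p.data.size for p in params if p.trainable)),
        total_parameter_count=int(sum(p.data.size for p in params)),
    )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(net: Module, path, extra: dict | None = None) -> None:
    """Serialise weights plus the rebuild recipe to one ``.npz`` file."""
    if isinstance(net, EnsembleNetwork):
        meta = {"kind": "ensemble", "n_classes": net.n_classes,
                "strategies": [[s.name, sorted(s.frozen_stage_indices)]
                               for s in net.strategies]}
    else:
        meta = {"kind": "unet", "backbone_name": net.backbone_name,
                "n_classes": net.n_classes}
    meta["width"] = getattr(net, "build_width", 1.0)
    meta.update(extra or {})
    state = net.state_dict()
    state["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> Module:
    data = dict(np.load(path))
    meta = json.loads(bytes(data.pop("__meta__")).decode())
    width = meta.get("width") or 1.0
    if meta["kind"] == "ensemble":
        strategies = tuple(FreezingStrategy(n, frozenset(idx))
                           for n, idx in meta["strategies"])
        net = build_ensemble(strategies=strategies,
                             n_classes=meta["n_classes"], width=width)
    else:
        net = build_network(meta["backbone_name"],
                            n_classes=meta["n_classes"], width=width)
    net.load_state_dict(data)
    return net
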