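"""Nested-U organoid segmentation network.

The architecture is a six-encoder / five-decoder U-of-U-blocks ("U2")
encoder-decoder in which every stage is a residual U-block (RSU).  Two
additions target brightfield organoid imagery:

* **GCM** (grouping cross merge) replaces the plain concatenation at each
  encoder->decoder skip: shallow and deep feature maps are each split into
  ``n`` channel groups, matching groups are concatenated and squeezed to
  half their width by a 1x1 convolution, the group outputs are re-joined,
  and a residual of the deep input is added.  The five GCMs are serially
  linked deep-to-shallow through a carry channel.
* **RAG** (residual attention gate) at the shallowest resolution: the skip
  feature ``x`` and the half-resolution gating feature ``g`` are fused
  (1x1 convs, add, ReLU), filtered, globally pooled, squeezed through a
  two-layer bottleneck with a sigmoid to per-channel weights in (0,1),
  applied multiplicatively and added back residually.

Both additions are independently switchable, giving the four ablation
variants (plain backbone, +RAG, +GCM, +both).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import (
    Tensor,
    Module,
    Conv2d,
    BatchNorm2d,
    Linear,
    relu,
    sigmoid,
    concat,
    maxpool2,
    resize_bilinear,
    upsample2,
    global_avg_pool,
    scale_channels,
    dropout,
)


class ConfigError(ValueError):
    """Raised at build time when an architecture config is inconsistent."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RSUConfig:
    level: int
    in_channels: int
    mid_channels: int
    out_channels: int
    dilated: bool = False

    def validate(self):
        if self.level < 2:
            raise ConfigError(f"RSU level must be >= 2, got {self.level}")
        for f in ("in_channels", "mid_channels", "out_channels"):
            if getattr(self, f) < 1:
                raise ConfigError(f"RSU {f} must be positive")


@dataclass
class StageSpec:
    name: str
    rsu: RSUConfig
    resize: str  # "maxpool2" | "dilated-hold" | "upsample2"


@dataclass
class BackboneConfig:
    stage_table: list[StageSpec]
    input_size: tuple[int, int, int] = (3, 256, 256)

    @property
    def encoders(self) -> list[StageSpec]:
        return [s for s in self.stage_table if s.name.startswith("Encoder")]

    @property
    def decoders(self) -> list[StageSpec]:
        return [s for s in self.stage_table if s.name.startswith("Decoder")]

    def validate(self):
        if len(self.encoders) != 6 or len(self.decoders) != 5:
            raise ConfigError("backbone needs 6 encoder and 5 decoder stages")
        for s in self.stage_table:
            s.rsu.validate()


@dataclass
class GCMConfig:
    # skip depth 1 (shallowest, full resolution) .. 5 (deepest)
    groups_by_depth: dict[int, int] = field(
        default_factory=lambda: {1: 4, 2: 4, 3: 6, 4: 8, 5: 8}
    )
    serial_link: bool = True


@dataclass
class RAGConfig:
    reduction_ratio: int = 16
    inter_channels: int | None = None  # default: channels of x


@dataclass
class NetworkConfig:
    backbone: BackboneConfig
    gcm: GCMConfig = field(default_factory=GCMConfig)
    rag: RAGConfig = field(default_factory=RAGConfig)
    dropout_p: float = 0.5
    use_gcm: bool = True
    use_rag: bool = True
    # how the six-map splice and the RAG-classifier branch combine:
    # "average" (logit-space mean), "splice", "rag"
    fuse_mode: str = "average"
    side_outputs: int = 6

    def validate(self):
        self.backbone.validate()
        if self.side_outputs != 6:
            raise ConfigError("the backbone emits exactly 6 side outputs")
        if not 0 <= self.dropout_p < 1:
            raise ConfigError("dropout_p must be in [0,1)")
        if self.fuse_mode not in ("average", "splice", "rag"):
            raise ConfigError(f"unknown fuse_mode {self.fuse_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "NetworkConfig":
        bb = d["backbone"]
        stage_table = [
            StageSpec(s["name"], RSUConfig(**s["rsu"]), s["resize"]) for s in bb["stage_table"]
        ]
        gcm = GCMConfig(
            groups_by_depth={int(k): v for k, v in d["gcm"]["groups_by_depth"].items()},
            serial_link=d["gcm"]["serial_link"],
        )
        return NetworkConfig(
            backbone=BackboneConfig(stage_table, tuple(bb["input_size"])),
            gcm=gcm,
            rag=RAGConfig(**d["rag"]),
            dropout_p=d["dropout_p"],
            use_gcm=d["use_gcm"],
            use_rag=d["use_rag"],
            fuse_mode=d["fuse_mode"],
            side_outputs=d["side_outputs"],
        )


# Full-width channel plan: (name, L, mid, out, dilated).  Encoder1's output
# is 64 channels (the printed channel table carries a typo there, forced by
# Encoder2's 64-channel input); decoder input widths are derived at build
# time from the skip mode.
_ENCODER_PLAN = [
    ("Encoder1", 7, 32, 64, False),
    ("Encoder2", 6, 32, 128, False),
    ("Encoder3", 5, 64, 256, False),
    ("Encoder4", 4, 128, 512, False),
    ("Encoder5", 4, 256, 512, True),
    ("Encoder6", 4, 256, 512, True),
]
_DECODER_PLAN = [
    ("Decoder5", 4, 256, 512, True),
    ("Decoder4", 4, 128, 256, False),
    ("Decoder3", 5, 64, 128, False),
    ("Decoder2", 6, 32, 64, False),
    ("Decoder1", 7, 16, 32, False),
]


def default_network_config(width_divisor: int = 1,
                           input_hw: tuple[int, int] = (256, 256),
                           **overrides) -> NetworkConfig:
    """Build the standard configuration, optionally width-reduced.

    ``width_divisor`` divides every channel count (minimum 4), keeping the
    topology, skip structure and group counts intact; handy for CPU-scale
    training and tests.
    """

    def sc(c: int) -> int:
        return max(4, c // width_divisor) if width_divisor > 1 else c

    stages: list[StageSpec] = []
    prev = 3
    enc_out = []
    for i, (name, L, mid, out, dil) in enumerate(_ENCODER_PLAN):
        out_s = sc(out)
        # pooling happens BETWEEN encoder stages (after the first five),
        # regardless of whether the stage itself is a dilated block
        stages.append(
            StageSpec(
                name,
                RSUConfig(L, prev, sc(mid), out_s, dil),
                "maxpool2" if i < 5 else "dilated-hold",
            )
        )
        enc_out.append(out_s)
        prev = out_s
    # skip depth k (5..1) pairs Encoder k with the upsampled deeper feature;
    # both carry the same channel count, so the GCM halving law returns it.
    deep = enc_out[5]
    for (name, L, mid, out, dil), k in zip(_DECODER_PLAN, range(5, 0, -1)):
        c_in = (enc_out[k - 1] + deep) // 2  # table value under GCM skips
        stages.append(
            StageSpec(
                name,
                RSUConfig(L, c_in, sc(mid), sc(out), dil),
                "dilated-hold" if dil else "upsample2",
            )
        )
        deep = sc(out)
    cfg = NetworkConfig(
        backbone=BackboneConfig(stages, (3, input_hw[0], input_hw[1])), **overrides
    )
    cfg.validate()
    return cfg


def small_network_config(**overrides) -> NetworkConfig:
    """Width-reduced (channels / 8) preset for CPU training and tests."""
    return default_network_config(width_divisor=8, **overrides)


# ---------------------------------------------------------------------------
# StageFeature: plain container for inspection APIs
# ---------------------------------------------------------------------------


@dataclass
class StageFeature:
    values: np.ndarray  # C x H x W
    stage_name: str

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)


# ---------------------------------------------------------------------------
# RSU: residual U-block
# ---------------------------------------------------------------------------


class REBNCONV(Module):
    """3x3 conv + batch norm + ReLU, the primitive of every RSU."""

    def __init__(self, in_ch, out_ch, dilation=1, rng=None):
        self.conv = Conv2d(in_ch, out_ch, k=3, dilation=dilation, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def __call__(self, x):
        return relu(self.bn(self.conv(x)))


class RSU(Module):
    """Residual U-block of height L.

    An input 3x3 convolution lifts C_in to C_out; a symmetric U-structure
    over M mid channels extracts multi-scale context (2x2 max-pool descents
    and bilinear x2 ascents with skip concatenations); the U output is
    summed with the input convolution's map.  The dilated variant keeps the
    input resolution throughout, replacing resizing with dilation rates
    1, 2, 4, ... doubling per level.
    """

    def __init__(self, cfg: RSUConfig, rng=None):
        cfg.validate()
        self.cfg = cfg
        L, ci, m, co = cfg.level, cfg.in_channels, cfg.mid_channels, cfg.out_channels
        self.conv_in = REBNCONV(ci, co, rng=rng)
        if cfg.dilated:
            rates = [2 ** i for i in range(L)]
            self.enc = [
                REBNCONV(co if i == 0 else m, m, dilation=rates[i], rng=rng)
                for i in range(L - 1)
            ]
            self.bottom = REBNCONV(m, m, dilation=rates[L - 1], rng=rng)
            self.dec = [
                REBNCONV(2 * m, co if i == 0 else m, dilation=rates[i], rng=rng)
                for i in range(L - 1)
            ]
        else:
            self.enc = [REBNCONV(co if i == 0 else m, m, rng=rng) for i in range(L - 1)]
            self.bottom = REBNCONV(m, m, dilation=2, rng=rng)
            self.dec = [REBNCONV(2 * m, co if i == 0 else m, rng=rng) for i in range(L - 1)]
        self.last_internal_shapes: list[tuple] = []

    def __call__(self, x: Tensor) -> Tensor:
        L = self.cfg.level
        _, _, H, W = x.data.shape
        self.last_internal_shapes = []
        if not self.cfg.dilated and min(H, W) < 2 ** (L - 2):
            raise ValueError(
                f"RSU level {L} pools below 1x1 on a {H}x{W} input "
                f"(needs at least {2 ** (L - 2)} per side)"
            )
        hxin = self.conv_in(x)
        h = [self.enc[0](hxin)]
        self.last_internal_shapes.append(h[0].data.shape)
        for i in range(1, L - 1):
            prev = h[-1] if self.cfg.dilated else maxpool2(h[-1])
            h.append(self.enc[i](prev))
            self.last_internal_shapes.append(h[-1].data.shape)
        d = self.bottom(h[-1])
        self.last_internal_shapes.append(d.data.shape)
        for i in range(L - 2, -1, -1):
            d = self.dec[i](concat([d, h[i]], axis=1))
            self.last_internal_shapes.append(d.data.shape)
            if i > 0 and not self.cfg.dilated:
                th, tw = h[i - 1].data.shape[2:]
                d = resize_bilinear(d, th, tw)
        return d + hxin


def build_rsu(cfg: RSUConfig, rng=None) -> RSU:
    return RSU(cfg, rng=rng)


# ---------------------------------------------------------------------------
# GCM: grouping cross merge skip module
# ---------------------------------------------------------------------------


def _group_sizes(c: int, n: int) -> list[int]:
    # near-equal split, larger groups first (array_split semantics)
    q, r = divmod(c, n)
    return [q + 1] * r + [q] * (n - r)


class GCM(Module):
    """Grouped cross-merge of a shallow and a deep feature map.

    Output channel count is exactly (C_s + C_d) / 2.  A 1x1-projected
    residual of the deep input is added; an optional carry from the
    previous (deeper) GCM is resized, projected and summed into the deep
    input before grouping.
    """

    def __init__(self, c_shallow: int, c_deep: int, n: int,
                 carry_channels: int | None = None, rng=None):
        if n < 1:
            raise ConfigError("GCM group count must be >= 1")
        if n > min(c_shallow, c_deep):
            raise ConfigError(
                f"GCM group count n={n} exceeds channel count "
                f"min({c_shallow},{c_deep})"
            )
        if (c_shallow + c_deep) % 2:
            raise ConfigError("GCM needs an even total channel count to halve it")
        self.n = n
        self.sizes_s = _group_sizes(c_shallow, n)
        self.sizes_d = _group_sizes(c_deep, n)
        self.out_channels = (c_shallow + c_deep) // 2
        outs = [(s + d) // 2 for s, d in zip(self.sizes_s, self.sizes_d)]
        outs[0] += self.out_channels - sum(outs)
        self.group_convs = [
            Conv2d(s + d, o, k=1, rng=rng)
            for s, d, o in zip(self.sizes_s, self.sizes_d, outs)
        ]
        self.residual_proj = (
            Conv2d(c_deep, self.out_channels, k=1, rng=rng)
            if c_deep != self.out_channels
            else None
        )
        self.carry_proj = (
            Conv2d(carry_channels, c_deep, k=1, rng=rng)
            if carry_channels is not None and carry_channels != c_deep
            else None
        )
        self.carry_channels = carry_channels

    @staticmethod
    def _split(x: Tensor, sizes: list[int]) -> list[Tensor]:
        parts, at = [], 0
        for s in sizes:
            parts.append(nn.channel_slice(x, at, at + s))
            at += s
        return parts

    def __call__(self, shallow: Tensor, deep: Tensor, carry: Tensor | None = None) -> Tensor:
        if shallow.data.shape[2:] != deep.data.shape[2:]:
            raise ValueError("GCM inputs must share spatial size")
        if carry is not None:
            th, tw = deep.data.shape[2:]
            carry = resize_bilinear(carry, th, tw)
            if self.carry_proj is not None:
                carry = self.carry_proj(carry)
            deep = deep + carry
        gs = self._split(shallow, self.sizes_s)
        gd = self._split(deep, self.sizes_d)
        merged = concat(
            [conv(concat([a, b], axis=1)) for conv, a, b in zip(self.group_convs, gs, gd)],
            axis=1,
        )
        res = self.residual_proj(deep) if self.residual_proj is not None else deep
        return merged + res


# ---------------------------------------------------------------------------
# RAG: residual attention gate
# ---------------------------------------------------------------------------


class RAG(Module):
    """Channel attention gate over a skip feature x gated by coarser g.

    phi = ReLU(a(x) + b(up2(g))); d = W_phi(phi); A = sigmoid(FC(ReLU(FC(GAP(d)))));
    output o_f = A (x) d + d (per-channel reweighting plus residual).
    """

    def __init__(self, c_x: int, c_g: int, cfg: RAGConfig | None = None, rng=None):
        cfg = cfg or RAGConfig()
        inter = cfg.inter_channels or c_x
        r = max(1, cfg.reduction_ratio)
        if inter >= 4:
            r = min(r, inter // 4)  # keep at least 4 bottleneck channels
        r = max(1, r)
        hidden = max(1, inter // r)
        self.inter = inter
        self.a = Conv2d(c_x, inter, k=1, rng=rng)
        self.b = Conv2d(c_g, inter, k=1, rng=rng)
        self.d = Conv2d(inter, inter, k=1, rng=rng)
        self.fc1 = Linear(inter, hidden, rng=rng)
        self.fc2 = Linear(hidden, inter, rng=rng)
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor, g: Tensor) -> Tensor:
        _, _, H, W = x.data.shape
        gh, gw = g.data.shape[2:]
        if (gh, gw) != (H // 2, W // 2):
            raise ValueError(
                f"RAG gating feature must be half resolution: x {H}x{W}, g {gh}x{gw}"
            )
        phi = relu(self.a(x) + self.b(resize_bilinear(g, H, W)))
        dphi = self.d(phi)
        att = sigmoid(self.fc2(relu(self.fc1(global_avg_pool(dphi)))))
        self.last_attention = att.data.copy()
        return scale_channels(dphi, att) + dphi


# ---------------------------------------------------------------------------
# assembled network
# ---------------------------------------------------------------------------


class ACU2Net(Module):
    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        cfg.validate()
        rng = np.random.default_rng(seed)
        self.config = cfg
        enc_specs, dec_specs = cfg.backbone.encoders, cfg.backbone.decoders
        self.encoders = [RSU(s.rsu, rng=rng) for s in enc_specs]
        enc_out = [s.rsu.out_channels for s in enc_specs]

        # skip depth k = 5..1: shallow = Encoder k, deep = upsampled deeper
        self.gcms: list[GCM | None] = []
        self.decoders = []
        deep = enc_out[5]
        carry_ch = None
        for spec, k in zip(dec_specs, range(5, 0, -1)):
            c_s = enc_out[k - 1]
            if cfg.use_gcm:
                n = cfg.gcm.groups_by_depth.get(k)
                if n is None:
                    raise ConfigError(f"no GCM group count configured for skip depth {k}")
                try:
                    gcm = GCM(
                        c_s, deep, n,
                        carry_channels=carry_ch if cfg.gcm.serial_link else None,
                        rng=rng,
                    )
                except ConfigError as e:
                    raise ConfigError(f"{spec.name} skip (depth {k}): {e}") from e
                self.gcms.append(gcm)
                dec_in = gcm.out_channels
                carry_ch = gcm.out_channels
            else:
                self.gcms.append(None)
                dec_in = c_s + deep
            rsu_cfg = RSUConfig(
                spec.rsu.level, dec_in, spec.rsu.mid_channels,
                spec.rsu.out_channels, spec.rsu.dilated,
            )
            self.decoders.append(RSU(rsu_cfg, rng=rng))
            deep = spec.rsu.out_channels

        # six side heads: Encoder6 then Decoder5..Decoder1
        side_src = [enc_out[5]] + [s.rsu.out_channels for s in dec_specs]
        self.side_convs = [Conv2d(c, 1, k=3, rng=rng) for c in side_src]
        self.fuse_conv = Conv2d(6, 1, k=1, rng=rng)

        if cfg.use_rag:
            skip1_ch = self.decoders[-1].cfg.in_channels
            g_ch = dec_specs[3].rsu.out_channels  # Decoder2 output
            self.rag = RAG(skip1_ch, g_ch, cfg.rag, rng=rng)
            self.rag_classifier = Conv2d(self.rag.inter, 1, k=1, rng=rng)
        else:
            self.rag = None
            self.rag_classifier = None

    # -- forward ------------------------------------------------------------

    def forward(self, x: Tensor) -> dict:
        """Full forward pass.

        Returns a dict with sigmoid maps ``fused`` and ``sides`` (list of 6,
        order O6..O1), the corresponding logits, and ``stages`` mapping all
        11 stage names to their output tensors.
        """
        B, C, H, W = x.data.shape
        if H % 32 or W % 32:
            raise ValueError(f"input spatial size must be divisible by 32, got {H}x{W}")
        cfg = self.config

        stages: dict[str, Tensor] = {}
        enc_feats = []
        h = x
        for i, enc in enumerate(self.encoders):
            h = enc(h)
            enc_feats.append(h)
            stages[f"Encoder{i + 1}"] = h
            if i < 5:
                h = maxpool2(h)

        deep = enc_feats[5]
        carry = None
        skip1 = None
        for idx, k in enumerate(range(5, 0, -1)):
            shallow = enc_feats[k - 1]
            th, tw = shallow.data.shape[2:]
            deep_up = resize_bilinear(deep, th, tw)
            gcm = self.gcms[idx]
            if gcm is not None:
                skipped = gcm(shallow, deep_up, carry if cfg.gcm.serial_link else None)
                carry = skipped
            else:
                skipped = concat([deep_up, shallow], axis=1)
            if k == 1:
                skip1 = skipped
            deep = self.decoders[idx](skipped)
            stages[f"Decoder{k}"] = deep

        side_feats = [stages["Encoder6"]] + [stages[f"Decoder{k}"] for k in range(5, 0, -1)]
        side_logits = [
            resize_bilinear(conv(f), H, W) for conv, f in zip(self.side_convs, side_feats)
        ]
        splice_logit = self.fuse_conv(concat(side_logits, axis=1))

        if self.rag is not None:
            o_f = self.rag(skip1, stages["Decoder2"])
            o_f = dropout(o_f, cfg.dropout_p, self.training)
            rag_logit = self.rag_classifier(o_f)
            if cfg.fuse_mode == "average":
                fused_logit = (splice_logit + rag_logit) * 0.5
            elif cfg.fuse_mode == "rag":
                fused_logit = rag_logit
            else:
                fused_logit = splice_logit
        else:
            # the splice conv is the final classifier here; dropout precedes it
            dropped = dropout(concat(side_logits, axis=1), cfg.dropout_p, self.training)
            fused_logit = self.fuse_conv(dropped)

        return {
            "fused": sigmoid(fused_logit),
            "sides": [sigmoid(l) for l in side_logits],
            "fused_logit": fused_logit,
            "side_logits": side_logits,
            "stages": stages,
        }

    __call__ = forward


def assemble_acu2net(cfg: NetworkConfig, seed: int = 0) -> ACU2Net:
    return ACU2Net(cfg, seed=seed)


def forward_backbone(model: ACU2Net, image: np.ndarray) -> dict[str, StageFeature]:
    """Run one image (3xHxW, float) through the network; return all 11 stages."""
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError(f"expected a 3xHxW image, got shape {image.shape}")
    model.eval()
    with nn.no_grad():
        out = model(Tensor(image[None].astype(np.float32)))
    return {
        name: StageFeature(t.data[0].copy(), name) for name, t in out["stages"].items()
    }


def stage_table(cfg: NetworkConfig, input_hw: tuple[int, int] | None = None) -> list[dict]:
    """Analytic stage table (name, input/output C x H x W) for inspection."""
    if input_hw is None:
        input_hw = cfg.backbone.input_size[1:]
    H, W = input_hw
    rows = []
    c_prev, h, w = 3, H, W
    enc_out = []
    for spec in cfg.backbone.encoders:
        rows.append(
            {"name": spec.name, "in": (c_prev, h, w), "out": (spec.rsu.out_channels, h, w),
             "resize": spec.resize}
        )
        enc_out.append((spec.rsu.out_channels, h, w))
        if spec.resize == "maxpool2":
            h, w = (h + 1) // 2, (w + 1) // 2
        c_prev = spec.rsu.out_channels
    deep = enc_out[5][0]
    for spec, k in zip(cfg.backbone.decoders, range(5, 0, -1)):
        c_s, sh, sw = enc_out[k - 1]
        c_in = (c_s + deep) // 2 if cfg.use_gcm else c_s + deep
        rows.append(
            {"name": spec.name, "in": (c_in, sh, sw), "out": (spec.rsu.out_channels, sh, sw),
             "resize": spec.resize}
        )
        deep = spec.rsu.out_channels
    side_src = [enc_out[5]] + [
        (spec.rsu.out_channels,) + enc_out[k - 1][1:]
        for spec, k in zip(cfg.backbone.decoders, range(5, 0, -1))
    ]
    for i, (c, sh, sw) in enumerate(side_src):
        rows.append({"name": f"O{6 - i}", "in": (c, sh, sw), "out": (1, sh, sw),
                     "resize": "conv+sigmoid"})
    return rows
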