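"""Dual-stream fusion classifiers for distance/Doppler image pairs.

Both models extract modality-specific features with separate CNN blocks —
the distance stream maps a 1x96x288 image to a 128x12x36 feature block via
three (conv, batch-norm, ReLU, 2x2 max-pool) stages; the shallower Doppler
stream maps 1x50x80 to 128x12x20 via two stages (odd dimensions pool with
floor division: 50 -> 25 -> 12).

*ConcatFusion* globally average-pools each block to a 128-vector and
classifies the 256-long concatenation [z_d; z_v] with an MLP.

*AttnFusion* adaptively average-pools each block to 128x4x10, refines both
with a (weight-shared) spatial attention mask sigma(conv3x3([avg_c; max_c]))
in (0,1)^{1x4x10}, concatenates the refined maps channel-wise to 256x4x10,
applies a convolutional fusion block (3x3 conv to 512 channels + batch norm
+ ReLU), and classifies the globally pooled 512-vector with an MLP.

Only the boundary shapes above are fixed by the method; channel plans,
normalization, dropout and classifier widths are configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn
from .radar_io import CLASSES

#: Canonical input shapes (channels, height, width).
DISTANCE_SHAPE = (1, 96, 288)
DOPPLER_SHAPE = (1, 50, 80)


@dataclass
class SamplePair:
    """One dual-modality classifier input: X = (X_d, X_v) with label y."""

    xd: np.ndarray  # (1, 96, 288) float32 in [0, 1]
    xv: np.ndarray  # (1, 50, 80) float32 in [0, 1]
    y: int  # index into radar_io.CLASSES
    participant_id: Optional[str] = None

    @classmethod
    def from_images(cls, distance_image, doppler_image) -> "SamplePair":
        """Build a pair from the two 8-bit images (pixels scaled to [0, 1])."""
        if distance_image.class_label != doppler_image.class_label:
            raise ValueError("modality class labels disagree")
        return cls(
            xd=(distance_image.pixels[None].astype(np.float32) / 255.0),
            xv=(doppler_image.pixels[None].astype(np.float32) / 255.0),
            y=CLASSES.index(distance_image.class_label),
            participant_id=distance_image.participant_id,
        )


@dataclass
class ModelConfig:
    """Architecture configuration; defaults give the published shapes."""

    distance_channels: tuple[int, ...] = (32, 64, 128)
    doppler_channels: tuple[int, ...] = (64, 128)
    pooled_size: tuple[int, int] = (4, 10)
    fusion_channels: int = 512
    classifier_hidden: int = 128
    dropout: float = 0.3
    n_classes: int = 5
    shared_attention: bool = True
    seed: int = 0

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "ModelConfig":
        """Leaner channel plan for CPU-only desk-scale runs.

        All published boundary shapes (Fd 128x12x36, Fv 128x12x20, z=256,
        mask 1x4x10, fused 256x4x10, z=512) are unchanged; only the widths
        of the hidden stream stages shrink, cutting the convolution cost
        roughly fourfold.
        """
        return cls(distance_channels=(16, 32, 128), doppler_channels=(32, 128),
                   seed=seed)


def _stream(channels: tuple[int, ...], rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Module] = []
    cin = 1
    for cout in channels:
        layers += [nn.Conv2d(cin, cout, rng), nn.BatchNorm2d(cout),
                   nn.ReLU(), nn.MaxPool2d()]
        cin = cout
    layers[0].skip_input_grad = True  # stream input needs no gradient
    return nn.Sequential(*layers)


def _batchify(x: np.ndarray, shape: tuple[int, int, int], name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[1:] != shape:
        raise ValueError(f"{name}: expected shape {shape} (optionally batched), "
                         f"got {x.shape}")
    return x


class _FusionBase:
    """Shared stream plumbing for the two fusion models."""

    def __init__(self, config: Optional[ModelConfig] = None):
        self.config = config or ModelConfig()
        self.rng = np.random.default_rng(self.config.seed)
        self.stream_d = _stream(self.config.distance_channels, self.rng)
        self.stream_v = _stream(self.config.doppler_channels, self.rng)

    # -- parameter bookkeeping -------------------------------------------
    def _modules(self) -> list[nn.Module]:
        raise NotImplementedError

    def params(self) -> list[nn.Param]:
        seen: dict[int, nn.Param] = {}
        for m in self._modules():
            for p in m.params():
                seen.setdefault(id(p), p)
        return list(seen.values())

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def free_caches(self) -> None:
        """Release activation caches held by the layers (parameters stay)."""
        for m in self._modules():
            m.free_caches()
        for attr in ("gap", "gap_d", "gap_v", "pool_d", "pool_v", "fusion"):
            layer = getattr(self, attr, None)
            if layer is not None:
                layer.free_caches()
        if hasattr(self, "_cache"):
            self._cache = None

    def _bn_layers(self) -> list[nn.BatchNorm2d]:
        out = []
        for m in self._modules():
            layers = m.layers if isinstance(m, nn.Sequential) else [m]
            out += [l for l in layers if isinstance(l, nn.BatchNorm2d)]
        return out

    def snapshot(self) -> dict:
        return {
            "params": [p.value.copy() for p in self.params()],
            "bn": [(b.running_mean.copy(), b.running_var.copy())
                   for b in self._bn_layers()],
        }

    def restore(self, snap: dict) -> None:
        for p, v in zip(self.params(), snap["params"]):
            p.value[...] = v
        for b, (m, v) in zip(self._bn_layers(), snap["bn"]):
            b.running_mean[...] = m
            b.running_var[...] = v

    # -- stream features --------------------------------------------------
    def distance_stream(self, xd: np.ndarray, train: bool = False) -> np.ndarray:
        """Fd = f_d(Xd): (N, 128, 12, 36) for the canonical input."""
        return self.stream_d.forward(_batchify(xd, DISTANCE_SHAPE, "Xd"), train)

    def doppler_stream(self, xv: np.ndarray, train: bool = False) -> np.ndarray:
        """Fv = f_v(Xv): (N, 128, 12, 20) for the canonical input."""
        return self.stream_v.forward(_batchify(xv, DOPPLER_SHAPE, "Xv"), train)


class ConcatFusion(_FusionBase):
    """Baseline: global average pooling per stream + embedding concatenation."""

    def __init__(self, config: Optional[ModelConfig] = None):
        super().__init__(config)
        cfg = self.config
        embed = cfg.distance_channels[-1] + cfg.doppler_channels[-1]  # 256
        self.gap_d = nn.GlobalAvgPool()
        self.gap_v = nn.GlobalAvgPool()
        self.mlp = nn.Sequential(
            nn.Linear(embed, cfg.classifier_hidden, self.rng),
            nn.ReLU(),
            nn.Dropout(cfg.dropout, self.rng),
            nn.Linear(cfg.classifier_hidden, cfg.n_classes, self.rng),
        )
        self._embed = embed

    def _modules(self):
        return [self.stream_d, self.stream_v, self.mlp]

    def forward(self, xd, xv, train: bool = False, return_features: bool = False):
        fd = self.distance_stream(xd, train)
        fv = self.doppler_stream(xv, train)
        zd = self.gap_d.forward(fd, train)  # (N, 128)
        zv = self.gap_v.forward(fv, train)
        z = np.concatenate([zd, zv], axis=1)  # (N, 256)
        logits = self.mlp.forward(z, train)
        if return_features:
            return logits, {"Fd": fd, "Fv": fv, "zd": zd, "zv": zv, "z": z}
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.mlp.backward(dlogits)
        nd = self.config.distance_channels[-1]
        self.stream_d.backward(self.gap_d.backward(dz[:, :nd]))
        self.stream_v.backward(self.gap_v.backward(dz[:, nd:]))


class AttnFusion(_FusionBase):
    """Spatial attention + convolutional fusion of the two streams."""

    def __init__(self, config: Optional[ModelConfig] = None):
        super().__init__(config)
        cfg = self.config
        self.pool_d = nn.AdaptiveAvgPool2d(cfg.pooled_size)
        self.pool_v = nn.AdaptiveAvgPool2d(cfg.pooled_size)
        self.attn_d = nn.SpatialAttention(self.rng)
        self.attn_v = nn.SpatialAttention(self.rng)
        if cfg.shared_attention:
            # one shared 3x3 conv used by both streams
            self.attn_v.conv.w = self.attn_d.conv.w
            self.attn_v.conv.b = self.attn_d.conv.b
        fused_in = cfg.distance_channels[-1] + cfg.doppler_channels[-1]  # 256
        self.fusion = nn.Sequential(
            nn.Conv2d(fused_in, cfg.fusion_channels, self.rng),
            nn.BatchNorm2d(cfg.fusion_channels),
            nn.ReLU(),
        )
        self.gap = nn.GlobalAvgPool()
        self.mlp = nn.Sequential(
            nn.Linear(cfg.fusion_channels, cfg.classifier_hidden, self.rng),
            nn.ReLU(),
            nn.Dropout(cfg.dropout, self.rng),
            nn.Linear(cfg.classifier_hidden, cfg.n_classes, self.rng),
        )
        self._fused_in = fused_in
        #: test hook: when set, replaces both attention masks in forward
        self.mask_override: Optional[np.ndarray] = None

    def _modules(self):
        return [self.stream_d, self.stream_v, self.attn_d, self.attn_v,
                self.fusion, self.mlp]

    def spatial_attention(self, f: np.ndarray, stream: str = "d") -> np.ndarray:
        """Attention mask M_s(F) in (0,1)^{N x 1 x 4 x 10} for pooled features."""
        attn = self.attn_d if stream == "d" else self.attn_v
        return attn.forward(np.asarray(f, dtype=np.float32), train=False)

    def forward(self, xd, xv, train: bool = False, return_features: bool = False):
        fd = self.distance_stream(xd, train)
        fv = self.doppler_stream(xv, train)
        fdp = self.pool_d.forward(fd, train)  # (N, 128, 4, 10)
        fvp = self.pool_v.forward(fv, train)
        if self.mask_override is not None:
            md = np.broadcast_to(self.mask_override, fdp[:, :1].shape)
            mv = np.broadcast_to(self.mask_override, fvp[:, :1].shape)
        else:
            md = self.attn_d.forward(fdp, train)  # (N, 1, 4, 10)
            mv = self.attn_v.forward(fvp, train)
        fda = fdp * md
        fva = fvp * mv
        fused = np.concatenate([fda, fva], axis=1)  # (N, 256, 4, 10)
        g = self.fusion.forward(fused, train)
        z = self.gap.forward(g, train)  # (N, 512)
        logits = self.mlp.forward(z, train)
        self._cache = (fdp, fvp, md, mv)
        if return_features:
            return logits, {
                "Fd": fd, "Fv": fv, "Fd_pool": fdp, "Fv_pool": fvp,
                "mask_d": md, "mask_v": mv, "Fd_attn": fda, "Fv_attn": fva,
                "F_fused": fused, "z": z,
            }
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        fdp, fvp, md, mv = self._cache
        dz = self.mlp.backward(dlogits)
        dfused = self.fusion.backward(self.gap.backward(dz))
        nd = self.config.distance_channels[-1]
        dfda, dfva = dfused[:, :nd], dfused[:, nd:]
        # product rule through F_pool * mask, then through the attention head
        dfdp = dfda * md + self.attn_d.backward((dfda * fdp).sum(axis=1, keepdims=True))
        dfvp = dfva * mv + self.attn_v.backward((dfva * fvp).sum(axis=1, keepdims=True))
        self.stream_d.backward(self.pool_d.backward(dfdp))
        self.stream_v.backward(self.pool_v.backward(dfvp))


def make_model(name: str, config: Optional[ModelConfig] = None):
    """Factory: ``name`` is ``"concat"`` or ``"attn"``."""
    if name == "concat":
        return ConcatFusion(config)
    if name == "attn":
        return AttnFusion(config)
    raise ValueError(f"unknown model {name!r}; expected 'concat' or 'attn'")
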