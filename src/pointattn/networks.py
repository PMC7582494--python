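"""Classification and part-segmentation architectures.

The trunk is one CW-EdgeConv++ layer (which also emits the 10-channel
geometric descriptor for the global attention module) followed by three
CW-EdgeConv layers. Layer outputs are concatenated into a per-point global
feature g, the soft attention mask reweights it, and task heads consume the
masked feature g_m: max+avg pooling and a 3-layer MLP for classification, a
per-point 4-layer MLP with tiled category one-hot for segmentation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import PointCloud
from .layers import (BatchNorm, Dropout, EdgeConvBlock,
                     GlobalAttentionHead, GlobalFeatureBlock, Linear, Module,
                     ModuleList, activation_fn)

__all__ = [
    "ClassifierConfig", "SegmenterConfig", "ModelState",
    "Classifier", "Segmenter",
    "build_classifier", "build_segmenter",
    "classify_forward", "segment_forward", "export_attention",
    "save_model", "load_model",
]


@dataclass
class ClassifierConfig:
    layer_channels: tuple[int, ...] = (64, 64, 128, 256)
    k: int = 20
    global_dim: int = 1024
    head_width: int = 512
    reduction: int = 2            # head widths are (C, C/R, m)
    n_classes: int = 40
    dropout: float = 0.5
    pooling: str = "max_avg"      # or "max"
    activation: str = "leaky"     # or "relu"
    graph: str = "features"       # dynamic graph; "coords" fixes it
    global_inputs: str = "all"    # concat all layers; "last" = 4th only
    attention: str = "soft"       # "soft" | "hard" | "none"
    channel_gates: bool = True    # SE gates inside every CW-EdgeConv
    attn_hidden: int = 64
    batchnorm: bool = True

    @property
    def pooled_dim(self) -> int:
        return (2 if self.pooling == "max_avg" else 1) * self.global_dim


@dataclass
class SegmenterConfig(ClassifierConfig):
    n_categories: int = 16
    part_channels: tuple[int, ...] = (256, 256, 128)
    n_parts: int = 50


class _Trunk(Module):
    """Shared feature extractor: CW-EdgeConv++ then CW-EdgeConv stack,
    global feature and the global attention mask."""

    def __init__(self, cfg: ClassifierConfig, rng: np.random.Generator):
        super().__init__()
        chans = cfg.layer_channels
        blocks = []
        cin = 3
        for i, cout in enumerate(chans):
            blocks.append(EdgeConvBlock(
                cin, cout, cfg.k, rng, gated=cfg.channel_gates,
                activation=cfg.activation,
                graph="coords" if i == 0 else cfg.graph,
                batchnorm=cfg.batchnorm))
            cin = cout
        self.blocks = ModuleList(blocks)
        g_in = sum(chans) if cfg.global_inputs == "all" else chans[-1]
        self.global_block = GlobalFeatureBlock(g_in, cfg.global_dim, rng,
                                               cfg.activation)
        self.attn = GlobalAttentionHead(rng, hidden=cfg.attn_hidden,
                                        activation=cfg.activation)
        self.cfg = cfg

    def forward(self, coords: np.ndarray):
        """Returns (g_m, mask) for a (B, N, 3) coordinate stack."""
        from .layers import batch_geometric_descriptor

        cfg = self.cfg
        x = Tensor(coords)
        outputs = []
        desc = None
        for i, block in enumerate(self.blocks):
            x = block(x, coords)
            if i == 0:
                # CW-EdgeConv++: reuse the first grouping for the descriptor
                desc = Tensor(batch_geometric_descriptor(
                    coords, block.last_idx).astype(coords.dtype))
            outputs.append(x)
        feats = (ad.concat(outputs, axis=-1) if cfg.global_inputs == "all"
                 else outputs[-1])
        g = self.global_block(feats)
        B, N, Cg = g.shape
        if cfg.attention == "soft":
            mask = self.attn.soft(desc)
            g_m = ad.relu(g * ad.reshape(mask, (B, N, 1)))
        elif cfg.attention == "hard":
            hard = self.attn.hard(desc)
            mask = Tensor(hard.astype(coords.dtype))
            g_m = ad.relu(g * ad.reshape(mask, (B, N, 1)))
        else:
            mask = Tensor(np.ones((B, N), dtype=coords.dtype))
            g_m = ad.relu(g)
        return g_m, mask

    __call__ = forward


class _MLPHead(Module):
    """Stack of Linear+BN+activation(+dropout) ending in a plain Linear."""

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 activation: str, dropout: float, n_dropout: int):
        super().__init__()
        layers = []
        for i in range(len(widths) - 2):
            layers.append(Linear(widths[i], widths[i + 1], rng))
            layers.append(BatchNorm(widths[i + 1]))
            if i < n_dropout:
                layers.append(Dropout(dropout))
        layers.append(Linear(widths[-2], widths[-1], rng))
        self.layers = ModuleList(layers)
        self.act = activation

    def forward(self, x: Tensor) -> Tensor:
        act = activation_fn(self.act)
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                x = act(layer(x))
            else:
                x = layer(x)
        return x

    __call__ = forward


class Classifier(Module):
    def __init__(self, cfg: ClassifierConfig, rng: np.random.Generator):
        super().__init__()
        self.trunk = _Trunk(cfg, rng)
        C, R = cfg.head_width, cfg.reduction
        self.head = _MLPHead([cfg.pooled_dim, C, C // R, cfg.n_classes],
                             rng, cfg.activation, cfg.dropout, n_dropout=2)
        self.cfg = cfg

    def forward(self, coords: np.ndarray) -> Tensor:
        g_m, _ = self.trunk(coords)
        pooled = ad.tmax(g_m, axis=1)
        if self.cfg.pooling == "max_avg":
            pooled = ad.concat([pooled, ad.tmean(g_m, axis=1)], axis=-1)
        return self.head(pooled)

    __call__ = forward


class Segmenter(Module):
    def __init__(self, cfg: SegmenterConfig, rng: np.random.Generator):
        super().__init__()
        self.trunk = _Trunk(cfg, rng)
        cin = cfg.n_categories + 2 * cfg.global_dim
        widths = [cin, *cfg.part_channels, cfg.n_parts]
        self.head = _MLPHead(widths, rng, cfg.activation, cfg.dropout,
                             n_dropout=2)
        self.cfg = cfg

    def forward(self, coords: np.ndarray, onehot: np.ndarray) -> Tensor:
        onehot = np.asarray(onehot, dtype=coords.dtype)
        if onehot.ndim == 1:
            onehot = onehot[None]
        if not np.allclose(onehot.sum(axis=-1), 1.0):
            raise ValueError("category one-hot must sum to 1")
        g_m, _ = self.trunk(coords)
        B, N, Cg = g_m.shape
        pooled = ad.relu(ad.tmax(g_m, axis=1))                    # (B, Cg)
        tiled_pool = ad.broadcast_to(ad.reshape(pooled, (B, 1, Cg)),
                                     (B, N, Cg))
        cat = Tensor(np.broadcast_to(onehot[:, None, :],
                                     (B, N, onehot.shape[-1])))
        feats = ad.concat([cat, g_m, tiled_pool], axis=-1)
        return self.head(feats)

    __call__ = forward


@dataclass
class ModelState:
    """A built network plus its architecture config and RNG seed record."""

    module: Module
    config: ClassifierConfig
    task: str                     # "classify" | "segment"
    seed: int = 0
    epoch_log: list = field(default_factory=list)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.module.parameters()))


def build_classifier(cfg: ClassifierConfig | None = None, seed: int = 0,
                     dtype=np.float64) -> ModelState:
    cfg = cfg or ClassifierConfig()
    rng = np.random.default_rng(seed)
    module = Classifier(cfg, rng).astype(dtype)
    return ModelState(module, cfg, task="classify", seed=seed)


def build_segmenter(cfg: SegmenterConfig | None = None, seed: int = 0,
                    dtype=np.float64) -> ModelState:
    cfg = cfg or SegmenterConfig()
    rng = np.random.default_rng(seed)
    module = Segmenter(cfg, rng).astype(dtype)
    return ModelState(module, cfg, task="segment", seed=seed)


def _as_batch(cloud: PointCloud, model: ModelState) -> np.ndarray:
    dtype = next(iter(model.module.parameters())).dtype
    coords = cloud.coords.astype(dtype)[None]
    if cloud.n_points < model.config.k:
        raise ValueError("cloud has fewer points than the group size k")
    return coords


def classify_forward(cloud: PointCloud, model: ModelState) -> np.ndarray:
    """Class logits (m,) for one cloud, inference mode."""
    if model.task != "classify":
        raise ValueError("model is not a classifier")
    model.module.eval()
    return model.module(_as_batch(cloud, model)).data[0]


def segment_forward(cloud: PointCloud, category_onehot: np.ndarray,
                    model: ModelState) -> np.ndarray:
    """Per-point part logits (N, P) for one cloud, inference mode."""
    if model.task != "segment":
        raise ValueError("model is not a segmenter")
    model.module.eval()
    return model.module(_as_batch(cloud, model),
                        np.asarray(category_onehot)).data[0]


def export_attention(cloud: PointCloud, model: ModelState) -> np.ndarray:
    """The soft global-attention weights (N,) in (0,1) for one cloud."""
    model.module.eval()
    g_m, mask = model.module.trunk(_as_batch(cloud, model))
    return np.asarray(mask.data[0], dtype=float)


# ---------------------------------------------------------------------------
# checkpointing

def save_model(model: ModelState, path) -> None:
    """Single-file checkpoint: weights + buffers + config + seed."""
    meta = {
        "task": model.task,
        "seed": model.seed,
        "config": dataclasses.asdict(model.config),
        "epoch_log": model.epoch_log,
    }
    payload = dict(model.module.state_dict())
    payload["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_model(path) -> ModelState:
    with np.load(path) as data:
        arrays = {n: data[n] for n in data.files}
    meta = json.loads(bytes(arrays.pop("__meta__")).decode())
    cfg_dict = dict(meta["config"])
    for key in ("layer_channels", "part_channels"):
        if key in cfg_dict:
            cfg_dict[key] = tuple(cfg_dict[key])
    if meta["task"] == "classify":
        cfg = ClassifierConfig(**cfg_dict)
        model = build_classifier(cfg, seed=meta["seed"])
    else:
        cfg = SegmenterConfig(**cfg_dict)
        model = build_segmenter(cfg, seed=meta["seed"])
    model.module.load_state_dict(arrays)
    dtype = arrays[next(n for n in arrays if not n.startswith("buffer:"))].dtype
    model.module.astype(dtype)
    model.epoch_log = list(meta.get("epoch_log", []))
    return model
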