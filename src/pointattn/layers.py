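"""Learnable blocks: SE channel gates, CW-EdgeConv, global feature and the
three attention mechanisms (soft global mask, hard global mask, spatial
attention inside EdgeConv).

Two surfaces are exposed. The ``Module`` classes operate on batched
``autodiff.Tensor`` stacks (B, N, ..., C) and are what the network trains.
The lower-case functions mirror them on a single in-memory cloud (NumPy in,
NumPy out, inference mode) and are the convenient unit-test/analysis API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import (GroupedFeature, NeighborhoodIndex, batch_knn,
                       geometric_descriptor)

__all__ = [
    "Module", "ModuleList", "Linear", "BatchNorm", "Dropout", "ChannelGate",
    "EdgeConvBlock", "GlobalAttentionHead", "SpatialAttentionEdgeConv",
    "GlobalFeatureBlock", "AttentionMask",
    "se_gate", "cw_edgeconv", "cw_edgeconv_pp", "global_feature",
    "global_attention_mask", "hard_attention_mask",
    "spatial_attention_edgeconv", "apply_mask", "activation_fn",
]


def activation_fn(tag: str):
    if tag == "leaky":
        return lambda t: ad.leaky_relu(t, 0.2)
    if tag == "relu":
        return ad.relu
    raise ValueError(f"unknown activation '{tag}'")


# ---------------------------------------------------------------------------
# module system

class Module:
    """Tiny parameter-tree base class (explicit, NumPy-backed)."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", False)

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = name
        object.__setattr__(self, name, np.asarray(value))

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + n: p for n, p in self._params.items()}
        for n, m in self._modules.items():
            out.update(m.named_parameters(prefix + n + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + n: getattr(self, n) for n in self._buffers}
        for n, m in self._modules.items():
            out.update(m.named_buffers(prefix + n + "."))
        return out

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def astype(self, dtype):
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for name, mod in self._walk():
            for bname in mod._buffers:
                arr = getattr(mod, bname)
                if np.issubdtype(arr.dtype, np.floating):
                    object.__setattr__(mod, bname, arr.astype(dtype))
        return self

    def _walk(self, prefix: str = ""):
        yield prefix, self
        for n, m in self._modules.items():
            yield from m._walk(prefix + n + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {n: p.data for n, p in self.named_parameters().items()}
        out.update({"buffer:" + n: b for n, b in self.named_buffers().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        for name, arr in state.items():
            if name.startswith("buffer:"):
                bname = name[len("buffer:"):]
                *path, leaf = bname.split(".")
                mod = self
                for p in path:
                    mod = mod._modules[p]
                object.__setattr__(mod, leaf, np.asarray(arr).copy())
            else:
                if name not in params:
                    raise KeyError(f"unexpected parameter '{name}'")
                params[name].data = np.asarray(arr).copy()
        return self


class ModuleList(Module):
    def __init__(self, modules):
        super().__init__()
        self._items = list(modules)
        for i, m in enumerate(self._items):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def __len__(self):
        return len(self._items)


class Linear(Module):
    """Dense map on the last axis; equivalent to a 1x1 shared convolution."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = np.sqrt(6.0 / cin)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(cin, cout)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        shape = x.shape
        flat = ad.reshape(x, (-1, shape[-1]))
        out = ad.matmul(flat, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return ad.reshape(out, shape[:-1] + (self.weight.shape[1],))

    __call__ = forward


class BatchNorm(Module):
    """Batch normalization over every axis except the trailing channel."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = ad.batch_norm_train(x, self.gamma, self.beta,
                                               self.eps)
            m = self.momentum
            n = x.data.size // x.shape[-1]
            unbias = n / max(n - 1, 1)
            object.__setattr__(self, "running_mean",
                               (1 - m) * self.running_mean + m * mu)
            object.__setattr__(self, "running_var",
                               (1 - m) * self.running_var + m * unbias * var)
            return out
        # inference: a constant per-channel affine map (no backprop needed)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = Tensor((self.gamma.data * inv).astype(x.dtype))
        shift = Tensor((self.beta.data
                        - self.running_mean * inv * self.gamma.data
                        ).astype(x.dtype))
        return x * scale + shift

    __call__ = forward


class Dropout(Module):
    def __init__(self, p: float = 0.5):
        super().__init__()
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        rng = self.rng if self.rng is not None else np.random.default_rng()
        keep = (rng.random(x.shape) >= self.p).astype(x.dtype)
        return x * Tensor(keep / (1.0 - self.p))

    __call__ = forward


def seed_dropout(root: Module, rng: np.random.Generator):
    """Point every Dropout in the tree at one shared generator."""
    for _, m in root._walk():
        if isinstance(m, Dropout):
            m.rng = rng


# ---------------------------------------------------------------------------
# channel gate (squeeze-and-excitation, full width)

class ChannelGate(Module):
    """Two-stage per-channel recalibration: squeeze (mean over all spatial
    axes per sample) -> full-width excitation -> sigmoid scalar in (0,1).

    No bottleneck reduction: both excitation stages keep the layer's
    channel count.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 activation: str = "leaky"):
        super().__init__()
        self.fc1 = Linear(channels, channels, rng)
        self.fc2 = Linear(channels, channels, rng)
        self.act = activation
        self.channels = channels
        self.identity = False  # diagnostics: bypass gating entirely

    def scalars(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.channels:
            raise ValueError("channel count does not match gate")
        axes = tuple(range(1, x.ndim - 1))  # keep batch and channel
        squeezed = ad.tmean(x, axis=axes) if axes else x
        act = activation_fn(self.act)
        return ad.sigmoid(self.fc2(act(self.fc1(squeezed))))

    def forward(self, x: Tensor) -> Tensor:
        if self.identity:
            return x
        s = self.scalars(x)
        shape = (x.shape[0],) + (1,) * (x.ndim - 2) + (self.channels,)
        return x * ad.reshape(s, shape)

    __call__ = forward


# ---------------------------------------------------------------------------
# edge convolution blocks

def batch_geometric_descriptor(coords: np.ndarray, idx: np.ndarray,
                               with_distance: bool = True) -> np.ndarray:
    """Batched fixed descriptor [x_i, x_j, x_j-x_i (,dist)]: (B,N,k,10|9)."""
    B = coords.shape[0]
    batch = np.arange(B)[:, None, None]
    xj = coords[batch, idx]
    xi = np.broadcast_to(coords[:, :, None, :], xj.shape)
    diff = xj - xi
    parts = [xi, xj, diff]
    if with_distance:
        parts.append(np.linalg.norm(diff, axis=-1, keepdims=True))
    return np.concatenate(parts, axis=-1)


class EdgeConvBlock(Module):
    """(CW-)EdgeConv: kNN grouping, shared MLP on edge pairs, optional SE
    channel gate, max aggregation over the group axis.

    ``graph`` picks the metric space of the kNN query: 'features' recomputes
    the graph in the current feature space (dynamic graph), 'coords' fixes
    it on input coordinates.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 gated: bool = True, activation: str = "leaky",
                 graph: str = "features", batchnorm: bool = True):
        super().__init__()
        # the shared MLP h((x_j - x_i, x_i)) splits into two per-point
        # products: h = (x_j - x_i) @ W_diff + x_i @ W_center + b, and
        # gather(x) @ W == gather(x @ W), so the dense work is O(N) not O(Nk)
        self.mlp_diff = Linear(cin, cout, rng, bias=False)
        self.mlp_center = Linear(cin, cout, rng)
        self.bn = BatchNorm(cout) if batchnorm else None
        self.gate = ChannelGate(cout, rng, activation) if gated else None
        self.k = k
        self.act = activation
        self.graph = graph
        self.last_idx: np.ndarray | None = None

    def group(self, x: Tensor, coords: np.ndarray) -> np.ndarray:
        basis = x.data if self.graph == "features" else coords
        idx = batch_knn(basis, self.k)
        self.last_idx = idx
        return idx

    def forward(self, x: Tensor, coords: np.ndarray,
                idx: np.ndarray | None = None) -> Tensor:
        if idx is None:
            idx = self.group(x, coords)
        h = ad.edge_combine(self.mlp_diff(x), self.mlp_center(x), idx)
        if self.bn is not None:
            h = self.bn(h)
        h = activation_fn(self.act)(h)
        if self.gate is not None:
            h = self.gate(h)
        return ad.tmax(h, axis=2)

    __call__ = forward


class GlobalAttentionHead(Module):
    """Point-wise soft/hard attention from the 10-channel group descriptor.

    Two shared 1x1 stages reduce 10 -> hidden -> 1; sigmoid keeps responses
    in (0,1). Soft mode takes the max response over the group, hard mode
    thresholds the group-mean response at 0.5 (inclusive).
    """

    def __init__(self, rng: np.random.Generator, hidden: int = 64,
                 activation: str = "leaky", in_channels: int = 10):
        super().__init__()
        self.fc1 = Linear(in_channels, hidden, rng)
        self.bn = BatchNorm(hidden)
        self.fc2 = Linear(hidden, 1, rng)
        self.act = activation
        self.in_channels = in_channels

    def responses(self, desc: Tensor) -> Tensor:
        if desc.shape[-1] != self.in_channels:
            raise ValueError(
                f"descriptor must have {self.in_channels} channels")
        act = activation_fn(self.act)
        h = act(self.bn(self.fc1(desc)))
        return ad.sigmoid(self.fc2(h))          # (B,N,k,1)

    def soft(self, desc: Tensor) -> Tensor:
        r = self.responses(desc)
        return ad.reshape(ad.tmax(r, axis=2), desc.shape[:2])   # (B,N)

    def hard(self, desc: Tensor) -> np.ndarray:
        r = self.responses(desc)
        mean = ad.tmean(r, axis=2).data.reshape(desc.shape[:2])
        return (mean >= 0.5).astype(float)

    __call__ = soft


class SpatialAttentionEdgeConv(Module):
    """Plain EdgeConv modulated by a point-wise soft mask computed from the
    9-channel spatial descriptor (no distance channel: its gradient is
    unstable and blows up in training)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 activation: str = "leaky", graph: str = "features"):
        super().__init__()
        self.edge = EdgeConvBlock(cin, cout, k, rng, gated=False,
                                  activation=activation, graph=graph)
        self.mask_mlp = Linear(9, 1, rng)
        self.mask_bn = BatchNorm(1)

    def mask(self, coords: np.ndarray, idx: np.ndarray) -> Tensor:
        desc = Tensor(batch_geometric_descriptor(coords, idx,
                                                 with_distance=False))
        r = ad.sigmoid(self.mask_bn(self.mask_mlp(desc)))   # (B,N,k,1)
        return ad.reshape(ad.tmax(r, axis=2), coords.shape[:2])

    def forward(self, x: Tensor, coords: np.ndarray) -> Tensor:
        idx = self.edge.group(x, coords)
        ec = self.edge(x, coords, idx=idx)
        m = self.mask(coords, idx)
        B, N = m.shape
        return ec * ad.reshape(m, (B, N, 1))

    __call__ = forward


class GlobalFeatureBlock(Module):
    """Shared MLP + per-point SE-1d gate building the global feature from
    concatenated layer outputs."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 activation: str = "leaky"):
        super().__init__()
        self.mlp = Linear(cin, cout, rng)
        self.bn = BatchNorm(cout)
        self.gate = ChannelGate(cout, rng, activation)
        self.act = activation

    def forward(self, x: Tensor) -> Tensor:
        h = activation_fn(self.act)(self.bn(self.mlp(x)))
        return self.gate(h)

    __call__ = forward


# ---------------------------------------------------------------------------
# single-cloud functional surface

@dataclass
class AttentionMask:
    """Per-point attention weights; soft in (0,1), hard in {0,1}."""

    weights: np.ndarray
    mode: str = "soft"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if self.mode == "soft":
            if not ((self.weights > 0) & (self.weights < 1)).all():
                raise ValueError("soft mask weights must lie strictly in (0,1)")
        elif self.mode == "hard":
            if not np.isin(self.weights, (0.0, 1.0)).all():
                raise ValueError("hard mask weights must be 0 or 1")
        else:
            raise ValueError("mode must be 'soft' or 'hard'")


def _single(x: np.ndarray) -> Tensor:
    return Tensor(np.asarray(x, dtype=float)[None])


def se_gate(features: np.ndarray | GroupedFeature, gate: ChannelGate) -> np.ndarray:
    """Apply the SE channel gate to one cloud's (N,k,C) or (N,C) features."""
    values = features.values if isinstance(features, GroupedFeature) else features
    was_training = gate.training
    gate.eval()
    out = gate(_single(values)).data[0]
    gate.train(was_training)
    return out


def cw_edgeconv(point_feats: np.ndarray, params: EdgeConvBlock, k: int | None = None) -> np.ndarray:
    """One CW-EdgeConv layer on a single cloud (inference mode)."""
    if k is not None and k != params.k:
        params.k = k
    was_training = params.training
    params.eval()
    x = _single(point_feats)
    coords = np.asarray(point_feats, dtype=float)[None]
    out = params(x, coords).data[0]
    params.train(was_training)
    return out


def cw_edgeconv_pp(coords: np.ndarray, params: EdgeConvBlock,
                   k: int | None = None) -> tuple[np.ndarray, GroupedFeature]:
    """First-layer variant: CW-EdgeConv output plus the 10-channel
    geometric descriptor of the same grouping."""
    out = cw_edgeconv(coords, params, k)
    idx = params.last_idx[0]
    nbr = NeighborhoodIndex(idx, k=params.k, metric_space="coords")
    desc = geometric_descriptor(np.asarray(coords, dtype=float), nbr)
    return out, desc


def global_feature(layer_outputs: list[np.ndarray],
                   params: GlobalFeatureBlock) -> np.ndarray:
    n = {np.asarray(o).shape[0] for o in layer_outputs}
    if len(n) != 1:
        raise ValueError("layer outputs must share the point count")
    cat = np.concatenate([np.asarray(o, dtype=float) for o in layer_outputs],
                         axis=1)
    was_training = params.training
    params.eval()
    out = params(_single(cat)).data[0]
    params.train(was_training)
    return out


def _mask_input(desc: GroupedFeature | np.ndarray) -> Tensor:
    values = desc.values if isinstance(desc, GroupedFeature) else np.asarray(desc)
    return _single(values)


def global_attention_mask(desc: GroupedFeature,
                          mask_params: GlobalAttentionHead) -> AttentionMask:
    was_training = mask_params.training
    mask_params.eval()
    w = mask_params.soft(_mask_input(desc)).data[0]
    mask_params.train(was_training)
    return AttentionMask(w, mode="soft")


def hard_attention_mask(desc: GroupedFeature,
                        mask_params: GlobalAttentionHead) -> AttentionMask:
    was_training = mask_params.training
    mask_params.eval()
    w = mask_params.hard(_mask_input(desc))[0]
    mask_params.train(was_training)
    return AttentionMask(w, mode="hard")


def spatial_attention_edgeconv(coords: np.ndarray, point_feats: np.ndarray,
                               params: SpatialAttentionEdgeConv,
                               k: int | None = None) -> np.ndarray:
    if k is not None:
        params.edge.k = k
    was_training = params.training
    params.eval()
    out = params(_single(point_feats),
                 np.asarray(coords, dtype=float)[None]).data[0]
    params.train(was_training)
    return out


def apply_mask(g: np.ndarray, mask: AttentionMask) -> np.ndarray:
    """Masked global feature g_m = ReLU(g * mask), mask broadcast over
    channels."""
    g = np.asarray(g, dtype=float)
    if len(mask.weights) != len(g):
        raise ValueError("mask length does not match point count")
    return np.maximum(g * mask.weights[:, None], 0.0)
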