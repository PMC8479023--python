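"""Hierarchical 3D CNN estimator of DKI scalar maps.

The network maps a stack of b0-normalized diffusion-weighted volumes
directly to the four DKI scalars, skipping the tensor fit. It is
"hierarchical" in the sense that the two output heads tap different depths:
the shallow head (FA, MD — quantities already defined by the Gaussian part
of the signal) is connected to the penultimate hidden layer, while the deep
head (MK, KFA — kurtosis quantities that need higher-order signal features)
is connected to the final hidden layer. The first hidden layer uses a
3x3x3 kernel so estimates pool information across neighboring voxels, and a
dropout layer precedes each head.

Everything runs in NumPy: convolutions are im2col + GEMM with same-padding,
gradients are derived analytically, and optimization is Adam on masked
mean-squared error per head. This keeps training fully deterministic under
a single seed and fast enough for whole-volume batches on desk-scale
phantom volumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .dki import ScalarMaps
from .schemes import DWIDataset

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "TrainedEstimator",
    "Network",
    "build_network",
    "prepare_inputs",
    "train",
    "predict_scalars",
]

_NORM_CLAMP = 1.5  # upper clamp for b0-normalized signal ratios


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the hierarchical estimator.

    hidden_layers is a sequence of (kernel_size, n_filters); all layers use
    ReLU. The first hidden layer must have a 3x3x3 kernel and all kernels
    must be odd so that same-padding preserves spatial alignment.
    """

    n_input_channels: int = 61
    hidden_layers: tuple = ((3, 24), (3, 24), (3, 32), (1, 48), (1, 48), (1, 48))
    dropout_rate: float = 0.1
    shallow_outputs: tuple = ("FA", "MD")
    deep_outputs: tuple = ("MK", "KFA")
    seed: int = 0

    def __post_init__(self):
        if len(self.hidden_layers) < 2:
            raise ValueError("need at least two hidden layers (two-head taps)")
        if self.hidden_layers[0][0] != 3:
            raise ValueError("first hidden layer must use a 3x3x3 kernel")
        for k, f in self.hidden_layers:
            if k % 2 != 1:
                raise ValueError("kernel sizes must be odd for same-padding")
            if f < 1:
                raise ValueError("n_filters must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 100
    learning_rate: float = 1e-3
    head_weights: tuple = (1.0, 1.0)     # (shallow, deep)
    md_scale: float = 1e3                # MD in mm^2/s -> O(1) units
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if any(w <= 0 for w in self.head_weights):
            raise ValueError("head weights must be positive")


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, X, Y, Z) -> (V, C*k^3) patch matrix with same-padding."""
    c = x.shape[0]
    if k == 1:
        return np.ascontiguousarray(x.reshape(c, -1).T)
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    v = x.shape[1] * x.shape[2] * x.shape[3]
    return np.ascontiguousarray(
        win.reshape(c, v, k ** 3).transpose(1, 0, 2).reshape(v, c * k ** 3))


class _Conv3D:
    """Same-padding 3D convolution, stored as a (C_in*k^3, C_out) GEMM."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k ** 3
        scale = np.sqrt(2.0 / fan_in)     # He init for ReLU stacks
        self.W = (rng.standard_normal((fan_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cols = None
        self._shape = None
        self.dW = None
        self.db = None

    def forward(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        cols = _im2col(x, self.k)
        if keep_cache:
            self._cols = cols
            self._shape = x.shape
        y = cols @ self.W + self.b
        sp = x.shape[1:]
        return y.reshape(*sp, self.c_out).transpose(3, 0, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        sp = dy.shape[1:]
        dym = dy.transpose(1, 2, 3, 0).reshape(-1, self.c_out)
        self.dW = self._cols.T @ dym
        self.db = dym.sum(axis=0)
        k = self.k
        if k == 1:
            dxm = dym @ self.W.T
            return dxm.reshape(*sp, self.c_in).transpose(3, 0, 1, 2)
        # gradient w.r.t. input = full correlation with flipped kernels
        w = self.W.reshape(self.c_in, k, k, k, self.c_out)
        w_back = np.ascontiguousarray(
            w[:, ::-1, ::-1, ::-1, :].transpose(4, 1, 2, 3, 0)
            .reshape(self.c_out * k ** 3, self.c_in))
        dxm = _im2col(dy, k) @ w_back
        return dxm.reshape(*sp, self.c_in).transpose(3, 0, 1, 2)

    @property
    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Network:
    """Hidden ReLU conv stack with shallow and deep output heads."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.hidden = []
        c = spec.n_input_channels
        for k, f in spec.hidden_layers:
            self.hidden.append(_Conv3D(c, f, k, rng))
            c = f
        c_penult = spec.hidden_layers[-2][1]
        c_final = spec.hidden_layers[-1][1]
        self.head_shallow = _Conv3D(c_penult, len(spec.shallow_outputs), 1, rng)
        self.head_deep = _Conv3D(c_final, len(spec.deep_outputs), 1, rng)
        self._cache = None

    @property
    def layers(self):
        return [*self.hidden, self.head_shallow, self.head_deep]

    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """x: (C, X, Y, Z) -> (shallow (2,X,Y,Z), deep (2,X,Y,Z))."""
        x = np.asarray(x, dtype=np.float32)
        relu_masks = []
        h = x
        acts = []
        for layer in self.hidden:
            h = layer.forward(h, keep_cache=train)
            m = h > 0
            h = h * m
            relu_masks.append(m)
            acts.append(h)
        p = self.spec.dropout_rate
        if train and p > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            dm_sh = (rng.random(acts[-2].shape) >= p).astype(np.float32) / (1 - p)
            dm_dp = (rng.random(acts[-1].shape) >= p).astype(np.float32) / (1 - p)
        else:
            dm_sh = dm_dp = None
        in_sh = acts[-2] * dm_sh if dm_sh is not None else acts[-2]
        in_dp = acts[-1] * dm_dp if dm_dp is not None else acts[-1]
        out_sh = self.head_shallow.forward(in_sh, keep_cache=train)
        out_dp = self.head_deep.forward(in_dp, keep_cache=train)
        if train:
            self._cache = (relu_masks, dm_sh, dm_dp)
        return out_sh, out_dp

    def backward(self, d_shallow: np.ndarray, d_deep: np.ndarray):
        relu_masks, dm_sh, dm_dp = self._cache
        d_in_sh = self.head_shallow.backward(d_shallow.astype(np.float32))
        d_in_dp = self.head_deep.backward(d_deep.astype(np.float32))
        if dm_sh is not None:
            d_in_sh = d_in_sh * dm_sh
            d_in_dp = d_in_dp * dm_dp
        # through final hidden layer
        d = d_in_dp * relu_masks[-1]
        d = self.hidden[-1].backward(d)
        # penultimate activation feeds both the shallow head and the final layer
        d = (d + d_in_sh) * relu_masks[-2]
        for i in range(len(self.hidden) - 2, -1, -1):
            d = self.hidden[i].backward(d)
            if i > 0:
                d = d * relu_masks[i - 1]
        self._cache = None
        return d


def build_network(spec: NetworkSpec | None = None) -> Network:
    """Instantiate an untrained network; init is deterministic in spec.seed."""
    return Network(spec if spec is not None else NetworkSpec())


def prepare_inputs(dwi: DWIDataset) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a DWI volume into the network's input block.

    Each channel is divided voxelwise by the mean b=0 channel and clamped to
    [0, 1.5]; voxels whose b0 falls below a small floor are zeroed across all
    channels, as is everything outside the mask. Returns ((C, X, Y, Z) float32
    block, mask).
    """
    b0 = dwi.signal[..., dwi.scheme.b0_mask].mean(axis=-1)
    mask = dwi.mask
    pos = b0[mask]
    pos = pos[pos > 0]
    if pos.size == 0:
        raise ValueError("b0 signal is zero everywhere inside the mask")
    floor = 1e-6 * np.median(pos)
    valid = mask & (b0 > floor)
    if not np.any(valid):
        raise ValueError("b0 signal is zero everywhere inside the mask")
    with np.errstate(divide="ignore", invalid="ignore"):
        block = dwi.signal / np.maximum(b0, floor)[..., None]
    block = np.clip(block, 0.0, _NORM_CLAMP)
    block[~valid] = 0.0
    return block.transpose(3, 0, 1, 2).astype(np.float32), mask


class _Adam:
    def __init__(self, params, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g = g.astype(p.dtype)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedEstimator:
    """A trained network plus everything needed to apply it consistently."""

    spec: NetworkSpec
    network: Network
    scheme_fingerprint: str
    channel_means: np.ndarray      # per-channel mean over training masked voxels
    md_scale: float
    loss_history: list = field(default_factory=list)

    def save(self, path) -> None:
        arrays = {}
        for i, layer in enumerate(self.network.layers):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
        meta = {
            "spec": asdict(self.spec),
            "scheme_fingerprint": self.scheme_fingerprint,
            "md_scale": self.md_scale,
            "loss_history": [float(x) for x in self.loss_history],
        }
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 channel_means=self.channel_means, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedEstimator":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            spec_d = meta["spec"]
            spec_d["hidden_layers"] = tuple(tuple(h) for h in spec_d["hidden_layers"])
            spec_d["shallow_outputs"] = tuple(spec_d["shallow_outputs"])
            spec_d["deep_outputs"] = tuple(spec_d["deep_outputs"])
            spec = NetworkSpec(**spec_d)
            net = Network(spec)
            for i, layer in enumerate(net.layers):
                layer.W = data[f"W{i}"].copy()
                layer.b = data[f"b{i}"].copy()
            return cls(spec=spec, network=net,
                       scheme_fingerprint=meta["scheme_fingerprint"],
                       channel_means=data["channel_means"].copy(),
                       md_scale=meta["md_scale"],
                       loss_history=meta["loss_history"])


def _masked_head_loss(pred, target, maskf, weight):
    """Masked MSE over a head's channels; returns (loss, dpred)."""
    diff = (pred - target) * maskf
    n = maskf.sum() * pred.shape[0]
    loss = weight * float((diff ** 2).sum()) / n
    dpred = (2.0 * weight / n) * diff
    return loss, dpred


def train(network: Network, pairs: list, config: TrainingConfig | None = None
          ) -> TrainedEstimator:
    """Train on (degraded DWIDataset, target ScalarMaps) pairs.

    Targets are the model-fitted maps of the high-quality reference scans;
    the loss is the weighted sum of masked mean-squared errors of the two
    heads, with MD rescaled to O(1) units so the shallow head's channels are
    commensurate. Whole volumes are used as batches (one subject per step).
    Fully deterministic for a fixed config seed in a single-threaded run.
    """
    config = config or TrainingConfig()
    if len(pairs) < 1:
        raise ValueError("need at least one training pair")
    fp = pairs[0][0].scheme.fingerprint()
    for dwi, _ in pairs:
        if dwi.scheme.fingerprint() != fp:
            raise ValueError("all training pairs must share one acquisition scheme")
    prepared = []
    for dwi, maps in pairs:
        block, mask = prepare_inputs(dwi)
        if not np.any(mask):
            raise ValueError("empty mask in training pair")
        t_sh = np.stack([maps[name] * (config.md_scale if name == "MD" else 1.0)
                         for name in network.spec.shallow_outputs]).astype(np.float32)
        t_dp = np.stack([maps[name] for name in network.spec.deep_outputs]
                        ).astype(np.float32)
        prepared.append((block, mask.astype(np.float32)[None], t_sh, t_dp))

    # center channels on the pooled training distribution
    counts = sum(p[1].sum() for p in prepared)
    channel_means = (sum((p[0] * p[1]).sum(axis=(1, 2, 3)) for p in prepared)
                     / counts).astype(np.float32)
    prepared = [((p[0] - channel_means[:, None, None, None]) * p[1],
                 p[1], p[2], p[3]) for p in prepared]

    rng = np.random.default_rng(config.seed)
    opt = _Adam(network.parameters(), config.learning_rate)
    w_sh, w_dp = config.head_weights
    loss_history = []
    for _epoch in range(config.epochs):
        order = rng.permutation(len(prepared)) if config.shuffle \
            else np.arange(len(prepared))
        epoch_loss = 0.0
        for idx in order:
            block, maskf, t_sh, t_dp = prepared[idx]
            out_sh, out_dp = network.forward(block, train=True, rng=rng)
            l_sh, d_sh = _masked_head_loss(out_sh, t_sh, maskf, w_sh)
            l_dp, d_dp = _masked_head_loss(out_dp, t_dp, maskf, w_dp)
            network.backward(d_sh, d_dp)
            opt.step(network.parameters(), network.gradients())
            epoch_loss += l_sh + l_dp
        loss_history.append(epoch_loss / len(prepared))
    return TrainedEstimator(spec=network.spec, network=network,
                            scheme_fingerprint=fp, channel_means=channel_means,
                            md_scale=config.md_scale, loss_history=loss_history)


def predict_scalars(estimator: TrainedEstimator, dwi: DWIDataset,
                    force: bool = False) -> ScalarMaps:
    """Apply a trained estimator to one acquisition.

    Refuses inputs acquired under a different scheme than the training one
    unless ``force`` is set (a fingerprint mismatch means the channel
    semantics differ). Outputs are clipped into the valid scalar ranges and
    zeroed outside the mask; inference is deterministic (dropout inactive).
    """
    if dwi.scheme.fingerprint() != estimator.scheme_fingerprint:
        if not force:
            raise ValueError(
                "acquisition scheme fingerprint does not match the scheme the "
                "estimator was trained for (pass force=True to override)")
        warnings.warn("scheme fingerprint mismatch; proceeding because force=True")
    block, mask = prepare_inputs(dwi)
    block = (block - estimator.channel_means[:, None, None, None]) \
        * mask.astype(np.float32)[None]
    out_sh, out_dp = estimator.network.forward(block, train=False)
    named = {}
    for i, name in enumerate(estimator.spec.shallow_outputs):
        named[name] = out_sh[i].astype(float)
    for i, name in enumerate(estimator.spec.deep_outputs):
        named[name] = out_dp[i].astype(float)
    named["MD"] = named["MD"] / estimator.md_scale
    m = mask.astype(float)
    fa = np.clip(named["FA"], 0.0, 1.0) * m
    md = np.maximum(named["MD"], 0.0) * m
    mk = np.clip(named["MK"], -3.0 / 7.0, 10.0) * m
    kfa = np.clip(named["KFA"], 0.0, 1.0) * m
    return ScalarMaps(FA=fa, MD=md, MK=mk, KFA=kfa, mask=mask, method="cnn")
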