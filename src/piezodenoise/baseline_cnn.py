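"""One-dimensional convolutional encoder-decoder baseline denoiser.

The comparator network: two stride-1 same-padded convolution + max-pool
stages, a bottleneck convolution, a sigmoid attention gate, two
upsample-and-convolve ("deconvolution") stages restoring the input
resolution, a skip connection from the first convolution's features added
through a short projection kernel, and a final length-1 projection down to
one output channel.  Implemented directly in numpy with analytic
backpropagation so it trains with the same Adam optimizer, joint loss and
learning-rate schedule as the DBN.

Undocumented architectural details are fixed as: stride-1 convolutions with
zero same-padding, max-pooling of width 2 and stride 2, nearest-neighbour
upsampling before each decoder convolution, and the skip source being the
first convolutional layer's activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dbn_core import (AdamState, LossConfig, TrainConfig, adam_step,
                       joint_loss, joint_loss_grad, _sigmoid)

__all__ = ["LayerSpec", "CNNSpec", "build_default_cnn", "init_cnn_weights",
           "cnn_forward", "train_cnn"]


@dataclass(frozen=True)
class LayerSpec:
    kind: str                 # conv | pool | attention | deconv | skip
    kernel: int
    channels: int = 0         # 0 where Table-style spec lists none
    activation: str = "none"  # relu | sigmoid | none


@dataclass(frozen=True)
class CNNSpec:
    layers: tuple[LayerSpec, ...]

    def __post_init__(self) -> None:
        for sp in self.layers:
            if sp.kind not in ("conv", "pool", "attention", "deconv", "skip"):
                raise ValueError(f"unknown layer kind {sp.kind!r}")
            if sp.kind in ("conv", "deconv", "attention") and sp.channels < 1:
                raise ValueError(f"{sp.kind} layer needs channels > 0")


def build_default_cnn() -> CNNSpec:
    """The default nine-stage encoder-decoder comparator."""
    return CNNSpec(layers=(
        LayerSpec("conv", 15, 64, "relu"),
        LayerSpec("pool", 2),
        LayerSpec("conv", 11, 128, "relu"),
        LayerSpec("pool", 2),
        LayerSpec("conv", 7, 256, "relu"),
        LayerSpec("attention", 1, 256, "sigmoid"),
        LayerSpec("deconv", 5, 128, "relu"),
        LayerSpec("deconv", 7, 64, "relu"),
        LayerSpec("skip", 3),
    ))


# ---------------------------------------------------------------------------
# primitive ops (forward + backward), channel-last layout (B, T, C)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, T, C) -> (B, T, C*k) with zero same-padding (odd k)."""
    B, T, C = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
    cols = np.empty((B, T, k, C), dtype=x.dtype)
    for j in range(k):
        cols[:, :, j, :] = xp[:, j:j + T, :]
    return cols.reshape(B, T, k * C)


def _col2im(g_cols: np.ndarray, k: int, T: int, C: int) -> np.ndarray:
    B = g_cols.shape[0]
    p = k // 2
    g = g_cols.reshape(B, T, k, C)
    gx = np.zeros((B, T + 2 * p, C))
    for j in range(k):
        gx[:, j:j + T, :] += g[:, :, j, :]
    return gx[:, p:p + T, :]


class _Conv:
    """Stride-1 same-padded convolution with optional activation."""

    def __init__(self, name: str, k: int, act: str):
        self.name, self.k, self.act = name, k, act

    def init(self, c_in: int, c_out: int, rng: np.random.Generator) -> dict:
        fan_in = self.k * c_in
        W = rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
        return {self.name + ".W": W, self.name + ".b": np.zeros(c_out)}

    def forward(self, x: np.ndarray, weights: dict):
        cols = _im2col(x, self.k)
        z = cols @ weights[self.name + ".W"] + weights[self.name + ".b"]
        if self.act == "relu":
            y = np.maximum(z, 0.0)
        elif self.act == "sigmoid":
            y = _sigmoid(z)
        else:
            y = z
        self._cache = (cols, y, x.shape)
        return y

    def backward(self, gy: np.ndarray, weights: dict, grads: dict):
        cols, y, xshape = self._cache
        if self.act == "relu":
            gz = gy * (y > 0)
        elif self.act == "sigmoid":
            gz = gy * y * (1.0 - y)
        else:
            gz = gy
        B, T, _ = gz.shape
        W = weights[self.name + ".W"]
        grads[self.name + ".W"] = cols.reshape(-1, W.shape[0]).T @ \
            gz.reshape(-1, W.shape[1])
        grads[self.name + ".b"] = gz.sum(axis=(0, 1))
        return _col2im(gz @ W.T, self.k, xshape[1], xshape[2])


class _MaxPool:
    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x: np.ndarray):
        B, T, C = x.shape
        xr = x.reshape(B, T // self.k, self.k, C)
        self._arg = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, gy: np.ndarray):
        B, T, C = self._shape
        gx = np.zeros((B, T // self.k, self.k, C))
        np.put_along_axis(gx, self._arg[:, :, None, :], gy[:, :, None, :],
                          axis=2)
        return gx.reshape(B, T, C)


class _Upsample:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray):
        return np.repeat(x, 2, axis=1)

    def backward(self, gy: np.ndarray):
        B, T2, C = gy.shape
        return gy.reshape(B, T2 // 2, 2, C).sum(axis=2)


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def _build_ops(spec: CNNSpec) -> list:
    ops, idx = [], 0
    for sp in spec.layers:
        name = f"l{idx}_{sp.kind}"
        if sp.kind == "conv":
            ops.append(("conv", sp, _Conv(name, sp.kernel, sp.activation)))
        elif sp.kind == "pool":
            ops.append(("pool", sp, _MaxPool(sp.kernel)))
        elif sp.kind == "attention":
            ops.append(("attention", sp,
                        _Conv(name, sp.kernel, "sigmoid")))
        elif sp.kind == "deconv":
            ops.append(("deconv", sp,
                        (_Upsample(), _Conv(name, sp.kernel, sp.activation))))
        elif sp.kind == "skip":
            ops.append(("skip", sp, _Conv(name, sp.kernel, "none")))
        idx += 1
    ops.append(("project", LayerSpec("conv", 1, 1),
                _Conv("out_project", 1, "none")))
    return ops


def init_cnn_weights(spec: CNNSpec, seed: int | np.random.Generator = 0
                     ) -> dict:
    """Seeded He-style initialization of every convolution in the stack."""
    rng = np.random.default_rng(seed)
    weights: dict = {}
    c = 1
    c_first = None
    for kind, sp, op in _build_ops(spec):
        if kind in ("conv", "deconv"):
            conv = op if kind == "conv" else op[1]
            weights.update(conv.init(c, sp.channels, rng))
            c = sp.channels
            if c_first is None:
                c_first = c
        elif kind == "attention":
            weights.update(op.init(c, sp.channels, rng))
        elif kind == "skip":
            weights.update(op.init(c_first, c, rng))
        elif kind == "project":
            weights.update(op.init(c, 1, rng))
    return weights


def _cnn_run(spec: CNNSpec, weights: dict, x: np.ndarray, need_grad: bool):
    """Forward pass; returns output, op list and skip bookkeeping."""
    batch = np.atleast_2d(np.asarray(x, float))
    B, T = batch.shape
    n_pool = sum(1 for sp in spec.layers if sp.kind == "pool")
    mult = 2 ** n_pool
    pad = (-T) % mult
    h = np.pad(batch, ((0, 0), (0, pad)), mode="edge")[:, :, None]

    ops = _build_ops(spec)
    first_conv_out = None
    attn_cache = None
    for kind, sp, op in ops:
        if kind == "conv":
            h = op.forward(h, weights)
            if first_conv_out is None:
                first_conv_out = h
        elif kind == "pool":
            h = op.forward(h)
        elif kind == "attention":
            gate = op.forward(h, weights)
            attn_cache = (h.copy(), gate)
            h = h * gate
        elif kind == "deconv":
            up, conv = op
            h = conv.forward(up.forward(h), weights)
        elif kind == "skip":
            h = h + op.forward(first_conv_out, weights)
        elif kind == "project":
            h = op.forward(h, weights)
    out = h[:, :T, 0]
    return out, ops, attn_cache, (B, T, pad)


def cnn_forward(spec: CNNSpec, weights: dict, x: np.ndarray,
                chunk_size: int = 512) -> np.ndarray:
    """Run the network on a batch of windows (rows); output matches input
    length (inputs are edge-padded to a pooling-compatible length and the
    output cropped back).  Large batches are processed in chunks to bound
    the im2col buffers."""
    batch = np.atleast_2d(np.asarray(x, float))
    outs = [_cnn_run(spec, weights, batch[i:i + chunk_size], False)[0]
            for i in range(0, batch.shape[0], chunk_size)]
    out = np.vstack(outs)
    return out if np.asarray(x).ndim > 1 else out[0]


def _cnn_backprop(spec: CNNSpec, weights: dict, x: np.ndarray,
                  target: np.ndarray, loss_cfg: LossConfig
                  ) -> tuple[float, dict]:
    out, ops, attn_cache, (B, T, pad) = _cnn_run(spec, weights, x, True)
    loss, g_out = joint_loss_grad(np.atleast_2d(target), out, loss_cfg)

    grads: dict = {}
    g = np.pad(g_out, ((0, 0), (0, pad)))[:, :, None]
    g_first_conv = None
    first_conv = next(op for k, _, op in ops if k == "conv")
    for kind, sp, op in reversed(ops):
        if kind == "project":
            g = op.backward(g, weights, grads)
        elif kind == "skip":
            # skip branch reads the first conv's output; stash its gradient
            g_first_conv = op.backward(g, weights, grads)
        elif kind == "deconv":
            up, conv = op
            g = up.backward(conv.backward(g, weights, grads))
        elif kind == "attention":
            feat, gate = attn_cache
            g_gate = op.backward(g * feat, weights, grads)
            g = g * gate + g_gate
        elif kind == "pool":
            g = op.backward(g)
        elif kind == "conv":
            if op is first_conv and g_first_conv is not None:
                g = g + g_first_conv
            g = op.backward(g, weights, grads)
    return loss, grads


def _flatten(weights: dict, keys: list[str]) -> np.ndarray:
    return np.concatenate([weights[k].ravel() for k in keys])


def _unflatten(flat: np.ndarray, template: dict, keys: list[str]) -> dict:
    out, pos = {}, 0
    for k in keys:
        n = template[k].size
        out[k] = flat[pos:pos + n].reshape(template[k].shape)
        pos += n
    return out


def train_cnn(spec: CNNSpec, noisy: np.ndarray, clean: np.ndarray,
              cfg: TrainConfig = TrainConfig(),
              loss_cfg: LossConfig = LossConfig(),
              weights: dict | None = None) -> tuple[dict, list[dict]]:
    """Train the comparator with the same Adam step, joint loss, validation
    split and learning-rate schedule as the DBN fine-tuning stage."""
    noisy = np.atleast_2d(np.asarray(noisy, float))
    clean = np.atleast_2d(np.asarray(clean, float))
    if noisy.shape != clean.shape:
        raise ValueError(
            f"paired batches must match: {noisy.shape} vs {clean.shape}")
    rng = np.random.default_rng(cfg.seed + 1)
    n = noisy.shape[0]
    n_val = int(round(cfg.validation_fraction * n))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xt, Yt = noisy[train_idx], clean[train_idx]
    Xv, Yv = noisy[val_idx], clean[val_idx]

    weights = (init_cnn_weights(spec, seed=cfg.seed) if weights is None
               else {k: v.copy() for k, v in weights.items()})
    keys = sorted(weights)
    params = _flatten(weights, keys)
    state = AdamState.zeros_like(params, alpha=cfg.rate_at(1))
    history: list[dict] = []
    for epoch in range(1, cfg.finetune_epochs + 1):
        state.alpha = cfg.rate_at(epoch)
        order = rng.permutation(Xt.shape[0])
        for start in range(0, Xt.shape[0], cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            _, grads = _cnn_backprop(spec, weights, Xt[idx], Yt[idx],
                                     loss_cfg)
            gflat = _flatten(grads, keys)
            params, state = adam_step(params, gflat, state)
            weights = _unflatten(params, weights, keys)
        train_loss = joint_loss(Yt, cnn_forward(spec, weights, Xt), loss_cfg)
        val_loss = (joint_loss(Yv, cnn_forward(spec, weights, Xv), loss_cfg)
                    if Xv.size else float("nan"))
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "learning_rate": state.alpha})
    return weights, history
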