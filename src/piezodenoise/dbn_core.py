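"""Gauss-Bernoulli deep belief network for signal-window reconstruction.

The model stacks three restricted Boltzmann machines (continuous Gaussian
visible units in the first layer, binary units above) pre-trained greedily
with contrastive divergence, then topped with a linear regression head and
fine-tuned end to end under a joint time/frequency loss

    L = lambda1 * MSE(x, xhat) + lambda2 * mean| |F x| - |F xhat| |

using an Adam optimizer written from first principles (bias-corrected first
and second gradient moments).  Pre-training uses plain stochastic gradient
CD; Adam enters only at the fine-tuning stage.

Energy functions
----------------
Bernoulli RBM:        E(v,h) = -a.v - b.h - v.W.h
Gauss-Bernoulli RBM:  E(v,h) = sum_i (v_i - a_i)^2 / (2 sigma_i^2)
                               - b.h - sum_ij (v_i/sigma_i) W_ij h_j

Both give the conditionals ``P(h_j=1|v) = sigmoid(b_j + (v/sigma).W[:,j])``
and, for the Gaussian visible layer, ``E[v|h] = a + sigma * (W.h)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .signal_prep import (TimeSeries, build_trajectory_matrix,
                          normalize_columns, denormalize_columns,
                          diagonal_average, TrajectoryMatrix)

__all__ = [
    "RBMLayer", "DBNModel", "AdamState", "LossConfig", "TrainConfig",
    "rbm_energy", "hidden_probability", "visible_mean", "cd_update",
    "pretrain", "forward", "joint_loss", "joint_loss_grad", "adam_step",
    "fine_tune", "denoise", "exact_bernoulli_loglik",
    "save_checkpoint", "load_checkpoint",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class RBMLayer:
    """One restricted Boltzmann machine layer.

    W : (D, F) visible-to-hidden weights; a : visible biases (D,);
    b : hidden biases (F,); sigma : per-visible-unit scales (D,), all ones
    for Bernoulli units.
    """

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray
    sigma: np.ndarray
    unit_type: str = "bernoulli"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float).ravel()
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.sigma = np.asarray(self.sigma, dtype=float).ravel()
        if self.unit_type not in ("bernoulli", "gauss_bernoulli"):
            raise ValueError(f"unknown unit_type {self.unit_type!r}")
        D, F = self.W.shape
        if self.a.size != D or self.b.size != F or self.sigma.size != D:
            raise ValueError("RBM parameter shapes are inconsistent")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RBMLayer":
        return RBMLayer(self.W.copy(), self.a.copy(), self.b.copy(),
                        self.sigma.copy(), self.unit_type)

    @classmethod
    def initialize(cls, n_visible: int, n_hidden: int, unit_type: str,
                   rng: np.random.Generator, scale: float = 0.01
                   ) -> "RBMLayer":
        W = scale * rng.standard_normal((n_visible, n_hidden))
        return cls(W=W, a=np.zeros(n_visible), b=np.zeros(n_hidden),
                   sigma=np.ones(n_visible), unit_type=unit_type)


@dataclass
class DBNModel:
    """Three stacked RBMs plus a linear regression head."""

    layers: list[RBMLayer]
    head_W: np.ndarray
    head_b: np.ndarray

    def __post_init__(self) -> None:
        self.head_W = np.asarray(self.head_W, dtype=float)
        self.head_b = np.asarray(self.head_b, dtype=float).ravel()
        for lo, hi in zip(self.layers, self.layers[1:]):
            if lo.n_hidden != hi.n_visible:
                raise ValueError("adjacent RBM layer dimensions do not chain")
        if self.layers[0].unit_type != "gauss_bernoulli":
            raise ValueError("first layer must use Gaussian visible units")
        if self.head_W.shape[0] != self.layers[-1].n_hidden:
            raise ValueError("regression head does not match top hidden layer")

    @property
    def input_dim(self) -> int:
        return self.layers[0].n_visible

    @property
    def output_dim(self) -> int:
        return self.head_W.shape[1]

    def copy(self) -> "DBNModel":
        return DBNModel([l.copy() for l in self.layers],
                        self.head_W.copy(), self.head_b.copy())

    @classmethod
    def initialize(cls, input_dim: int = 64,
                   hidden_dims: tuple[int, ...] = (256, 128, 64),
                   seed: int | np.random.Generator = 0) -> "DBNModel":
        rng = np.random.default_rng(seed)
        dims = (input_dim, *hidden_dims)
        layers = [
            RBMLayer.initialize(dims[i], dims[i + 1],
                                "gauss_bernoulli" if i == 0 else "bernoulli",
                                rng)
            for i in range(len(hidden_dims))
        ]
        head_W = 0.01 * rng.standard_normal((hidden_dims[-1], input_dim))
        return cls(layers=layers, head_W=head_W, head_b=np.zeros(input_dim))


@dataclass
class AdamState:
    """First/second moment accumulators for one flat parameter vector."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0
    alpha: float = 5e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    @classmethod
    def zeros_like(cls, params: np.ndarray, **kwargs) -> "AdamState":
        return cls(m=np.zeros_like(params, dtype=float),
                   v=np.zeros_like(params, dtype=float), **kwargs)


@dataclass(frozen=True)
class LossConfig:
    """Weights of the joint time/frequency reconstruction loss."""

    lambda1: float = 0.7
    lambda2: float = 0.3

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule for pre-training and fine-tuning.

    The learning-rate schedule is a list of ``(epoch, rate)`` breakpoints
    applied from that (1-based) epoch onward; the default halves the rate
    at epoch 90.
    """

    pretrain_epochs: int = 10
    finetune_epochs: int = 100
    batch_size: int = 32
    cd_steps: int = 1
    pretrain_rate: float = 1e-3
    lr_schedule: tuple = ((1, 5e-3), (90, 2.5e-3))
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.finetune_epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        epochs = [e for e, _ in self.lr_schedule]
        if epochs != sorted(epochs):
            raise ValueError("lr_schedule epochs must increase")

    def rate_at(self, epoch: int) -> float:
        rate = self.lr_schedule[0][1]
        for e, r in self.lr_schedule:
            if epoch >= e:
                rate = r
        return rate


# ---------------------------------------------------------------------------
# RBM primitives
# ---------------------------------------------------------------------------

def rbm_energy(v: np.ndarray, h: np.ndarray, layer: RBMLayer) -> float:
    """Energy of a joint visible/hidden configuration."""
    v = np.asarray(v, float).ravel()
    h = np.asarray(h, float).ravel()
    if v.size != layer.n_visible or h.size != layer.n_hidden:
        raise ValueError(
            f"configuration shapes ({v.size}, {h.size}) do not match layer "
            f"({layer.n_visible}, {layer.n_hidden})")
    if layer.unit_type == "bernoulli":
        return float(-layer.a @ v - layer.b @ h - v @ layer.W @ h)
    quad = np.sum((v - layer.a) ** 2 / (2.0 * layer.sigma ** 2))
    return float(quad - layer.b @ h - (v / layer.sigma) @ layer.W @ h)


def hidden_probability(v: np.ndarray, layer: RBMLayer) -> np.ndarray:
    """``P(h_j = 1 | v)`` for each hidden unit; accepts a batch of rows."""
    v = np.asarray(v, float)
    if v.shape[-1] != layer.n_visible:
        raise ValueError(f"visible dim {v.shape[-1]} != {layer.n_visible}")
    return _sigmoid((v / layer.sigma) @ layer.W + layer.b)


def visible_mean(h: np.ndarray, layer: RBMLayer) -> np.ndarray:
    """``E[v | h]``: affine for Gaussian units, sigmoid for binary ones."""
    h = np.asarray(h, float)
    if h.shape[-1] != layer.n_hidden:
        raise ValueError(f"hidden dim {h.shape[-1]} != {layer.n_hidden}")
    act = h @ layer.W.T
    if layer.unit_type == "gauss_bernoulli":
        return layer.a + layer.sigma * act
    return _sigmoid(layer.a + act)


def cd_update(layer: RBMLayer, batch: np.ndarray, rate: float, k: int = 1,
              rng: np.random.Generator | None = None) -> RBMLayer:
    """One contrastive-divergence (CD-k) parameter update on a batch.

    Hidden states are sampled (seeded Bernoulli draws).  Visible
    reconstructions use the conditional mean for Gaussian units (the
    usual low-variance choice) but are *sampled* for Bernoulli units,
    which keeps the expected update exactly zero when the data already
    follow the model distribution.  Gradient statistics are
    positive-phase minus k-step reconstruction phase, averaged over the
    batch; for Gaussian visible units the visible-bias gradient carries the
    ``1/sigma^2`` scaling of the energy.
    """
    batch = np.atleast_2d(np.asarray(batch, float))
    if batch.size == 0:
        raise ValueError("cd_update requires a non-empty batch")
    if batch.shape[1] != layer.n_visible:
        raise ValueError(f"batch dim {batch.shape[1]} != {layer.n_visible}")
    if k < 1:
        raise ValueError("cd_steps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    B = batch.shape[0]
    gauss = layer.unit_type == "gauss_bernoulli"

    vs = batch / layer.sigma if gauss else batch
    p_h0 = hidden_probability(batch, layer)
    v_k = batch
    p_hk = p_h0
    for _ in range(k):
        h = (rng.random(p_hk.shape) < p_hk).astype(float)
        v_k = visible_mean(h, layer)
        if not gauss:
            v_k = (rng.random(v_k.shape) < v_k).astype(float)
        p_hk = hidden_probability(v_k, layer)
    vks = v_k / layer.sigma if gauss else v_k

    dW = (vs.T @ p_h0 - vks.T @ p_hk) / B
    if gauss:
        da = ((batch - v_k) / layer.sigma ** 2).mean(axis=0)
    else:
        da = (batch - v_k).mean(axis=0)
    db = (p_h0 - p_hk).mean(axis=0)

    new = layer.copy()
    new.W += rate * dW
    new.a += rate * da
    new.b += rate * db
    return new


def pretrain(model: DBNModel, data: np.ndarray, cfg: TrainConfig) -> DBNModel:
    """Greedy layer-wise unsupervised pre-training with plain-SGD CD.

    Each layer is trained on the previous layer's hidden probabilities;
    Adam is deliberately not used at this stage.
    """
    data = np.atleast_2d(np.asarray(data, float))
    if data.shape[1] != model.input_dim:
        raise ValueError(f"data dim {data.shape[1]} != {model.input_dim}")
    if cfg.pretrain_epochs == 0:
        return model
    rng = np.random.default_rng(cfg.seed)
    model = model.copy()
    inputs = data
    for li, layer in enumerate(model.layers):
        for _ in range(cfg.pretrain_epochs):
            order = rng.permutation(inputs.shape[0])
            for start in range(0, inputs.shape[0], cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                layer = cd_update(layer, inputs[idx], cfg.pretrain_rate,
                                  k=cfg.cd_steps, rng=rng)
        model.layers[li] = layer
        inputs = hidden_probability(inputs, layer)
    return model


# ---------------------------------------------------------------------------
# deterministic forward pass, loss, Adam
# ---------------------------------------------------------------------------

def forward(model: DBNModel, v: np.ndarray) -> np.ndarray:
    """Deterministic reconstruction: three sigmoid layers then affine head."""
    v = np.asarray(v, float)
    single = v.ndim == 1
    h = np.atleast_2d(v)
    if h.shape[1] != model.input_dim:
        raise ValueError(f"input dim {h.shape[1]} != {model.input_dim}")
    for layer in model.layers:
        h = hidden_probability(h, layer)
    out = h @ model.head_W + model.head_b
    return out[0] if single else out


def _forward_cached(model: DBNModel, v: np.ndarray):
    acts = [np.atleast_2d(v)]
    h = acts[0]
    for layer in model.layers:
        h = hidden_probability(h, layer)
        acts.append(h)
    out = h @ model.head_W + model.head_b
    return out, acts


def joint_loss(x: np.ndarray, xhat: np.ndarray,
               cfg: LossConfig = LossConfig()) -> float:
    """Weighted sum of time-domain MSE and spectral-magnitude L1.

    Both terms are mean-reduced per element; the spectral term compares
    full-DFT magnitude spectra of each window.
    """
    x = np.atleast_2d(np.asarray(x, float))
    xhat = np.atleast_2d(np.asarray(xhat, float))
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {xhat.shape}")
    mse = np.mean((x - xhat) ** 2)
    spec = np.mean(np.abs(np.abs(np.fft.fft(xhat, axis=1))
                          - np.abs(np.fft.fft(x, axis=1))))
    return float(cfg.lambda1 * mse + cfg.lambda2 * spec)


def joint_loss_grad(x: np.ndarray, xhat: np.ndarray,
                    cfg: LossConfig = LossConfig()
                    ) -> tuple[float, np.ndarray]:
    """Loss and its analytic gradient with respect to ``xhat``.

    The spectral L1 term uses the subgradient 0 at ties and at zero
    magnitude.  For ``|X_k|`` with ``X = F xhat`` the gradient is
    ``Re(ifft(sign * X/|X|))`` per window (real input).
    """
    x = np.atleast_2d(np.asarray(x, float))
    xhat = np.atleast_2d(np.asarray(xhat, float))
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {xhat.shape}")
    B, L = x.shape
    diff = xhat - x
    mse = np.mean(diff ** 2)
    g_mse = 2.0 * diff / diff.size

    X = np.fft.fft(xhat, axis=1)
    Y = np.fft.fft(x, axis=1)
    magX, magY = np.abs(X), np.abs(Y)
    spec = np.mean(np.abs(magX - magY))
    s = np.sign(magX - magY)
    u = np.where(magX > 0, X / np.where(magX > 0, magX, 1.0), 0.0)
    # d mean|.|/d xhat = Re(ifft(s*u)) * (L / (B*L)) = Re(ifft(s*u)) / B
    g_spec = np.fft.ifft(s * u, axis=1).real / B

    loss = float(cfg.lambda1 * mse + cfg.lambda2 * spec)
    return loss, cfg.lambda1 * g_mse + cfg.lambda2 * g_spec


def adam_step(params: np.ndarray, grad: np.ndarray, state: AdamState
              ) -> tuple[np.ndarray, AdamState]:
    """One Adam update: bias-corrected moment estimates, then the step
    ``theta -= alpha * mhat / (sqrt(vhat) + eps)``."""
    params = np.asarray(params, float)
    grad = np.asarray(grad, float)
    if params.shape != grad.shape or params.shape != state.m.shape:
        raise ValueError("params, grad and Adam state shapes must agree")
    t = state.t + 1
    m = state.beta1 * state.m + (1.0 - state.beta1) * grad
    v = state.beta2 * state.v + (1.0 - state.beta2) * grad ** 2
    mhat = m / (1.0 - state.beta1 ** t)
    vhat = v / (1.0 - state.beta2 ** t)
    new_params = params - state.alpha * mhat / (np.sqrt(vhat) + state.eps)
    new_state = AdamState(m=m, v=v, t=t, alpha=state.alpha,
                          beta1=state.beta1, beta2=state.beta2,
                          eps=state.eps)
    return new_params, new_state


# ---------------------------------------------------------------------------
# fine-tuning (supervised backpropagation with Adam)
# ---------------------------------------------------------------------------

def _pack(model: DBNModel) -> np.ndarray:
    parts = []
    for layer in model.layers:
        parts += [layer.W.ravel(), layer.b]
    parts += [model.head_W.ravel(), model.head_b]
    return np.concatenate(parts)


def _unpack(model: DBNModel, flat: np.ndarray) -> None:
    pos = 0
    for layer in model.layers:
        n = layer.W.size
        layer.W = flat[pos:pos + n].reshape(layer.W.shape); pos += n
        n = layer.b.size
        layer.b = flat[pos:pos + n].copy(); pos += n
    n = model.head_W.size
    model.head_W = flat[pos:pos + n].reshape(model.head_W.shape); pos += n
    model.head_b = flat[pos:].copy()


def _backprop(model: DBNModel, v: np.ndarray, target: np.ndarray,
              loss_cfg: LossConfig) -> tuple[float, np.ndarray]:
    """Loss and flat gradient over all weights/hidden biases and the head."""
    out, acts = _forward_cached(model, v)
    loss, g_out = joint_loss_grad(target, out, loss_cfg)

    grads: list[np.ndarray | None] = [None] * (2 * len(model.layers) + 2)
    top = acts[-1]
    g_head_W = top.T @ g_out
    g_head_b = g_out.sum(axis=0)
    delta = g_out @ model.head_W.T
    for li in range(len(model.layers) - 1, -1, -1):
        layer = model.layers[li]
        h = acts[li + 1]
        dz = delta * h * (1.0 - h)
        vin = acts[li] / layer.sigma
        grads[2 * li] = (vin.T @ dz).ravel()
        grads[2 * li + 1] = dz.sum(axis=0)
        delta = (dz @ layer.W.T) / layer.sigma
    grads[-2] = g_head_W.ravel()
    grads[-1] = g_head_b
    return loss, np.concatenate(grads)  # type: ignore[arg-type]


def fine_tune(model: DBNModel, noisy: np.ndarray, clean: np.ndarray,
              cfg: TrainConfig = TrainConfig(),
              loss_cfg: LossConfig = LossConfig()
              ) -> tuple[DBNModel, list[dict]]:
    """Supervised end-to-end training of the whole stack with Adam.

    Returns the trained model and a per-epoch history of train loss,
    validation loss and the learning rate in force (the default schedule
    halves the rate from 5e-3 to 2.5e-3 at epoch 90).
    """
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

    model = model.copy()
    params = _pack(model)
    state = AdamState.zeros_like(params, alpha=cfg.rate_at(1))
    history: list[dict] = []
    for epoch in range(1, cfg.finetune_epochs + 1):
        state.alpha = cfg.rate_at(epoch)
        order = rng.permutation(Xt.shape[0])
        for start in range(0, Xt.shape[0], cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            _, grad = _backprop(model, Xt[idx], Yt[idx], loss_cfg)
            params, state = adam_step(params, grad, state)
            _unpack(model, params)
        train_loss = joint_loss(Yt, forward(model, Xt), loss_cfg)
        val_loss = (joint_loss(Yv, forward(model, Xv), loss_cfg)
                    if Xv.size else float("nan"))
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "learning_rate": state.alpha})
    return model, history


def denoise(model: DBNModel, x: TimeSeries | np.ndarray,
            L: int | None = None) -> TimeSeries:
    """Window-wise denoising of a whole signal.

    Embeds the signal as a trajectory matrix, z-scores each window, runs the
    network on every window, undoes the scaling, and collapses the stack of
    overlapping reconstructions by diagonal averaging.  Output length equals
    input length.
    """
    L = model.input_dim if L is None else L
    if L != model.input_dim:
        raise ValueError(f"window length {L} != model input dim "
                         f"{model.input_dim}")
    X = build_trajectory_matrix(x, L)
    Xn = normalize_columns(X)
    rec = forward(model, Xn.values.T).T
    out = denormalize_columns(TrajectoryMatrix(
        values=rec, rate=Xn.rate, normalized=True,
        column_means=Xn.column_means, column_stds=Xn.column_stds))
    return diagonal_average(out)


# ---------------------------------------------------------------------------
# exact likelihood oracle (tiny Bernoulli models only)
# ---------------------------------------------------------------------------

def _bit_states(n: int) -> np.ndarray:
    return ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(float)


def exact_bernoulli_loglik(layer: RBMLayer, data: np.ndarray) -> float:
    """Exact mean log-likelihood by enumerating every (v, h) state.

    Only feasible for toy models (D + F <= 16); serves as an independent
    reference for contrastive-divergence training.
    """
    if layer.unit_type != "bernoulli":
        raise ValueError("exact likelihood implemented for Bernoulli units")
    D, F = layer.n_visible, layer.n_hidden
    if D + F > 16:
        raise ValueError(f"model too large to enumerate (D+F={D + F} > 16)")
    data = np.atleast_2d(np.asarray(data, float))
    vs = _bit_states(D)
    hs = _bit_states(F)
    # energy matrix over all joint states
    E = -(vs @ layer.a)[:, None] - (hs @ layer.b)[None, :] \
        - (vs @ layer.W) @ hs.T
    logZ = _logsumexp(-E)
    # unnormalized log marginal of each data row
    Ed = -(data @ layer.a)[:, None] - (hs @ layer.b)[None, :] \
        - (data @ layer.W) @ hs.T
    log_p = _logsumexp(-Ed, axis=1) - logZ
    return float(np.mean(log_p))


def _logsumexp(a: np.ndarray, axis=None):
    amax = np.max(a, axis=axis, keepdims=True)
    out = np.log(np.sum(np.exp(a - amax), axis=axis, keepdims=True)) + amax
    return out if axis is None else np.squeeze(out, axis=axis)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: DBNModel, config: dict | None = None
                    ) -> None:
    """Write a self-describing JSON checkpoint (exact float round-trip)."""
    payload = {
        "format": "piezodenoise-dbn-v1",
        "layers": [
            {"W": layer.W.tolist(), "a": layer.a.tolist(),
             "b": layer.b.tolist(), "sigma": layer.sigma.tolist(),
             "unit_type": layer.unit_type}
            for layer in model.layers
        ],
        "head_W": model.head_W.tolist(),
        "head_b": model.head_b.tolist(),
        "config": config or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def load_checkpoint(path) -> tuple[DBNModel, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "piezodenoise-dbn-v1":
        raise ValueError(f"unrecognized checkpoint format in {path}")
    layers = [RBMLayer(W=np.array(d["W"]), a=np.array(d["a"]),
                       b=np.array(d["b"]), sigma=np.array(d["sigma"]),
                       unit_type=d["unit_type"])
              for d in payload["layers"]]
    model = DBNModel(layers=layers, head_W=np.array(payload["head_W"]),
                     head_b=np.array(payload["head_b"]))
    return model, payload.get("config", {})
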