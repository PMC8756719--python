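"""Symmetric autoencoder with geometric-series layer widths.

The encoder compresses a miRNA expression profile (984 features in the
reference configuration) down to a low-dimensional latent vector through
layers whose widths form a geometric series; the decoder mirrors the
encoder. Training minimises mean squared reconstruction error plus a small
L2 weight penalty with Adam.

The network is implemented directly on numpy arrays: the models involved
are small multilayer perceptrons, and an explicit implementation keeps the
exact Jacobian of the encoder — needed by the activation-gradient
attribution — cheap and transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .config import TrainConfig

__all__ = [
    "Autoencoder",
    "build_autoencoder",
    "geometric_layer_sizes",
    "pretrain_autoencoder",
    "encode",
    "reconstruct",
    "encoder_jacobian",
    "AdamOptimizer",
]

_ACTIVATIONS: dict[str, tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray, np.ndarray], np.ndarray]]] = {
    # name -> (f(s), f'(s, a) where a = f(s))
    "tanh": (np.tanh, lambda s, a: 1.0 - a * a),
    "sigmoid": (lambda s: 1.0 / (1.0 + np.exp(-s)), lambda s, a: a * (1.0 - a)),
    "relu": (lambda s: np.maximum(s, 0.0), lambda s, a: (s > 0).astype(float)),
    "linear": (lambda s: s, lambda s, a: np.ones_like(s)),
}


def geometric_layer_sizes(input_dim: int, latent_dim: int, n_layers: int) -> tuple[int, ...]:
    """Encoder widths ``input_dim * r**k`` rounded, with ``r`` chosen so the
    series ends exactly at ``latent_dim`` after ``n_layers - 1`` steps."""
    if latent_dim >= input_dim:
        raise ValueError(f"latent_dim ({latent_dim}) must be < input_dim ({input_dim})")
    if latent_dim < 1:
        raise ValueError("latent_dim must be >= 1")
    if n_layers < 2:
        raise ValueError("need at least 2 encoder layers (input and latent)")
    r = (latent_dim / input_dim) ** (1.0 / (n_layers - 1))
    widths = [int(round(input_dim * r**k)) for k in range(n_layers)]
    widths[0], widths[-1] = input_dim, latent_dim
    return tuple(widths)


@dataclass
class Autoencoder:
    """Mirror-symmetric multilayer perceptron autoencoder.

    ``layer_sizes`` holds the full stack (encoder widths followed by the
    mirrored decoder widths); ``weights[l]`` has shape
    ``(layer_sizes[l], layer_sizes[l+1])``. All layers use ``activation``
    except the final reconstruction layer, which is linear.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "tanh"
    l2_strength: float = 1e-5

    def __post_init__(self) -> None:
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}; choose from {sorted(_ACTIVATIONS)}")
        if len(self.weights) != len(self.layer_sizes) - 1:
            raise ValueError("one weight matrix per layer transition required")

    @property
    def input_dim(self) -> int:
        return self.layer_sizes[0]

    @property
    def latent_dim(self) -> int:
        return self.layer_sizes[self.n_encoder_layers - 1]

    @property
    def n_encoder_layers(self) -> int:
        # layer_sizes is palindromic: encoder occupies the first half inclusive
        return (len(self.layer_sizes) + 1) // 2

    @property
    def encoder_sizes(self) -> tuple[int, ...]:
        return self.layer_sizes[: self.n_encoder_layers]

    def copy(self) -> "Autoencoder":
        return Autoencoder(
            layer_sizes=self.layer_sizes,
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            activation=self.activation,
            l2_strength=self.l2_strength,
        )

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Full forward pass; returns pre-activations and activations per layer."""
        a = np.asarray(x, dtype=float)
        pre: list[np.ndarray] = []
        acts: list[np.ndarray] = [a]
        last = len(self.weights) - 1
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            s = a @ w + b
            f, _ = _ACTIVATIONS["linear" if l == last else self.activation]
            a = f(s)
            pre.append(s)
            acts.append(a)
        return pre, acts


def build_autoencoder(
    input_dim: int,
    latent_dim: int = 25,
    n_encoder_layers: int = 3,
    seed: int = 0,
    activation: str = "tanh",
    l2_strength: float = 1e-5,
) -> Autoencoder:
    """Construct a symmetric autoencoder with geometric-series widths.

    Weights are drawn uniformly in [0, 1), centered to zero mean, and
    scaled by ``1/sqrt(fan_in)`` (documented fan-in factor); biases start
    at zero. Centering matters: an all-positive init leaves every hidden
    unit computing nearly the same saturated function, and breaking that
    symmetry costs thousands of epochs. Deterministic under ``seed``.
    """
    enc = geometric_layer_sizes(input_dim, latent_dim, n_encoder_layers)
    sizes = enc + tuple(reversed(enc[:-1]))
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for d_in, d_out in zip(sizes[:-1], sizes[1:]):
        w = rng.uniform(0.0, 1.0, size=(d_in, d_out)) - 0.5
        weights.append(w / np.sqrt(d_in))
        biases.append(np.zeros(d_out))
    return Autoencoder(
        layer_sizes=sizes,
        weights=weights,
        biases=biases,
        activation=activation,
        l2_strength=l2_strength,
    )


def encode(ae: Autoencoder, x: np.ndarray) -> np.ndarray:
    """Map samples (n x input_dim, in the scaled training space) to the latent space."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != ae.input_dim:
        raise ValueError(f"expected {ae.input_dim} features, got {x.shape[1]}")
    a = x
    f, _ = _ACTIVATIONS[ae.activation]
    for l in range(ae.n_encoder_layers - 1):
        a = f(a @ ae.weights[l] + ae.biases[l])
    return a


def reconstruct(ae: Autoencoder, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != ae.input_dim:
        raise ValueError(f"expected {ae.input_dim} features, got {x.shape[1]}")
    _, acts = ae.forward(x)
    return acts[-1]


def encoder_jacobian(ae: Autoencoder, x: np.ndarray) -> np.ndarray:
    """Exact Jacobian dz/dx of the encoder at a single input, shape (dL, d0)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != ae.input_dim:
        raise ValueError(f"expected {ae.input_dim} features, got {x.size}")
    a = x[None, :]
    jac = np.eye(ae.input_dim)
    f, fprime = _ACTIVATIONS[ae.activation]
    for l in range(ae.n_encoder_layers - 1):
        s = a @ ae.weights[l] + ae.biases[l]
        a = f(s)
        # d a / d prev = diag(f'(s)) W^T ; chain onto running jacobian
        jac = (ae.weights[l].T * fprime(s, a).ravel()[:, None]) @ jac
    return jac


class AdamOptimizer:
    """Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _backprop(
    ae: Autoencoder,
    x: np.ndarray,
    latent_extra_grad: np.ndarray | None = None,
) -> tuple[float, list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Gradients of the reconstruction loss for one batch.

    ``latent_extra_grad`` (same shape as the latent batch) is an additional
    dLoss/dz term injected at the latent layer; used by joint fine-tuning
    to pull latent codes toward their best-matching SOM node.

    Returns (reconstruction mse, weight grads, bias grads, latent batch).
    """
    n, d0 = x.shape
    pre, acts = ae.forward(x)
    xhat = acts[-1]
    mse = float(np.mean((xhat - x) ** 2))
    delta = 2.0 * (xhat - x) / (n * d0)
    grads_w = [np.empty(0)] * len(ae.weights)
    grads_b = [np.empty(0)] * len(ae.biases)
    latent_index = ae.n_encoder_layers - 1  # index into acts
    last = len(ae.weights) - 1
    _, fprime = _ACTIVATIONS[ae.activation]
    for l in range(last, -1, -1):
        grads_w[l] = acts[l].T @ delta + 2.0 * ae.l2_strength * ae.weights[l]
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = delta @ ae.weights[l].T
            if latent_extra_grad is not None and l == latent_index:
                delta = delta + latent_extra_grad
            delta = delta * fprime(pre[l - 1], acts[l])
    return mse, grads_w, grads_b, acts[latent_index]


def _as_array(data) -> np.ndarray:
    values = getattr(data, "values", data)
    return np.asarray(values, dtype=float)


def pretrain_autoencoder(
    ae: Autoencoder,
    data,
    cfg: TrainConfig,
) -> tuple[Autoencoder, list[float]]:
    """Train the autoencoder alone; returns the trained model and per-epoch loss.

    ``data`` is an ExpressionMatrix (already feature-scaled for training) or a
    plain array. The loss recorded per epoch is the mean reconstruction MSE
    over batches plus the L2 penalty.
    """
    x_all = _as_array(data)
    if x_all.shape[1] != ae.input_dim:
        raise ValueError(f"expected {ae.input_dim} features, got {x_all.shape[1]}")
    ae = ae.copy()
    rng = np.random.default_rng(cfg.seed)
    opt = AdamOptimizer(ae.weights + ae.biases, lr=cfg.ae_lr)
    history: list[float] = []
    n = x_all.shape[0]
    for epoch in range(cfg.ae_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = x_all[order[start : start + cfg.batch_size]]
            mse, gw, gb, _ = _backprop(ae, batch)
            l2 = ae.l2_strength * sum(float(np.sum(w * w)) for w in ae.weights)
            loss = mse + l2
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite autoencoder loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            opt.step(gw + gb)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return ae, history
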