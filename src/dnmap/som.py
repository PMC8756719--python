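"""Self-organizing map over the autoencoder latent space.

An H x W lattice of weight vectors is trained so that latent vectors that
are close in Euclidean distance map to nearby lattice nodes. Each input is
assigned to its best matching unit (BMU) — the node with the smallest
Euclidean distance — and the BMU together with its Gaussian neighbourhood
moves toward the input. The neighbourhood width sigma decays exponentially
over training: wide early (global ordering), narrow late (local
refinement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import TrainConfig

__all__ = [
    "SOMLattice",
    "build_lattice",
    "init_lattice_from_data",
    "sigma_schedule",
    "find_bmu",
    "find_bmu_batch",
    "som_update_batch",
    "pretrain_som",
    "quantization_error",
]


@dataclass
class SOMLattice:
    """H x W grid of weight vectors in latent space."""

    height: int
    width: int
    weights: np.ndarray  # (H, W, latent_dim)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[:2] != (self.height, self.width):
            raise ValueError("weights must have shape (height, width, latent_dim)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("lattice weights must be finite")

    @property
    def latent_dim(self) -> int:
        return self.weights.shape[2]

    @property
    def n_nodes(self) -> int:
        return self.height * self.width

    def flat_weights(self) -> np.ndarray:
        return self.weights.reshape(self.n_nodes, self.latent_dim)

    def grid_coords(self) -> np.ndarray:
        """(n_nodes, 2) array of (row, col) coordinates in row-major order."""
        rows, cols = np.divmod(np.arange(self.n_nodes), self.width)
        return np.column_stack([rows, cols])

    def copy(self) -> "SOMLattice":
        return SOMLattice(self.height, self.width, self.weights.copy())


def build_lattice(height: int, width: int, latent_dim: int, seed: int = 0) -> SOMLattice:
    """Lattice with weights drawn uniformly in [0, 1), deterministic under seed."""
    if height < 1 or width < 1:
        raise ValueError("lattice dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    return SOMLattice(height, width, rng.uniform(0.0, 1.0, size=(height, width, latent_dim)))


def sigma_schedule(
    t: int,
    total_epochs: int,
    height: int,
    width: int,
    sigma_start: float | None = None,
    sigma_end: float = 1.0,
) -> float:
    """Exponentially decaying neighbourhood width.

    Geometric decay from ``sigma_start`` (default half the larger lattice
    span) to ``sigma_end`` over the run: with the defaults this is
    sigma0 * exp(-t / tau) with tau = T / log(sigma0), shrinking from a
    lattice-wide neighbourhood to about one node. Degenerate lattices and
    non-decreasing endpoints collapse to a constant width.
    """
    if sigma_start is None:
        sigma_start = max(height, width) / 2.0
    sigma_start = max(sigma_start, 1e-3)
    if sigma_end >= sigma_start or total_epochs <= 1:
        return float(max(sigma_start, 0.5))
    frac = t / total_epochs
    return float(sigma_start * (sigma_end / sigma_start) ** frac)


def find_bmu(lattice: SOMLattice, z: np.ndarray) -> tuple[int, int, float]:
    """Best matching unit of a single latent vector.

    Ties are broken by the smallest row-major node index.
    """
    z = np.asarray(z, dtype=float).ravel()
    if z.size != lattice.latent_dim:
        raise ValueError(f"expected latent dim {lattice.latent_dim}, got {z.size}")
    d2 = np.sum((lattice.flat_weights() - z) ** 2, axis=1)
    idx = int(np.argmin(d2))  # argmin returns the first minimum: row-major tie-break
    return idx // lattice.width, idx % lattice.width, float(np.sqrt(d2[idx]))


def find_bmu_batch(lattice: SOMLattice, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flat BMU indices and distances for a batch of latent vectors."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    w = lattice.flat_weights()
    # (n, nodes) squared distances without forming huge intermediates
    d2 = (
        np.sum(Z * Z, axis=1)[:, None]
        - 2.0 * Z @ w.T
        + np.sum(w * w, axis=1)[None, :]
    )
    idx = np.argmin(d2, axis=1)
    dist = np.sqrt(np.maximum(d2[np.arange(len(Z)), idx], 0.0))
    return idx, dist


def som_update_batch(
    lattice: SOMLattice,
    Z: np.ndarray,
    t: int,
    total_epochs: int,
    learning_rate: float,
    sigma_start: float | None = None,
    sigma_end: float = 1.0,
) -> SOMLattice:
    """One batch of SOM updates at epoch ``t`` (out of ``total_epochs``).

    Every node (i, j) moves by ``lr * h * (z - w_ij)`` for each batch
    vector z, where h is a Gaussian over squared lattice distance to the
    BMU of z with width sigma(t). Returns a new lattice.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    sigma = sigma_schedule(
        t, total_epochs, lattice.height, lattice.width, sigma_start, sigma_end
    )
    if sigma <= 0:
        raise ValueError("sigma(t) must be positive")
    out = lattice.copy()
    if learning_rate == 0.0 or len(Z) == 0:
        return out
    coords = lattice.grid_coords()  # (nodes, 2)
    bmu_idx, _ = find_bmu_batch(out, Z)
    bmu_coords = coords[bmu_idx]  # (n, 2)
    # grid_d2[n, node] = squared lattice distance from z_n's BMU to node
    diff = coords[None, :, :] - bmu_coords[:, None, :]
    grid_d2 = np.sum(diff * diff, axis=2)
    h = np.exp(-grid_d2 / (2.0 * sigma * sigma))  # (n, nodes)
    w = out.flat_weights()
    # standard batch step: accumulate lr * h * (z - w) against pre-batch weights
    delta = learning_rate * (h.T @ Z - h.sum(axis=0)[:, None] * w)
    out.weights = (w + delta).reshape(out.height, out.width, out.latent_dim)
    return out


def quantization_error(lattice: SOMLattice, Z: np.ndarray) -> float:
    """Mean Euclidean distance of latent vectors to their BMU weights."""
    _, dist = find_bmu_batch(lattice, Z)
    return float(np.mean(dist))


def init_lattice_from_data(
    height: int, width: int, Z: np.ndarray, seed: int = 0
) -> SOMLattice:
    """Lattice initialized from latent vectors sampled without replacement.

    Starting node weights on the data manifold avoids stranding lattice
    nodes in empty regions of a high-dimensional latent space; samples are
    drawn with replacement only when there are fewer than H*W of them.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    rng = np.random.default_rng(seed)
    n_nodes = height * width
    replace = Z.shape[0] < n_nodes
    picks = rng.choice(Z.shape[0], size=n_nodes, replace=replace)
    return SOMLattice(height, width, Z[picks].reshape(height, width, Z.shape[1]).copy())


def pretrain_som(
    lattice: SOMLattice,
    Z: np.ndarray,
    cfg: TrainConfig,
) -> tuple[SOMLattice, list[float]]:
    """Train the SOM on frozen latent vectors.

    Runs :func:`som_update_batch` over shuffled batches each epoch under the
    decaying neighbourhood schedule; the autoencoder is not touched during
    this phase. Returns the trained lattice and the per-epoch quantization
    error (measured after each epoch's updates).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != lattice.latent_dim:
        raise ValueError(f"latent dim mismatch: lattice {lattice.latent_dim}, data {Z.shape[1]}")
    rng = np.random.default_rng(cfg.seed)
    lattice = lattice.copy()
    history: list[float] = []
    n = Z.shape[0]
    for epoch in range(cfg.som_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = Z[order[start : start + cfg.batch_size]]
            lattice = som_update_batch(
                lattice, batch, epoch, cfg.som_epochs, cfg.som_lr,
                sigma_end=cfg.som_sigma_end,
            )
        history.append(quantization_error(lattice, Z))
    return lattice, history
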