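"""The Deep Neural Map: autoencoder + SOM with joint fine-tuning.

Training runs in three phases:

1. autoencoder pre-training (reconstruction MSE + L2, Adam);
2. SOM pre-training on the frozen latent embedding;
3. joint fine-tuning, where the squared distance of each sample's latent
   code to its best-matching SOM node is added to the autoencoder loss
   (weighted by ``joint_weight``) while the SOM keeps training on the
   evolving latent codes.

The BMU index and its weight vector are treated as constants within each
gradient step (no gradient through the argmin).

:class:`DNMModel` bundles the trained autoencoder, lattice, the min-max
feature scaler fitted on training data, and the configuration; it provides
checkpointing and end-to-end sample mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autoencoder import (
    AdamOptimizer,
    Autoencoder,
    _backprop,
    build_autoencoder,
    encode,
    pretrain_autoencoder,
)
from .config import DNMConfig, TrainConfig
from .preprocessing import ExpressionMatrix
from .som import (
    SOMLattice,
    build_lattice,
    find_bmu_batch,
    init_lattice_from_data,
    pretrain_som,
    quantization_error,
    som_update_batch,
)

__all__ = [
    "BMUAssignment",
    "FeatureScaler",
    "DNMModel",
    "joint_finetune",
    "map_samples",
    "train_dnm",
]

CHECKPOINT_SCHEMA = 1


@dataclass(frozen=True)
class BMUAssignment:
    """Per-sample winning-node coordinates and distances."""

    sample_ids: tuple[str, ...]
    rows: np.ndarray
    cols: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (len(self.rows) == len(self.cols) == len(self.distances) == n):
            raise ValueError("assignment arrays must align with sample_ids")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def node_of(self) -> dict[str, tuple[int, int]]:
        return {
            s: (int(r), int(c))
            for s, r, c in zip(self.sample_ids, self.rows, self.cols)
        }

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "row": self.rows.astype(int),
                "col": self.cols.astype(int),
                "distance": self.distances,
            }
        )


class FeatureScaler:
    """Per-feature min-max scaling to [0, 1], fitted on training data only.

    Constant features map to 0. The scaler is persisted in checkpoints so
    test data pass through the identical transform.
    """

    def __init__(self, data_min: np.ndarray, data_range: np.ndarray) -> None:
        self.data_min = np.asarray(data_min, dtype=float)
        self.data_range = np.asarray(data_range, dtype=float)

    @classmethod
    def fit(cls, x: np.ndarray) -> "FeatureScaler":
        x = np.asarray(x, dtype=float)
        lo = x.min(axis=0)
        rng = x.max(axis=0) - lo
        rng[rng == 0] = 1.0
        return cls(lo, rng)

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.data_min.size:
            raise ValueError(
                f"expected {self.data_min.size} features, got {x.shape[1]}"
            )
        return (x - self.data_min) / self.data_range


def joint_finetune(
    ae: Autoencoder,
    lattice: SOMLattice,
    data,
    cfg: TrainConfig,
) -> tuple[Autoencoder, SOMLattice, list[float]]:
    """Jointly fine-tune the autoencoder and the SOM.

    Per batch: latent codes are computed, each code's BMU weight is looked
    up (held fixed for the step), the autoencoder takes an Adam step on
    ``MSE + l2 + joint_weight * mean((z - w_bmu)^2)``, and the SOM then
    takes one batch update on the codes. Returns the combined per-epoch loss.
    """
    x_all = np.asarray(getattr(data, "values", data), dtype=float)
    if x_all.shape[1] != ae.input_dim:
        raise ValueError(f"expected {ae.input_dim} features, got {x_all.shape[1]}")
    ae = ae.copy()
    lattice = lattice.copy()
    rng = np.random.default_rng(cfg.seed)
    opt = AdamOptimizer(ae.weights + ae.biases, lr=cfg.ae_lr)
    history: list[float] = []
    n = x_all.shape[0]
    lam = cfg.joint_weight
    for epoch in range(cfg.joint_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = x_all[order[start : start + cfg.batch_size]]
            z = encode(ae, batch)
            idx, _ = find_bmu_batch(lattice, z)
            w_bmu = lattice.flat_weights()[idx]
            nb, dl = z.shape
            # per-latent-unit mean squared distance to the BMU, matching the
            # per-feature normalization of the reconstruction term
            som_term = float(np.mean((z - w_bmu) ** 2))
            extra = None
            if lam > 0:
                extra = 2.0 * lam * (z - w_bmu) / (nb * dl)
            mse, gw, gb, _ = _backprop(ae, batch, latent_extra_grad=extra)
            l2 = ae.l2_strength * sum(float(np.sum(w * w)) for w in ae.weights)
            loss = mse + l2 + lam * som_term
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite joint loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            opt.step(gw + gb)
            lattice = som_update_batch(
                lattice, z, epoch, cfg.joint_epochs, cfg.som_lr,
                sigma_start=cfg.joint_sigma_start, sigma_end=cfg.joint_sigma_end,
            )
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return ae, lattice, history


def map_samples(
    ae: Autoencoder,
    lattice: SOMLattice,
    samples,
    sample_ids=None,
) -> BMUAssignment:
    """Encode samples (already in the scaled training space) and assign BMUs."""
    if isinstance(samples, ExpressionMatrix):
        if sample_ids is None:
            sample_ids = samples.sample_ids
        x = samples.values
    else:
        x = np.atleast_2d(np.asarray(samples, dtype=float))
        if sample_ids is None:
            sample_ids = tuple(str(i) for i in range(x.shape[0]))
    z = encode(ae, x)
    idx, dist = find_bmu_batch(lattice, z)
    return BMUAssignment(
        sample_ids=tuple(sample_ids),
        rows=idx // lattice.width,
        cols=idx % lattice.width,
        distances=dist,
    )


@dataclass
class DNMModel:
    """A trained Deep Neural Map with its feature scaler and config."""

    ae: Autoencoder
    lattice: SOMLattice
    scaler: FeatureScaler
    feature_names: tuple[str, ...]
    config: DNMConfig

    def scale(self, m: ExpressionMatrix) -> np.ndarray:
        if m.feature_names != self.feature_names:
            raise ValueError(
                "feature axis mismatch: matrix features differ from the "
                f"{len(self.feature_names)} features the model was trained on"
            )
        return self.scaler.transform(m.values)

    def encode(self, m: ExpressionMatrix) -> np.ndarray:
        return encode(self.ae, self.scale(m))

    def map_samples(self, m: ExpressionMatrix) -> BMUAssignment:
        return map_samples(self.ae, self.lattice, self.scale(m), sample_ids=m.sample_ids)

    def quantization_error(self, m: ExpressionMatrix) -> float:
        return quantization_error(self.lattice, self.encode(m))

    # -- checkpointing ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {
            "som_weights": self.lattice.weights,
            "scaler_min": self.scaler.data_min,
            "scaler_range": self.scaler.data_range,
        }
        for i, (w, b) in enumerate(zip(self.ae.weights, self.ae.biases)):
            arrays[f"ae_w{i}"] = w
            arrays[f"ae_b{i}"] = b
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "layer_sizes": list(self.ae.layer_sizes),
            "activation": self.ae.activation,
            "l2_strength": self.ae.l2_strength,
            "lattice": [self.lattice.height, self.lattice.width],
            "feature_names": list(self.feature_names),
            "config": self.config.to_dict(),
        }
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DNMModel":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            if meta.get("schema") != CHECKPOINT_SCHEMA:
                raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
            n_layers = len(meta["layer_sizes"]) - 1
            ae = Autoencoder(
                layer_sizes=tuple(meta["layer_sizes"]),
                weights=[npz[f"ae_w{i}"] for i in range(n_layers)],
                biases=[npz[f"ae_b{i}"] for i in range(n_layers)],
                activation=meta["activation"],
                l2_strength=meta["l2_strength"],
            )
            h, w = meta["lattice"]
            lattice = SOMLattice(h, w, npz["som_weights"])
            scaler = FeatureScaler(npz["scaler_min"], npz["scaler_range"])
        return cls(
            ae=ae,
            lattice=lattice,
            scaler=scaler,
            feature_names=tuple(meta["feature_names"]),
            config=DNMConfig.from_dict(meta["config"]),
        )


def _build_initial_lattice(config: DNMConfig, z: np.ndarray, seed: int) -> SOMLattice:
    if config.som_init == "data":
        return init_lattice_from_data(
            config.lattice_height, config.lattice_width, z, seed=seed
        )
    if config.som_init == "uniform":
        return build_lattice(
            config.lattice_height, config.lattice_width, config.latent_dim, seed=seed
        )
    raise ValueError(f"unknown som_init {config.som_init!r}")


def train_dnm(
    train_matrix: ExpressionMatrix,
    config: DNMConfig | None = None,
    val_matrix: ExpressionMatrix | None = None,
    n_restarts: int = 1,
) -> tuple[DNMModel, dict[str, list[float]]]:
    """Run all three training phases on a (normalized) training matrix.

    The min-max scaler is fitted on the training matrix only; the
    autoencoder is pre-trained once. With ``n_restarts > 1`` the SOM
    pre-training and joint fine-tuning are repeated from different lattice
    initializations (sub-seeded from ``config.train.seed``) and the run
    with the fewest training-empty lattice nodes — ties broken by
    validation (or training) quantization error — is kept. Both selection
    statistics are label-free; restart selection follows the protocol of
    choosing models by held-out winning-node distance.

    Returns the selected model and its loss/quantization-error histories.
    """
    config = config or DNMConfig()
    cfg = config.train
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    scaler = FeatureScaler.fit(train_matrix.values)
    x = scaler.transform(train_matrix.values)
    x_sel = scaler.transform(val_matrix.values) if val_matrix is not None else x
    ae0 = build_autoencoder(
        input_dim=train_matrix.n_features,
        latent_dim=config.latent_dim,
        n_encoder_layers=config.n_encoder_layers,
        seed=cfg.seed,
        activation=config.activation,
        l2_strength=config.l2_strength,
    )
    ae0, ae_history = pretrain_autoencoder(ae0, x, cfg)
    z0 = encode(ae0, x)
    best = None
    for k in range(n_restarts):
        sub_seed = cfg.seed + 1000 * k
        sub_cfg = cfg.replace(seed=sub_seed)
        lattice = _build_initial_lattice(config, z0, sub_seed)
        lattice, qe_history = pretrain_som(lattice, z0, sub_cfg)
        ae, lattice, joint_history = joint_finetune(ae0, lattice, x, sub_cfg)
        z_train = encode(ae, x)
        occupied = len(set(map(tuple, np.column_stack(
            np.divmod(find_bmu_batch(lattice, z_train)[0], lattice.width)
        ).tolist())))
        n_empty = lattice.n_nodes - occupied
        sel_qe = quantization_error(lattice, encode(ae, x_sel))
        key = (n_empty, sel_qe)
        if best is None or key < best[0]:
            best = (key, ae, lattice, qe_history, joint_history)
    _, ae, lattice, qe_history, joint_history = best
    model = DNMModel(
        ae=ae,
        lattice=lattice,
        scaler=scaler,
        feature_names=train_matrix.feature_names,
        config=config,
    )
    histories = {
        "ae_loss": ae_history,
        "som_quantization_error": qe_history,
        "joint_loss": joint_history,
    }
    return model, histories
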