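"""Synthetic miRNA-like cohorts with controlled class structure.

Real miRNA expression atlases of this kind are largely unreleased, so the
package ships a generator that emulates their salient structure: combined
(tissue, neoplasticity) classes, a handful of globally shared
high-abundance miRNAs, disjoint per-class marker miRNAs, library-size
variation, planted low-depth and outlier samples for exercising QC, and an
optional cross-tissue "NET-like" signature carried by a subgroup of
samples in several tissues — the pattern by which neuroendocrine-like
tumours from different organs co-cluster.

Counts follow a negative-binomial model: per-feature baseline abundances
are log-normal, class effects act multiplicatively on the expected
composition, and each sample's counts are drawn with mean proportional to
its library size and variance ``mu + dispersion * mu**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .preprocessing import ExpressionMatrix, SampleOntology

__all__ = ["SynthConfig", "SynthTruth", "generate_cohort", "generate_minimal_fixture"]

Class = tuple[str, bool]


@dataclass(frozen=True)
class SynthConfig:
    """Study-design knobs for a synthetic cohort.

    Defaults describe a compact dual-status design: three tissues, each
    with a neoplastic and a non-neoplastic class (six combined classes) of
    40 samples, 300 miRNA-like features, eight markers per class at
    four-fold enrichment, five globally shared high-abundance features,
    and a NET-like signature carried by a quarter of the samples of each
    neoplastic class.
    """

    n_tissues: int = 3
    dual_status_tissues: int = 3
    samples_per_class: int = 40
    n_features: int = 300
    markers_per_class: int = 8
    shared_markers: int = 5
    shared_fold: float = 50.0
    marker_fold: float = 4.0
    dispersion: float = 0.2
    library_size_range: tuple[float, float] = (2_000_000.0, 5_000_000.0)
    lowdepth_size_range: tuple[float, float] = (200_000.0, 800_000.0)
    n_outliers: int = 0
    n_lowdepth: int = 0
    net_like_tissues: tuple[str, ...] = ("tissue_00", "tissue_01", "tissue_02")
    net_signature_size: int = 6
    net_fold: float = 8.0
    net_fraction: float = 0.25
    baseline_log_mean: float = np.log(30.0)
    baseline_log_sigma: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dual_status_tissues > self.n_tissues:
            raise ValueError("dual_status_tissues cannot exceed n_tissues")
        needed = (
            self.n_classes * self.markers_per_class
            + self.shared_markers
            + (self.net_signature_size if self.net_like_tissues else 0)
        )
        if self.n_features <= needed:
            raise ValueError(
                f"n_features ({self.n_features}) must exceed markers + shared "
                f"+ signature ({needed})"
            )
        unknown = set(self.net_like_tissues) - set(self.tissue_names)
        if unknown:
            raise ValueError(f"net_like_tissues not in cohort: {sorted(unknown)}")
        if not 0 <= self.net_fraction <= 1:
            raise ValueError("net_fraction must be in [0, 1]")

    @property
    def tissue_names(self) -> tuple[str, ...]:
        return tuple(f"tissue_{i:02d}" for i in range(self.n_tissues))

    @property
    def classes(self) -> tuple[Class, ...]:
        out: list[Class] = []
        for i, t in enumerate(self.tissue_names):
            out.append((t, True))
            if i < self.dual_status_tissues:
                out.append((t, False))
        return tuple(out)

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth of a generated cohort, for tests and audits."""

    ontology: SampleOntology
    marker_map: dict[Class, tuple[str, ...]]
    shared_marker_names: tuple[str, ...]
    net_signature_names: tuple[str, ...]
    net_sample_ids: tuple[str, ...]
    planted_outlier_ids: tuple[str, ...]
    planted_lowdepth_ids: tuple[str, ...]


def _feature_names(n: int) -> tuple[str, ...]:
    return tuple(f"mir-{i:04d}" for i in range(n))


def generate_cohort(cfg: SynthConfig) -> tuple[ExpressionMatrix, SynthTruth]:
    """Draw a raw count cohort and its ground truth, deterministic under seed."""
    rng = np.random.default_rng(cfg.seed)
    features = _feature_names(cfg.n_features)

    # feature roles: shared markers first, then per-class markers, then the
    # NET signature; the remainder is background
    cursor = 0
    shared_idx = np.arange(cursor, cursor + cfg.shared_markers)
    cursor += cfg.shared_markers
    marker_idx: dict[Class, np.ndarray] = {}
    for cls in cfg.classes:
        marker_idx[cls] = np.arange(cursor, cursor + cfg.markers_per_class)
        cursor += cfg.markers_per_class
    net_idx = np.arange(cursor, cursor + (cfg.net_signature_size if cfg.net_like_tissues else 0))

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sigma, cfg.n_features)
    baseline[shared_idx] *= cfg.shared_fold

    sample_ids: list[str] = []
    tissues: list[str] = []
    status: list[bool] = []
    rows: list[np.ndarray] = []
    net_ids: list[str] = []
    lowdepth_ids: list[str] = []
    outlier_ids: list[str] = []

    net_classes = {(t, True) for t in cfg.net_like_tissues}
    # planted QC failures are spread over the cohort's first samples
    n_total = cfg.n_classes * cfg.samples_per_class
    lowdepth_slots = set(range(cfg.n_lowdepth))
    outlier_slots = set(range(cfg.n_lowdepth, cfg.n_lowdepth + cfg.n_outliers))
    if cfg.n_lowdepth + cfg.n_outliers > n_total:
        raise ValueError("more planted QC failures than samples")

    slot = 0
    for cls in cfg.classes:
        tissue, neoplastic = cls
        profile = baseline.copy()
        profile[marker_idx[cls]] *= cfg.marker_fold
        n_net = int(round(cfg.net_fraction * cfg.samples_per_class)) if cls in net_classes else 0
        for k in range(cfg.samples_per_class):
            sid = f"{tissue}{'+' if neoplastic else '-'}_s{k:03d}"
            p = profile.copy()
            if k < n_net:
                p[net_idx] *= cfg.net_fold
                net_ids.append(sid)
            if slot in outlier_slots:
                # skew composition: most mass on three background features,
                # which displaces the global log-expression summary
                p = np.full(cfg.n_features, 1e-3)
                p[-3:] = 1.0
                outlier_ids.append(sid)
            if slot in lowdepth_slots:
                lib = rng.uniform(*cfg.lowdepth_size_range)
                lowdepth_ids.append(sid)
            else:
                lib = rng.uniform(*cfg.library_size_range)
            mu = p / p.sum() * lib
            if cfg.dispersion > 0:
                size = 1.0 / cfg.dispersion
                counts = rng.negative_binomial(size, size / (size + mu))
            else:
                counts = rng.poisson(mu)
            sample_ids.append(sid)
            tissues.append(tissue)
            status.append(neoplastic)
            rows.append(counts.astype(float))
            slot += 1

    matrix = ExpressionMatrix(
        values=np.vstack(rows),
        sample_ids=tuple(sample_ids),
        feature_names=features,
        normalized=False,
    )
    truth = SynthTruth(
        ontology=SampleOntology(tuple(sample_ids), tuple(tissues), tuple(status)),
        marker_map={cls: tuple(features[i] for i in idx) for cls, idx in marker_idx.items()},
        shared_marker_names=tuple(features[i] for i in shared_idx),
        net_signature_names=tuple(features[i] for i in net_idx),
        net_sample_ids=tuple(net_ids),
        planted_outlier_ids=tuple(outlier_ids),
        planted_lowdepth_ids=tuple(lowdepth_ids),
    )
    return matrix, truth


def generate_minimal_fixture() -> tuple[ExpressionMatrix, SynthTruth]:
    """Tiny deterministic cohort for the fast test suite.

    Two dual-status tissues (four combined classes) of 12 samples over 60
    features, with clean QC (no planted failures, no NET signature).
    """
    cfg = SynthConfig(
        n_tissues=2,
        dual_status_tissues=2,
        samples_per_class=12,
        n_features=60,
        markers_per_class=4,
        shared_markers=3,
        marker_fold=6.0,
        dispersion=0.1,
        library_size_range=(1_500_000.0, 3_000_000.0),
        net_like_tissues=(),
        net_signature_size=0,
        seed=20240101,
    )
    return generate_cohort(cfg)
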