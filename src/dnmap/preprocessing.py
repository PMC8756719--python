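"""Quality control, normalization, filtering and stratified splitting.

The preprocessing pipeline applied to a raw miRNA count matrix runs in a
fixed order:

1. :func:`filter_low_depth` — drop samples sequenced to fewer than one
   million reads (configurable).
2. :func:`total_count_normalize` — total-count scaling to reads-per-million.
3. :func:`remove_outliers_iqr` — drop samples whose global expression
   summary falls outside Tukey fences over the cohort.
4. :func:`filter_features` — drop miRNAs expressed in too few samples.
5. :func:`drop_small_classes` — drop combined (tissue, neoplasticity)
   classes with fewer than ten samples.
6. :func:`stratified_split` — class-stratified train/validation/test split.

:func:`run_qc_pipeline` wires these together and reports what was removed
at each stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleOntology",
    "SplitAssignment",
    "filter_low_depth",
    "total_count_normalize",
    "remove_outliers_iqr",
    "filter_features",
    "drop_small_classes",
    "stratified_split",
    "sample_summary",
    "run_qc_pipeline",
]

#: relative tolerance on normalized row sums
ROW_SUM_RTOL = 1e-6


@dataclass(frozen=True)
class ExpressionMatrix:
    """A samples x miRNA-features expression matrix.

    Parameters
    ----------
    values
        Non-negative expression values, shape ``(n_samples, n_features)``.
        Raw sequencing counts or normalized units depending on ``normalized``.
    sample_ids
        Ordered unique sample identifiers (row labels).
    feature_names
        Ordered unique miRNA names (column labels).
    normalized
        ``True`` once rows have been scaled to a common total.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_names", tuple(str(f) for f in self.feature_names))
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        if values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"shape {values.shape} inconsistent with {len(self.sample_ids)} "
                f"sample ids and {len(self.feature_names)} feature names"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if np.any(values < 0):
            raise ValueError("expression values must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if self.normalized and len(self.sample_ids) > 0:
            sums = values.sum(axis=1)
            if sums.size and not np.allclose(sums, sums[0], rtol=ROW_SUM_RTOL):
                raise ValueError("normalized matrix rows do not share a common sum")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        """Return the sub-matrix for ``ids``, preserving the order given."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in ids]
        return replace(self, values=self.values[rows], sample_ids=tuple(ids))

    def subset_features(self, names: Sequence[str]) -> "ExpressionMatrix":
        index = {f: i for i, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in index]
        if missing:
            raise KeyError(f"unknown feature names: {missing[:5]}")
        cols = [index[f] for f in names]
        return replace(self, values=self.values[:, cols], feature_names=tuple(names))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_names)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, normalized: bool = False) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=tuple(str(s) for s in df.index),
            feature_names=tuple(str(c) for c in df.columns),
            normalized=normalized,
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, normalized: bool = False) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls.from_dataframe(df, normalized=normalized)


@dataclass(frozen=True)
class SampleOntology:
    """Per-sample labels: tissue-of-origin and neoplasticity status.

    The combined class — the (tissue, neoplastic) pair — is the unit of
    stratification, node labeling and accuracy scoring.
    """

    sample_ids: tuple[str, ...]
    tissue: tuple[str, ...]
    neoplastic: tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "tissue", tuple(str(t) for t in self.tissue))
        object.__setattr__(self, "neoplastic", tuple(bool(b) for b in self.neoplastic))
        if not (len(self.sample_ids) == len(self.tissue) == len(self.neoplastic)):
            raise ValueError("sample_ids, tissue and neoplastic must align")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in ontology")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def combined_class(self) -> tuple[tuple[str, bool], ...]:
        return tuple(zip(self.tissue, self.neoplastic))

    def class_of(self) -> dict[str, tuple[str, bool]]:
        return dict(zip(self.sample_ids, self.combined_class))

    def class_counts(self) -> dict[tuple[str, bool], int]:
        counts: dict[tuple[str, bool], int] = {}
        for c in self.combined_class:
            counts[c] = counts.get(c, 0) + 1
        return counts

    def subset(self, ids: Sequence[str]) -> "SampleOntology":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"sample ids missing from ontology: {missing[:5]}")
        rows = [index[s] for s in ids]
        return SampleOntology(
            sample_ids=tuple(ids),
            tissue=tuple(self.tissue[i] for i in rows),
            neoplastic=tuple(self.neoplastic[i] for i in rows),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "tissue": list(self.tissue),
                "neoplastic": ["neoplastic" if b else "non-neoplastic" for b in self.neoplastic],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleOntology":
        df = pd.read_csv(path, sep=None, engine="python")
        required = {"sample_id", "tissue", "neoplastic"}
        if not required.issubset(df.columns):
            raise ValueError(f"ontology table must have columns {sorted(required)}")
        return cls(
            sample_ids=tuple(str(s) for s in df["sample_id"]),
            tissue=tuple(str(t) for t in df["tissue"]),
            neoplastic=tuple(_parse_status(v) for v in df["neoplastic"]),
        )


def _parse_status(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float)):
        if value in (0, 1):
            return bool(value)
        raise ValueError(f"cannot parse neoplasticity status {value!r}")
    text = str(value).strip().lower()
    if text in {"neoplastic", "1", "true", "yes", "+"}:
        return True
    if text in {"non-neoplastic", "nonneoplastic", "0", "false", "no", "-"}:
        return False
    raise ValueError(f"cannot parse neoplasticity status {value!r}")


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint train / validation / test identifier sets."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("train/val/test sets overlap")

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.train_ids + self.val_ids + self.test_ids

    def to_dataframe(self) -> pd.DataFrame:
        rows = (
            [(s, "train") for s in self.train_ids]
            + [(s, "val") for s in self.val_ids]
            + [(s, "test") for s in self.test_ids]
        )
        return pd.DataFrame(rows, columns=["sample_id", "partition"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SplitAssignment":
        df = pd.read_csv(path, sep=None, engine="python")
        parts = {k: tuple(str(s) for s in df.loc[df["partition"] == k, "sample_id"]) for k in ("train", "val", "test")}
        return cls(train_ids=parts["train"], val_ids=parts["val"], test_ids=parts["test"])


# ---------------------------------------------------------------------------
# pipeline operations
# ---------------------------------------------------------------------------


def filter_low_depth(raw: ExpressionMatrix, min_reads: float = 1_000_000) -> ExpressionMatrix:
    """Drop samples sequenced to fewer than ``min_reads`` total reads.

    The boundary is inclusive: a sample with exactly ``min_reads`` reads is
    kept ("less than" is strict).
    """
    if raw.normalized:
        raise ValueError("filter_low_depth expects raw (unnormalized) counts")
    if min_reads <= 0:
        raise ValueError("min_reads must be positive")
    keep = raw.row_sums() >= min_reads
    if not keep.any():
        raise ValueError(f"all samples removed: no sample reaches {min_reads} reads")
    ids = [s for s, k in zip(raw.sample_ids, keep) if k]
    return raw.subset_samples(ids)


def total_count_normalize(raw: ExpressionMatrix, scale: float = 1_000_000) -> ExpressionMatrix:
    """Total-count scaling: divide each row by its sum, multiply by ``scale``.

    With the default ``scale`` of 1e6 the output is in reads-per-million.
    """
    sums = raw.row_sums()
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"zero-sum sample(s) cannot be normalized: {raw.sample_ids[zero[0]]!r}")
    values = raw.values / sums[:, None] * scale
    return replace(raw, values=values, normalized=True)


def sample_summary(m: ExpressionMatrix, statistic: str = "mean_log2") -> np.ndarray:
    """Per-sample scalar quality summary used by the IQR outlier screen.

    ``mean_log2`` (default): mean over features of log2(value + 1), a
    standard global expression summary. ``median_log2`` and ``mean`` are
    also accepted.
    """
    if statistic == "mean_log2":
        return np.log2(m.values + 1.0).mean(axis=1)
    if statistic == "median_log2":
        return np.median(np.log2(m.values + 1.0), axis=1)
    if statistic == "mean":
        return m.values.mean(axis=1)
    raise ValueError(f"unknown summary statistic {statistic!r}")


def remove_outliers_iqr(
    m: ExpressionMatrix,
    k: float = 1.5,
    statistic: str = "mean_log2",
) -> tuple[ExpressionMatrix, tuple[str, ...]]:
    """Remove samples whose summary lies outside Tukey fences.

    A sample is an outlier when its :func:`sample_summary` falls outside
    ``[Q1 - k*IQR, Q3 + k*IQR]`` computed over the cohort with
    linear-interpolation (type-7) quantiles.

    Returns the filtered matrix and the removed sample ids.
    """
    if not m.normalized:
        raise ValueError("remove_outliers_iqr expects a normalized matrix")
    if k <= 0:
        raise ValueError("k must be positive")
    if m.n_samples < 4:
        raise ValueError("need at least 4 samples for meaningful quartiles")
    summary = sample_summary(m, statistic)
    q1, q3 = np.quantile(summary, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    keep = (summary >= lo) & (summary <= hi)
    removed = tuple(s for s, kp in zip(m.sample_ids, keep) if not kp)
    kept_ids = [s for s, kp in zip(m.sample_ids, keep) if kp]
    if not kept_ids:
        raise ValueError("all samples flagged as outliers")
    return m.subset_samples(kept_ids), removed


def filter_features(m: ExpressionMatrix, min_fraction_expressed: float = 0.1) -> ExpressionMatrix:
    """Keep features expressed (> 0) in at least ``min_fraction_expressed`` of samples.

    Rows are rescaled back to the common row sum afterwards, so the output
    is total-count normalized over the retained features.
    """
    if not m.normalized:
        raise ValueError("filter_features expects a normalized matrix")
    if not 0 <= min_fraction_expressed <= 1:
        raise ValueError("min_fraction_expressed must be in [0, 1]")
    if min_fraction_expressed == 0:
        return m
    frac = (m.values > 0).mean(axis=0)
    keep = frac >= min_fraction_expressed
    if not keep.any():
        raise ValueError("all features removed by expression filter")
    names = tuple(f for f, kp in zip(m.feature_names, keep) if kp)
    scale = float(np.median(m.row_sums()))
    values = m.values[:, keep]
    sums = values.sum(axis=1)
    if np.any(sums == 0):
        bad = m.sample_ids[int(np.flatnonzero(sums == 0)[0])]
        raise ValueError(f"sample {bad!r} has no reads on retained features")
    return replace(m, values=values / sums[:, None] * scale, feature_names=names)


def drop_small_classes(
    m: ExpressionMatrix,
    ont: SampleOntology,
    min_n: int = 10,
) -> tuple[ExpressionMatrix, SampleOntology]:
    """Remove samples of combined classes with fewer than ``min_n`` members."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    ont_sub = ont.subset(m.sample_ids)
    counts = ont_sub.class_counts()
    class_of = ont_sub.class_of()
    keep = [s for s in m.sample_ids if counts[class_of[s]] >= min_n]
    if not keep:
        import warnings

        warnings.warn("drop_small_classes removed every sample", stacklevel=2)
        return (
            replace(m, values=m.values[:0], sample_ids=()),
            SampleOntology((), (), ()),
        )
    return m.subset_samples(keep), ont.subset(keep)


def stratified_split(
    ont: SampleOntology,
    test_frac: float = 0.4,
    val_frac: float = 0.2,
    seed: int = 0,
) -> SplitAssignment:
    """Class-stratified train/validation/test split.

    Per combined class, ``round(test_frac * n)`` samples (clamped to
    ``[1, n-1]`` so both sides are represented) go to test; ``val_frac`` of
    the remaining training samples are then set aside for validation.
    Deterministic under ``seed``.
    """
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    if not 0 <= val_frac < 1:
        raise ValueError("val_frac must be in [0, 1)")
    counts = ont.class_counts()
    singles = [c for c, n in counts.items() if n < 2]
    if singles:
        raise ValueError(
            f"classes with a single sample cannot be stratified: {singles[:3]}; "
            "run drop_small_classes first"
        )
    rng = np.random.default_rng(seed)
    class_of = ont.class_of()
    train: list[str] = []
    val: list[str] = []
    test: list[str] = []
    # iterate classes in first-appearance order for determinism
    seen: dict[tuple[str, bool], list[str]] = {}
    for s in ont.sample_ids:
        seen.setdefault(class_of[s], []).append(s)
    for members in seen.values():
        n = len(members)
        n_test = int(np.clip(round(test_frac * n), 1, n - 1))
        order = rng.permutation(n)
        shuffled = [members[i] for i in order]
        test.extend(sorted(shuffled[:n_test]))
        remaining = shuffled[n_test:]
        n_val = int(np.clip(round(val_frac * len(remaining)), 0, len(remaining) - 1))
        val.extend(sorted(remaining[:n_val]))
        train.extend(sorted(remaining[n_val:]))
    return SplitAssignment(train_ids=tuple(train), val_ids=tuple(val), test_ids=tuple(test))


@dataclass
class QCReport:
    """What the pipeline removed and why."""

    low_depth_ids: tuple[str, ...] = ()
    outlier_ids: tuple[str, ...] = ()
    small_class_ids: tuple[str, ...] = ()
    dropped_features: tuple[str, ...] = ()

    def to_dataframe(self) -> pd.DataFrame:
        rows = (
            [(s, "low_depth") for s in self.low_depth_ids]
            + [(s, "iqr_outlier") for s in self.outlier_ids]
            + [(s, "small_class") for s in self.small_class_ids]
        )
        return pd.DataFrame(rows, columns=["sample_id", "reason"])


def run_qc_pipeline(
    raw: ExpressionMatrix,
    ont: SampleOntology,
    min_reads: float = 1_000_000,
    scale: float = 1_000_000,
    iqr_k: float = 1.5,
    iqr_statistic: str = "mean_log2",
    min_fraction_expressed: float = 0.1,
    min_class_size: int = 10,
) -> tuple[ExpressionMatrix, SampleOntology, QCReport]:
    """Run the full fixed-order QC pipeline on a raw count matrix."""
    missing = set(raw.sample_ids) - set(ont.sample_ids)
    if missing:
        raise ValueError(f"samples missing from ontology: {sorted(missing)[:5]}")
    deep = filter_low_depth(raw, min_reads=min_reads)
    low_depth = tuple(s for s in raw.sample_ids if s not in set(deep.sample_ids))
    norm = total_count_normalize(deep, scale=scale)
    kept, outliers = remove_outliers_iqr(norm, k=iqr_k, statistic=iqr_statistic)
    feat = filter_features(kept, min_fraction_expressed=min_fraction_expressed)
    dropped_features = tuple(f for f in kept.feature_names if f not in set(feat.feature_names))
    final_m, final_ont = drop_small_classes(feat, ont, min_n=min_class_size)
    small = tuple(s for s in feat.sample_ids if s not in set(final_m.sample_ids))
    report = QCReport(
        low_depth_ids=low_depth,
        outlier_ids=outliers,
        small_class_ids=small,
        dropped_features=dropped_features,
    )
    return final_m, final_ont, report
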