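"""Activation-gradient attribution for the autoencoder.

Rather than gradients of a training error, attribution scores are built
from gradients of the latent activations themselves: the score of input
feature i is the sum over latent units j of the absolute partial
derivative |dz_j / dx_i| of the encoder, evaluated at a sample. Averaging
per-sample profiles over a class gives the "class-average activation";
averaging over the samples mapped to one lattice node gives the
"sample-specific activation" for that node.

Key-feature sets are the minimal top-ranked features covering a cumulative
fraction (default 75%) of a profile's total score. Multi-class lattice
nodes are interpreted by intersecting the key-feature sets of the classes
present, and each shared feature is annotated with an up/down trend when
every node sample's score lies strictly above/below its own class average.

Gradients are taken in the scaled input space used for training; scores
are reported per original miRNA name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .autoencoder import Autoencoder, encoder_jacobian
from .dnm import BMUAssignment, DNMModel
from .map_eval import MulticlassNode, find_multiclass_nodes
from .preprocessing import ExpressionMatrix, SampleOntology

__all__ = [
    "ActivationProfile",
    "KeyFeatureSet",
    "input_activation_gradient",
    "class_average_activation",
    "top_features",
    "shared_key_features",
    "class_average_only_features",
    "annotate_trends",
    "expression_summary",
    "profile_for_samples",
    "class_profiles",
    "multiclass_node_report",
    "NodeReport",
]

Class = tuple[str, bool]
Trend = Literal["up", "down", "none"]


@dataclass(frozen=True)
class ActivationProfile:
    """Per-feature attribution scores for a sample, sample set, or class."""

    feature_names: tuple[str, ...]
    scores: np.ndarray
    scope: str = "single-sample"
    n_samples: int = 1

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.feature_names),):
            raise ValueError("scores must align with feature_names")
        if not np.all(np.isfinite(scores)):
            raise ValueError("attribution scores must be finite")
        if np.any(scores < 0):
            raise ValueError("attribution scores must be non-negative")

    @property
    def total(self) -> float:
        return float(self.scores.sum())

    def normalized(self) -> np.ndarray:
        """Scores as fractions of the total (requires a positive total)."""
        total = self.total
        if total <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        return self.scores / total

    def score_of(self, feature: str) -> float:
        try:
            return float(self.scores[self.feature_names.index(feature)])
        except ValueError:
            raise KeyError(f"unknown feature {feature!r}") from None

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.feature_names), name="activation")


@dataclass(frozen=True)
class KeyFeatureSet:
    """Top-ranked features covering a cumulative fraction of a profile."""

    features: tuple[str, ...]
    scores: tuple[float, ...]
    cumulative_fractions: tuple[float, ...]
    threshold: float

    @property
    def names(self) -> frozenset[str]:
        return frozenset(self.features)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.features),
                "score": list(self.scores),
                "cumulative_fraction": list(self.cumulative_fractions),
            }
        )


def _default_names(n: int) -> tuple[str, ...]:
    return tuple(f"feature_{i}" for i in range(n))


def input_activation_gradient(
    ae: Autoencoder,
    x: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> ActivationProfile:
    """Attribution profile of one sample: score_i = sum_j |dz_j/dx_i|.

    ``x`` must be in the scaled space the autoencoder was trained on.
    """
    jac = encoder_jacobian(ae, x)
    if not np.all(np.isfinite(jac)):
        raise FloatingPointError("non-finite encoder gradient")
    scores = np.abs(jac).sum(axis=0)
    names = tuple(feature_names) if feature_names is not None else _default_names(scores.size)
    return ActivationProfile(feature_names=names, scores=scores, scope="single-sample", n_samples=1)


def class_average_activation(
    ae: Autoencoder,
    X: np.ndarray,
    feature_names: Sequence[str] | None = None,
    scope: str = "class-average",
) -> ActivationProfile:
    """Elementwise mean of per-sample profiles over a set of samples."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("cannot average activations over an empty sample set")
    profiles = np.stack(
        [input_activation_gradient(ae, row).scores for row in X]
    )
    names = tuple(feature_names) if feature_names is not None else _default_names(X.shape[1])
    return ActivationProfile(
        feature_names=names,
        scores=profiles.mean(axis=0),
        scope=scope,
        n_samples=X.shape[0],
    )


def top_features(profile: ActivationProfile, threshold: float = 0.75) -> KeyFeatureSet:
    """Minimal descending-score prefix covering ``threshold`` of total score.

    Features are ranked by descending score with name order breaking ties;
    if the cut falls inside a group of tied scores, the whole group is
    included.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    total = profile.total
    if total <= 0:
        raise ValueError("profile has zero total score")
    order = sorted(
        range(len(profile.feature_names)),
        key=lambda i: (-profile.scores[i], profile.feature_names[i]),
    )
    scores = profile.scores[order]
    cum = np.cumsum(scores) / total
    k = int(np.searchsorted(cum, threshold - 1e-12)) + 1
    if threshold == 1.0:
        # all features with nonzero score
        k = int(np.sum(scores > 0))
    else:
        while k < len(scores) and scores[k] == scores[k - 1]:
            k += 1
    chosen = order[:k]
    return KeyFeatureSet(
        features=tuple(profile.feature_names[i] for i in chosen),
        scores=tuple(float(profile.scores[i]) for i in chosen),
        cumulative_fractions=tuple(float(c) for c in cum[:k]),
        threshold=threshold,
    )


def shared_key_features(
    profiles: Sequence[ActivationProfile], threshold: float = 0.75
) -> frozenset[str]:
    """Features present in the key-feature set of every profile."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to intersect")
    sets = [top_features(p, threshold).names for p in profiles]
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def class_average_only_features(
    sample_profiles: Sequence[ActivationProfile],
    class_profiles: Sequence[ActivationProfile],
    threshold: float = 0.75,
) -> frozenset[str]:
    """Features in every class-average key set but no sample-specific key set."""
    if not class_profiles:
        raise ValueError("need at least one class-average profile")
    in_all_class = frozenset.intersection(
        *[top_features(p, threshold).names for p in class_profiles]
    )
    in_any_sample: frozenset[str] = frozenset()
    for p in sample_profiles:
        in_any_sample |= top_features(p, threshold).names
    return in_all_class - in_any_sample


def annotate_trends(
    node_sample_profiles: Mapping[Class, Sequence[ActivationProfile]],
    class_averages: Mapping[Class, ActivationProfile],
    features: Iterable[str],
) -> dict[str, Trend]:
    """Up/down/none trend per feature across the samples of a node.

    A feature trends "up" only if every node sample's score is strictly
    above its own class-average score, "down" only if every is strictly
    below; mixed or tied comparisons give "none".
    """
    trends: dict[str, Trend] = {}
    for feat in features:
        above = below = total = 0
        for cls, profiles in node_sample_profiles.items():
            ref = class_averages[cls].score_of(feat)
            for p in profiles:
                v = p.score_of(feat)
                total += 1
                if v > ref:
                    above += 1
                elif v < ref:
                    below += 1
        if total and above == total:
            trends[feat] = "up"
        elif total and below == total:
            trends[feat] = "down"
        else:
            trends[feat] = "none"
    return trends


def expression_summary(
    m: ExpressionMatrix,
    ont: SampleOntology,
    feature: str,
) -> pd.DataFrame:
    """Boxplot statistics of one miRNA's expression per combined class.

    Returns per class: n, median, q1, q3 (linear-interpolation quantiles)
    and Tukey whisker bounds (most extreme values within 1.5 IQR of the
    quartiles).
    """
    if feature not in m.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    col = m.values[:, m.feature_names.index(feature)]
    class_of = ont.class_of()
    rows = []
    groups: dict[Class, list[float]] = {}
    for s, v in zip(m.sample_ids, col):
        groups.setdefault(class_of[s], []).append(float(v))
    for cls in sorted(groups, key=lambda c: (c[0], c[1])):
        vals = np.asarray(groups[cls])
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        inside = vals[(vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)]
        rows.append(
            {
                "tissue": cls[0],
                "neoplastic": cls[1],
                "n": len(vals),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": float(inside.min()),
                "whisker_high": float(inside.max()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model-level conveniences
# ---------------------------------------------------------------------------


def profile_for_samples(
    model: DNMModel,
    m: ExpressionMatrix,
    sample_ids: Sequence[str],
    scope: str = "sample-set",
) -> ActivationProfile:
    """Average attribution profile of specific samples of a matrix."""
    sub = m.subset_samples(list(sample_ids))
    return class_average_activation(
        model.ae, model.scale(sub), feature_names=m.feature_names, scope=scope
    )


def class_profiles(
    model: DNMModel,
    m: ExpressionMatrix,
    ont: SampleOntology,
) -> dict[Class, ActivationProfile]:
    """Class-average activation profile for every combined class present."""
    class_of = ont.class_of()
    members: dict[Class, list[str]] = {}
    for s in m.sample_ids:
        members.setdefault(class_of[s], []).append(s)
    return {
        cls: profile_for_samples(model, m, ids, scope="class-average")
        for cls, ids in members.items()
    }


@dataclass(frozen=True)
class NodeReport:
    """Interpretation of one multi-class lattice node."""

    node: tuple[int, int]
    class_counts: dict[Class, int]
    shared_features: dict[str, Trend]
    class_average_only: frozenset[str]


def multiclass_node_report(
    model: DNMModel,
    m: ExpressionMatrix,
    ont: SampleOntology,
    assign: BMUAssignment,
    threshold: float = 0.75,
    min_classes: int = 3,
    status_filter: Literal["neoplastic", "non-neoplastic", "any"] = "any",
) -> list[NodeReport]:
    """Interpret every multi-class node of an assignment.

    Per node: the sample-specific profile of each class present is the
    average attribution over that class's samples at the node; shared
    features are the intersection of the per-class key-feature sets,
    annotated with trends against the cohort-wide class averages; the
    final column lists features key to every class average but to no
    sample-specific profile.
    """
    nodes = find_multiclass_nodes(
        assign, ont, min_classes=min_classes, status_filter=status_filter
    )
    averages = class_profiles(model, m, ont)
    reports = []
    for mc in nodes:
        sample_specific = {
            cls: profile_for_samples(model, m, ids, scope="sample-set")
            for cls, ids in mc.samples.items()
        }
        shared = shared_key_features(list(sample_specific.values()), threshold)
        per_sample = {
            cls: [
                profile_for_samples(model, m, [sid], scope="single-sample")
                for sid in ids
            ]
            for cls, ids in mc.samples.items()
        }
        trends = annotate_trends(
            per_sample, {cls: averages[cls] for cls in mc.samples}, shared
        )
        only = class_average_only_features(
            list(sample_specific.values()),
            [averages[cls] for cls in mc.samples],
            threshold,
        )
        reports.append(
            NodeReport(
                node=mc.node,
                class_counts=mc.class_counts,
                shared_features={f: trends[f] for f in sorted(shared)},
                class_average_only=only,
            )
        )
    return reports
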