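"""Post-hoc evaluation of the trained lattice.

After unsupervised training, each lattice node is labeled by the strict
majority combined class of the *training* samples mapped to it (ties and
empty nodes stay unlabeled). Held-out samples are then scored against the
label of their winning node; tissue-only and neoplasticity-only accuracies
are obtained by projecting the combined node label onto each axis.

Sensitivity and specificity are reported with neoplastic as the positive
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .dnm import BMUAssignment
from .preprocessing import SampleOntology

__all__ = [
    "UNLABELED",
    "NodeLabelMap",
    "EvalReport",
    "MulticlassNode",
    "label_nodes",
    "classify",
    "confusion_matrix",
    "density_map",
    "find_multiclass_nodes",
    "class_to_str",
]

#: sentinel label for empty or tied nodes
UNLABELED = "UNLABELED"

Class = tuple[str, bool]


def class_to_str(c: Class) -> str:
    tissue, neoplastic = c
    return f"{tissue}{'+' if neoplastic else '-'}"


@dataclass(frozen=True)
class NodeLabelMap:
    """Per-node majority class labels with the underlying training counts."""

    labels: dict[tuple[int, int], Class | None]
    counts: dict[tuple[int, int], dict[Class, int]]

    def label(self, node: tuple[int, int]) -> Class | None:
        return self.labels.get(node)

    @property
    def labeled_nodes(self) -> list[tuple[int, int]]:
        return [n for n, lab in self.labels.items() if lab is not None]


def label_nodes(assign: BMUAssignment, ont: SampleOntology) -> NodeLabelMap:
    """Strict-majority labeling of lattice nodes from training assignments."""
    class_of = ont.class_of()
    counts: dict[tuple[int, int], dict[Class, int]] = {}
    for s, r, c in zip(assign.sample_ids, assign.rows, assign.cols):
        node = (int(r), int(c))
        per = counts.setdefault(node, {})
        cls = class_of[s]
        per[cls] = per.get(cls, 0) + 1
    labels: dict[tuple[int, int], Class | None] = {}
    for node, per in counts.items():
        best = max(per.values())
        winners = [cls for cls, n in per.items() if n == best]
        labels[node] = winners[0] if len(winners) == 1 else None
    return NodeLabelMap(labels=labels, counts=counts)


@dataclass(frozen=True)
class EvalReport:
    """Classification accuracies of the labeled lattice on an assignment set."""

    accuracy_combined: float
    accuracy_tissue: float
    accuracy_neoplastic: float
    sensitivity: float
    specificity: float
    n_samples: int
    n_unlabeled: int
    unlabeled_mode: str
    confusion: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy_combined": self.accuracy_combined,
            "accuracy_tissue": self.accuracy_tissue,
            "accuracy_neoplastic": self.accuracy_neoplastic,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_samples": self.n_samples,
            "n_unlabeled": self.n_unlabeled,
            "unlabeled_mode": self.unlabeled_mode,
        }


def _predictions(
    assign: BMUAssignment, labels: NodeLabelMap
) -> list[Class | None]:
    node_of = zip(assign.rows, assign.cols)
    return [labels.label((int(r), int(c))) for r, c in node_of]


def classify(
    assign: BMUAssignment,
    labels: NodeLabelMap,
    ont: SampleOntology,
    unlabeled_mode: Literal["penalize", "exclude"] = "penalize",
) -> EvalReport:
    """Score samples against their winning node's label.

    ``unlabeled_mode`` controls samples landing on unlabeled nodes:
    ``penalize`` (default) counts them as misclassified on every axis;
    ``exclude`` drops them from all denominators.
    """
    class_of = ont.class_of()
    actual = [class_of[s] for s in assign.sample_ids]
    predicted = _predictions(assign, labels)
    n_unlabeled = sum(1 for p in predicted if p is None)
    pairs = list(zip(actual, predicted))
    if unlabeled_mode == "exclude":
        pairs = [(a, p) for a, p in pairs if p is not None]
    elif unlabeled_mode != "penalize":
        raise ValueError(f"unknown unlabeled_mode {unlabeled_mode!r}")
    n = len(pairs)
    if n == 0:
        raise ValueError("no scorable samples")
    comb = sum(1 for a, p in pairs if p is not None and p == a)
    tis = sum(1 for a, p in pairs if p is not None and p[0] == a[0])
    neo = sum(1 for a, p in pairs if p is not None and p[1] == a[1])
    pos = [(a, p) for a, p in pairs if a[1]]
    neg = [(a, p) for a, p in pairs if not a[1]]
    tp = sum(1 for a, p in pos if p is not None and p[1])
    tn = sum(1 for a, p in neg if p is not None and not p[1])
    conf = confusion_matrix(assign, labels, ont)
    return EvalReport(
        accuracy_combined=comb / n,
        accuracy_tissue=tis / n,
        accuracy_neoplastic=neo / n,
        sensitivity=tp / len(pos) if pos else float("nan"),
        specificity=tn / len(neg) if neg else float("nan"),
        n_samples=n,
        n_unlabeled=n_unlabeled,
        unlabeled_mode=unlabeled_mode,
        confusion=conf,
    )


def confusion_matrix(
    assign: BMUAssignment,
    labels: NodeLabelMap,
    ont: SampleOntology,
) -> pd.DataFrame:
    """Actual-class x predicted-label counts with a dedicated UNLABELED column.

    Rows are the actual combined classes of the scored samples; columns are
    the union of those classes and every node label, so a class with no
    majority node anywhere shows an all-zero predicted column. Row sums
    equal per-class sample counts.
    """
    class_of = ont.class_of()
    actual = [class_of[s] for s in assign.sample_ids]
    predicted = _predictions(assign, labels)
    classes = sorted(
        {a for a in actual} | {p for p in predicted if p is not None},
        key=class_to_str,
    )
    names = [class_to_str(c) for c in classes]
    table = pd.DataFrame(
        0, index=pd.Index(names, name="actual"), columns=names + [UNLABELED]
    )
    for a, p in zip(actual, predicted):
        col = UNLABELED if p is None else class_to_str(p)
        table.loc[class_to_str(a), col] += 1
    return table


def density_map(
    assign: BMUAssignment,
    height: int,
    width: int,
    subset: Iterable[str] | None = None,
) -> np.ndarray:
    """H x W per-node counts of (optionally subset) samples."""
    wanted = None if subset is None else set(subset)
    grid = np.zeros((height, width), dtype=int)
    for s, r, c in zip(assign.sample_ids, assign.rows, assign.cols):
        if wanted is None or s in wanted:
            grid[int(r), int(c)] += 1
    return grid


@dataclass(frozen=True)
class MulticlassNode:
    """A lattice node with samples from several combined classes."""

    node: tuple[int, int]
    class_counts: dict[Class, int]
    samples: dict[Class, tuple[str, ...]]

    @property
    def n_classes(self) -> int:
        return len(self.class_counts)


def find_multiclass_nodes(
    assign: BMUAssignment,
    ont: SampleOntology,
    min_classes: int = 3,
    status_filter: Literal["neoplastic", "non-neoplastic", "any"] = "any",
) -> list[MulticlassNode]:
    """Nodes whose mapped samples span ``min_classes`` or more combined classes.

    ``status_filter`` restricts the samples considered to one neoplasticity
    status (the lattice regions examined separately for tumour and normal
    tissue). Results are sorted by descending class count, then row-major
    node order.
    """
    if min_classes < 2:
        raise ValueError("min_classes must be >= 2")
    class_of = ont.class_of()
    rosters: dict[tuple[int, int], dict[Class, list[str]]] = {}
    for s, r, c in zip(assign.sample_ids, assign.rows, assign.cols):
        cls = class_of[s]
        if status_filter == "neoplastic" and not cls[1]:
            continue
        if status_filter == "non-neoplastic" and cls[1]:
            continue
        rosters.setdefault((int(r), int(c)), {}).setdefault(cls, []).append(s)
    out = [
        MulticlassNode(
            node=node,
            class_counts={cls: len(ids) for cls, ids in per.items()},
            samples={cls: tuple(ids) for cls, ids in per.items()},
        )
        for node, per in rosters.items()
        if len(per) >= min_classes
    ]
    out.sort(key=lambda m: (-m.n_classes, m.node))
    return out
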