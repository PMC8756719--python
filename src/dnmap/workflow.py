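"""End-to-end study protocol: QC -> split -> train -> label -> score.

This is the programmatic equivalent of chaining the CLI stages, used by
scripts and tests. The protocol follows the evaluation design of the
reference study: a class-stratified 40/60 test/train split with 20% of the
training data set aside as validation; unsupervised training on the
non-validation training samples; node labeling by the strict majority of
all training-partition samples (train + validation — the labels play no
role in training); held-out test samples scored against node labels.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import DNMConfig
from .dnm import BMUAssignment, DNMModel, train_dnm
from .map_eval import EvalReport, NodeLabelMap, classify, label_nodes
from .preprocessing import (
    ExpressionMatrix,
    QCReport,
    SampleOntology,
    SplitAssignment,
    run_qc_pipeline,
    stratified_split,
)

__all__ = ["StudyResult", "run_dnm_study"]


@dataclass
class StudyResult:
    """Everything a downstream analysis needs from one study run."""

    model: DNMModel
    matrix: ExpressionMatrix
    ontology: SampleOntology
    split: SplitAssignment
    qc_report: QCReport
    histories: dict[str, list[float]]
    node_labels: NodeLabelMap
    train_assign: BMUAssignment
    test_assign: BMUAssignment
    report: EvalReport

    def map_all(self) -> BMUAssignment:
        """BMU assignment of every QC-passing sample (train, val and test)."""
        return self.model.map_samples(self.matrix)


def run_dnm_study(
    raw: ExpressionMatrix,
    ontology: SampleOntology,
    config: DNMConfig | None = None,
    seed: int = 0,
    test_frac: float = 0.4,
    val_frac: float = 0.2,
    n_restarts: int = 4,
    min_reads: float = 1_000_000,
    min_class_size: int = 10,
) -> StudyResult:
    """Run the full pipeline on a raw count cohort.

    ``seed`` drives the split and, through ``config.train.seed``, all
    training randomness; when ``config`` is None a default configuration
    with this seed is used.
    """
    if config is None:
        config = DNMConfig()
    config = DNMConfig.from_dict(
        {**config.to_dict(), "train": {**config.to_dict()["train"], "seed": seed}}
    )
    matrix, ont, qc_report = run_qc_pipeline(
        raw, ontology, min_reads=min_reads, min_class_size=min_class_size
    )
    split = stratified_split(ont, test_frac=test_frac, val_frac=val_frac, seed=seed)
    train_m = matrix.subset_samples(split.train_ids)
    val_m = matrix.subset_samples(split.val_ids) if split.val_ids else None
    model, histories = train_dnm(train_m, config, val_matrix=val_m, n_restarts=n_restarts)
    label_ids = split.train_ids + split.val_ids
    train_assign = model.map_samples(matrix.subset_samples(label_ids))
    node_labels = label_nodes(train_assign, ont)
    test_assign = model.map_samples(matrix.subset_samples(split.test_ids))
    report = classify(test_assign, node_labels, ont)
    return StudyResult(
        model=model,
        matrix=matrix,
        ontology=ont,
        split=split,
        qc_report=qc_report,
        histories=histories,
        node_labels=node_labels,
        train_assign=train_assign,
        test_assign=test_assign,
        report=report,
    )
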