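"""Node labeling, accuracy scoring, confusion matrix, multi-class nodes."""

import itertools

import numpy as np
import pytest

from dnmap.dnm import BMUAssignment
from dnmap.map_eval import (
    UNLABELED,
    classify,
    confusion_matrix,
    density_map,
    find_multiclass_nodes,
    label_nodes,
)
from dnmap.preprocessing import SampleOntology


def make_assignment(placements):
    """placements: list of (sample_id, row, col)."""
    ids, rows, cols = zip(*placements)
    return BMUAssignment(
        sample_ids=tuple(ids),
        rows=np.array(rows),
        cols=np.array(cols),
        distances=np.zeros(len(ids)),
    )


def make_ontology(assignments):
    """assignments: dict sample_id -> (tissue, neoplastic)."""
    ids = tuple(assignments)
    return SampleOntology(
        sample_ids=ids,
        tissue=tuple(assignments[s][0] for s in ids),
        neoplastic=tuple(assignments[s][1] for s in ids),
    )


class TestLabelNodes:
    def test_strict_majority_ties_and_empties(self):
        ont = make_ontology(
            {"a1": ("A", True), "a2": ("A", True), "b1": ("B", True),
             "c1": ("C", False), "d1": ("A", True)}
        )
        assign = make_assignment(
            [("a1", 0, 0), ("a2", 0, 0), ("b1", 0, 0),  # majority A
             ("c1", 0, 1), ("d1", 0, 1)]                # tie -> unlabeled
        )
        labels = label_nodes(assign, ont)
        assert labels.label((0, 0)) == ("A", True)
        assert labels.label((0, 1)) is None
        assert labels.label((1, 1)) is None  # empty node
        assert labels.counts[(0, 0)] == {("A", True): 2, ("B", True): 1}


class TestClassify:
    def toy(self):
        # nodes: (0,0) labeled (A,True); (0,1) labeled (B,False); (1,0) tied
        train_ont = {
            f"t{i}": ("A", True) for i in range(3)
        } | {f"u{i}": ("B", False) for i in range(3)} | {
            "v0": ("A", True), "v1": ("B", False)
        }
        placements = [(f"t{i}", 0, 0) for i in range(3)]
        placements += [(f"u{i}", 0, 1) for i in range(3)]
        placements += [("v0", 1, 0), ("v1", 1, 0)]
        labels = label_nodes(make_assignment(placements), make_ontology(train_ont))

        test_ont = {
            # 7 samples on correctly labeled nodes
            **{f"x{i}": ("A", True) for i in range(4)},
            **{f"y{i}": ("B", False) for i in range(3)},
            # 2 on wrong-class nodes
            "w0": ("B", False), "w1": ("B", False),
            # 1 on the unlabeled node
            "z0": ("A", True),
        }
        test_assign = make_assignment(
            [(f"x{i}", 0, 0) for i in range(4)]
            + [(f"y{i}", 0, 1) for i in range(3)]
            + [("w0", 0, 0), ("w1", 0, 0), ("z0", 1, 0)]
        )
        return test_assign, labels, make_ontology(test_ont)

    def test_hand_counted_accuracies(self):
        assign, labels, ont = self.toy()
        report = classify(assign, labels, ont)
        assert report.accuracy_combined == pytest.approx(0.7)
        # w0/w1 are (B,False) on the (A,True) node: tissue and status wrong;
        # z0 unlabeled counts wrong everywhere
        assert report.accuracy_tissue == pytest.approx(0.7)
        assert report.accuracy_neoplastic == pytest.approx(0.7)
        assert report.n_unlabeled == 1

    def test_exclude_mode_drops_unlabeled(self):
        assign, labels, ont = self.toy()
        report = classify(assign, labels, ont, unlabeled_mode="exclude")
        assert report.n_samples == 9
        assert report.accuracy_combined == pytest.approx(7 / 9)

    def test_projection_of_combined_label(self):
        labels = label_nodes(
            make_assignment([("t0", 0, 0), ("t1", 0, 0)]),
            make_ontology({"t0": ("breast", True), "t1": ("breast", True)}),
        )
        assign = make_assignment([("s0", 0, 0)])
        ont = make_ontology({"s0": ("skin", True)})
        report = classify(assign, labels, ont)
        assert report.accuracy_combined == 0.0
        assert report.accuracy_tissue == 0.0
        assert report.accuracy_neoplastic == 1.0

    def test_perfect_mapping_scores_one_everywhere(self):
        ont = make_ontology({"a": ("A", True), "b": ("B", False)})
        train = make_assignment([("a", 0, 0), ("b", 0, 1)])
        labels = label_nodes(train, ont)
        report = classify(train, labels, ont)
        assert report.accuracy_combined == 1.0
        assert report.sensitivity == 1.0 and report.specificity == 1.0
        conf = report.confusion
        assert (conf.to_numpy().sum() == np.trace(conf.to_numpy()[:, :-1]))

    def test_sensitivity_specificity_recoverable_from_confusion(self):
        assign, labels, ont = self.toy()
        report = classify(assign, labels, ont)
        conf = report.confusion
        pos_rows = [r for r in conf.index if r.endswith("+")]
        pos_cols = [c for c in conf.columns if c.endswith("+")]
        neg_cols = [c for c in conf.columns if c.endswith("-")]
        tp = conf.loc[pos_rows, pos_cols].to_numpy().sum()
        p = conf.loc[pos_rows].to_numpy().sum()
        neg_rows = [r for r in conf.index if r.endswith("-")]
        tn = conf.loc[neg_rows, neg_cols].to_numpy().sum()
        n = conf.loc[neg_rows].to_numpy().sum()
        assert report.sensitivity == pytest.approx(tp / p)
        assert report.specificity == pytest.approx(tn / n)


class TestConfusionMatrix:
    def test_rows_sum_to_class_counts_and_unlabeled_column(self):
        toy = TestClassify().toy()
        conf = confusion_matrix(*toy[:2], toy[2])
        assert UNLABELED in conf.columns
        counts = {"A+": 5, "B-": 5}
        for name, n in counts.items():
            assert conf.loc[name].sum() == n
        assert conf[UNLABELED].sum() == 1

    def test_class_without_nodes_gets_empty_column(self):
        labels = label_nodes(
            make_assignment([("t0", 0, 0)]), make_ontology({"t0": ("A", True)})
        )
        assign = make_assignment([("s0", 0, 0)])
        ont = make_ontology({"s0": ("B", False)})
        conf = confusion_matrix(assign, labels, ont)
        assert conf.loc["B-", "A+"] == 1
        assert conf["B-"].sum() == 0  # no node predicts B-


class TestDensityMap:
    def test_totals_and_additivity(self):
        assign = make_assignment(
            [("a", 0, 0), ("b", 0, 0), ("c", 0, 0), ("d", 2, 1)]
        )
        grid = density_map(assign, 3, 3)
        assert grid.sum() == 4
        assert grid[0, 0] == 3 and grid[2, 1] == 1
        g1 = density_map(assign, 3, 3, subset={"a", "b"})
        g2 = density_map(assign, 3, 3, subset={"c", "d"})
        np.testing.assert_array_equal(g1 + g2, grid)


class TestMulticlassNodes:
    def test_single_class_cohort_has_none(self):
        ont = make_ontology({f"s{i}": ("A", True) for i in range(5)})
        assign = make_assignment([(f"s{i}", 0, 0) for i in range(5)])
        assert find_multiclass_nodes(assign, ont, min_classes=2) == []

    def test_roster_and_counts(self):
        ont = make_ontology(
            {**{f"a{i}": ("A", True) for i in range(3)},
             "b0": ("B", True),
             **{f"c{i}": ("C", True) for i in range(2)},
             "d0": ("D", False)}
        )
        placements = [(s, 1, 1) for s in ont.sample_ids if s != "d0"]
        placements.append(("d0", 0, 0))
        nodes = find_multiclass_nodes(make_assignment(placements), ont, min_classes=3)
        assert len(nodes) == 1
        node = nodes[0]
        assert node.node == (1, 1)
        assert node.class_counts == {("A", True): 3, ("B", True): 1, ("C", True): 2}

    def test_status_filter_restricts_samples(self):
        ont = make_ontology(
            {"a": ("A", True), "b": ("B", True), "c": ("C", False), "d": ("D", False)}
        )
        assign = make_assignment([("a", 0, 0), ("b", 0, 0), ("c", 0, 0), ("d", 0, 0)])
        neo = find_multiclass_nodes(assign, ont, min_classes=2, status_filter="neoplastic")
        assert len(neo) == 1 and set(neo[0].class_counts) == {("A", True), ("B", True)}
        non = find_multiclass_nodes(assign, ont, min_classes=3, status_filter="non-neoplastic")
        assert non == []


class TestMajorityOptimality:
    def test_brute_force_over_small_lattices(self):
        """Majority labeling maximizes training accuracy over all labelings.

        Exhaustive check over random placements of up to 6 samples from up
        to 3 classes on lattices up to 2 x 2. On tie-free placements the
        strict-majority labeling must match the best labeling found by
        enumeration exactly; nodes with tied maxima stay unlabeled by
        design, sacrificing exactly the tied nodes' samples, so there the
        majority accuracy must equal the enumeration optimum restricted to
        untied nodes.
        """
        rng = np.random.default_rng(0)
        classes = [("A", True), ("B", True), ("C", False)]
        n_tied_configs = 0
        for trial in range(200):
            h, w = rng.integers(1, 3, size=2)
            n = rng.integers(1, 7)
            placements, ont_map = [], {}
            for i in range(n):
                sid = f"s{i}"
                ont_map[sid] = classes[rng.integers(0, 3)]
                placements.append((sid, rng.integers(0, h), rng.integers(0, w)))
            ont = make_ontology(ont_map)
            assign = make_assignment(placements)
            labels = label_nodes(assign, ont)
            acc_majority = classify(assign, labels, ont).accuracy_combined
            # brute force: every assignment of a class label (or none) per node
            nodes = [(r, c) for r in range(h) for c in range(w)]
            best = 0.0
            for combo in itertools.product([None] + classes, repeat=len(nodes)):
                lab = dict(zip(nodes, combo))
                correct = sum(
                    1 for (sid, r, c) in placements if lab[(r, c)] == ont_map[sid]
                )
                best = max(best, correct / n)
            tied = [node for node, per in labels.counts.items()
                    if labels.labels[node] is None]
            if not tied:
                assert acc_majority == pytest.approx(best)
            else:
                n_tied_configs += 1
                tied_max = sum(max(labels.counts[node].values()) for node in tied)
                assert acc_majority == pytest.approx(best - tied_max / n)
        assert n_tied_configs > 0  # both branches exercised


class TestStudyInvariants:
    def test_projection_inequality_on_trained_study(self, study):
        result, _ = study
        r = result.report
        assert r.accuracy_combined <= r.accuracy_tissue + 1e-12
        assert r.accuracy_combined <= r.accuracy_neoplastic + 1e-12
        conf = r.confusion
        class_counts = {}
        class_of = result.ontology.class_of()
        from dnmap.map_eval import class_to_str
        for s in result.split.test_ids:
            name = class_to_str(class_of[s])
            class_counts[name] = class_counts.get(name, 0) + 1
        for name, n in class_counts.items():
            assert conf.loc[name].sum() == n
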