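import itertools

import numpy as np
import pytest

from celltypeagent import (AgreementReport, AlignmentError, ClusterGrade,
                           EmptyInputError, PartialRules, SynonymTable,
                           aggregate, compare_methods, grade,
                           grade_annotations, grade_mixture)

RULES = PartialRules([("T cell", "CD8+ T cell"), ("mural cell", "pericyte")])
SYN = SynonymTable({"NK cell": "natural killer cell"})


class TestGrade:
    @pytest.mark.parametrize("pred,truth,level,basis", [
        ("pericyte", "Pericytes", 1.0, "exact"),
        ("NK cell", "natural killer cell", 1.0, "synonym"),
        ("T cell", "CD8+ T cell", 0.5, "partial"),
        ("pericyte", "mural cell", 0.5, "partial"),
        ("fibroblast", "pericyte", 0.0, "mismatch"),
    ])
    def test_three_level_convention(self, pred, truth, level, basis):
        assert grade(pred, truth, SYN, RULES) == (level, basis)

    def test_head_noun_token_subset_gives_partial(self):
        # no declared relation needed: shared head noun + token subset
        assert grade("T cell", "alpha-beta T cell") == (0.5, "partial")
        assert grade("muscle cell", "smooth muscle cell") == (0.5, "partial")

    def test_symmetry_for_exact_and_synonym(self):
        for a, b in [("pericyte", "Pericytes"), ("NK cell", "natural killer cell")]:
            assert grade(a, b, SYN, RULES) == grade(b, a, SYN, RULES)

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            grade("", "pericyte")


class TestGradeMixture:
    def test_full_recovery(self):
        assert grade_mixture(["A", "B"], ["A", "B"])[0] == 1.0

    def test_half_recovery(self):
        assert grade_mixture(["A"], ["A", "B"])[0] == 0.5

    def test_nothing_matched(self):
        assert grade_mixture(["C"], ["A", "B"])[0] == 0.0

    def test_partial_match_counts_half(self):
        level, _ = grade_mixture(["T cell"], ["CD8+ T cell", "B cell"], SYN, RULES)
        assert level == 0.25

    def test_singletons_equal_plain_grade(self):
        for p, t in [("pericyte", "Pericytes"), ("T cell", "CD8+ T cell"),
                     ("fibroblast", "pericyte")]:
            assert grade_mixture([p], [t], SYN, RULES) == grade(p, t, SYN, RULES)


def report(levels, dataset="d1"):
    return AgreementReport([ClusterGrade(f"c{i}", ("x",), ("y",), lv, "exact", dataset)
                            for i, lv in enumerate(levels)])


class TestAggregate:
    def test_arithmetic_mean_within_group(self):
        assert aggregate(report([1.0, 0.5, 0.0]))["overall"] == pytest.approx(0.5)

    def test_datasets_weighted_equally(self):
        r = AgreementReport(report([1.0, 1.0, 1.0]).grades
                            + [ClusterGrade("z", ("x",), ("y",), 0.0, "mismatch", "d2")])
        agg = aggregate(r)
        assert agg["per_dataset"] == {"d1": 1.0, "d2": 0.0}
        assert agg["overall"] == pytest.approx(0.5)
        assert aggregate(r, pooled=True)["overall"] == pytest.approx(0.75)

    def test_single_cluster_boundary(self):
        assert aggregate(report([1.0]))["overall"] == 1.0

    def test_all_correct_is_exactly_one(self):
        assert aggregate(report([1.0] * 7))["overall"] == 1.0

    def test_permutation_invariance(self):
        levels = [1.0, 0.5, 0.0, 0.5, 1.0]
        base = aggregate(report(levels))["overall"]
        for perm in itertools.islice(itertools.permutations(levels), 20):
            assert aggregate(report(list(perm)))["overall"] == pytest.approx(base)

    def test_empty_is_error(self):
        with pytest.raises(EmptyInputError):
            aggregate(AgreementReport([]))


class TestGradeAnnotations:
    def test_mismatched_cluster_sets_raise_alignment_error(self):
        with pytest.raises(AlignmentError) as err:
            grade_annotations({"c1": "A"}, {"c1": "A", "c2": "B"})
        assert err.value.missing == ("c2",)

    def test_set_valued_labels_dispatch_to_mixture_grading(self):
        rep = grade_annotations({"c1": "A;B"}, {"c1": "A;B"})
        assert rep.grades[0].level == 1.0
        rep = grade_annotations({"c1": "A"}, {"c1": "A;B"})
        assert rep.grades[0].level == 0.5


class TestCompareMethods:
    def test_identical_predictions_identical_rows(self):
        t = compare_methods({"m1": report([1.0, 0.5]), "m2": report([1.0, 0.5])})
        assert (t.loc["m1"] == t.loc["m2"]).all()

    def test_extremes(self):
        t = compare_methods({"good": report([1.0, 1.0]), "bad": report([0.0, 0.0])})
        assert t.loc["good", "overall"] == 1.0
        assert t.loc["bad", "overall"] == 0.0

    def test_different_cluster_sets_raise(self):
        small = AgreementReport(report([1.0, 0.5]).grades[:1])
        with pytest.raises(AlignmentError):
            compare_methods({"m1": report([1.0, 0.5]), "m2": small})

    def test_deterministic_ordering(self):
        t = compare_methods({"b": report([1.0]), "a": report([0.5])})
        assert list(t.index) == ["a", "b"]
        assert list(t.columns)[-1] == "overall"
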