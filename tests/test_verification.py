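import numpy as np
import pandas as pd
import pytest

from celltypeagent import (CandidateList, ConfigurationError, ReferenceMatrix,
                           TissueView, VerifyConfig, score_candidate, verify,
                           verify_mixture)
from tests.conftest import PERICYTE_MARKERS


def cand(*names, cluster="c1"):
    return CandidateList(cluster_id=cluster, candidates=tuple(names),
                         raw_response="\n".join(names), model="scripted")


def ref_from_scores(scores: dict, gene="G1", tissue="t0"):
    """Reference with one gene per label whose value IS the desired score."""
    rows = [{"tissue": tissue, "cell_type": label, "gene": gene, "mean_expr": v}
            for label, v in scores.items()]
    return ReferenceMatrix(pd.DataFrame(rows))


def marker_set(genes, tissue="t0", cluster="c1"):
    from celltypeagent import MarkerSet
    return MarkerSet(cluster_id=cluster, tissue=tissue, species="Homo sapiens",
                     genes=tuple(genes))


class TestScoreCandidate:
    def test_mean_over_overlapping_genes_only(self):
        view = TissueView(tissue="t0", genes=("g1", "g2", "g3"),
                          entries={"A": {"g1": 2.0, "g2": 4.0}})
        s = score_candidate(view, "A", ["g1", "g2", "g3"], min_overlap=1)
        assert (s.n_overlap, s.score) == (2, 3.0)

    def test_empty_overlap_is_undefined(self):
        view = TissueView(tissue="t0", genes=("g1",), entries={"A": {}})
        s = score_candidate(view, "B", ["g1"], min_overlap=1)
        assert s.n_overlap == 0 and s.score is None

    def test_min_overlap_gate(self):
        view = TissueView(tissue="t0", genes=("g1",), entries={"A": {"g1": 5.0}})
        assert score_candidate(view, "A", ["g1"], min_overlap=2).score is None

    def test_matches_brute_force_mean_on_random_views(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            labels = [f"L{i}" for i in range(rng.integers(1, 6))]
            genes = [f"g{i}" for i in range(rng.integers(1, 8))]
            entries = {l: {g: float(rng.uniform(0, 10))
                           for g in genes if rng.random() > 0.3} for l in labels}
            view = TissueView(tissue="t0", genes=tuple(genes), entries=entries)
            markers = [g for g in genes if rng.random() > 0.2] or [genes[0]]
            for l in labels:
                s = score_candidate(view, l, markers)
                vals = [entries[l][g] for g in markers if g in entries[l]]
                if not vals:
                    assert s.score is None
                else:
                    assert s.score == pytest.approx(sum(vals) / len(vals))


class TestVerify:
    def test_highest_mean_expression_wins(self):
        ref = ref_from_scores({"fibroblast": 1.2, "pericyte": 3.4, "adipocyte": 0.8})
        res = verify(cand("fibroblast", "pericyte", "adipocyte"), ref, marker_set(["G1"]))
        assert res.chosen == ("pericyte",) and res.decision == "verified"

    def test_pericyte_recovered_from_rank_two(self, adipose_ref):
        """LLM ranks fibroblast first; expression evidence picks pericyte."""
        res = verify(cand("fibroblast", "pericyte cell", "adipocyte"),
                     adipose_ref, marker_set(PERICYTE_MARKERS, tissue="adipose tissue"))
        assert res.chosen == ("pericyte",)
        assert res.decision == "verified"
        assert res.scores[0].candidate_name == "fibroblast"

    def test_score_tie_resolves_by_llm_rank(self):
        ref = ref_from_scores({"A": 2.0, "B": 1.0, "C": 2.0})
        res = verify(cand("A", "B", "C"), ref, marker_set(["G1"]))
        assert res.chosen == ("A",)

    def test_all_unmatched_falls_back_to_top_llm_candidate(self):
        ref = ref_from_scores({"A": 1.0})
        res = verify(cand("xyzzy", "qwerty"), ref, marker_set(["G1"]))
        assert res.decision == "fallback_llm_rank"
        assert res.chosen == ("xyzzy",)

    def test_no_marker_coverage_falls_back(self):
        ref = ref_from_scores({"A": 1.0, "B": 2.0}, gene="G1")
        res = verify(cand("B", "A"), ref, marker_set(["G9"]))
        assert res.decision == "fallback_llm_rank" and res.chosen == ("B",)

    def test_empty_vocabulary_is_configuration_error(self):
        ref = ref_from_scores({"A": 1.0})
        ref.vocabulary = frozenset()
        with pytest.raises(ConfigurationError):
            verify(cand("A"), ref, marker_set(["G1"]))

    def test_chosen_never_scores_below_any_competitor(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            scores = {f"L{i}": float(rng.uniform(0, 10)) for i in range(4)}
            ref = ref_from_scores(scores)
            res = verify(cand(*scores), ref, marker_set(["G1"]))
            assert scores[res.chosen[0]] == max(scores.values())

    def test_scaling_down_a_loser_never_changes_the_winner(self):
        scores = {"A": 5.0, "B": 3.0, "C": 1.0}
        base = verify(cand(*scores), ref_from_scores(scores), marker_set(["G1"]))
        shrunk = dict(scores, B=0.3)
        after = verify(cand(*shrunk), ref_from_scores(shrunk), marker_set(["G1"]))
        assert after.chosen == base.chosen == ("A",)

    def test_raising_the_winner_never_unseats_it(self):
        scores = {"A": 5.0, "B": 3.0}
        for bump in (0.5, 2.0, 10.0):
            res = verify(cand("A", "B"), ref_from_scores({"A": 5.0 + bump, "B": 3.0}),
                         marker_set(["G1"]))
            assert res.chosen == ("A",)


class TestVerifyMixture:
    def test_threshold_keeps_near_max_candidates(self):
        ref = ref_from_scores({"A": 4.0, "B": 3.5, "C": 0.5})
        res = verify_mixture(cand("A", "B", "C"), ref, marker_set(["G1"]),
                             VerifyConfig(tau=0.8))
        assert res.chosen == ("A", "B")

    def test_threshold_drops_weak_candidates(self):
        ref = ref_from_scores({"A": 4.0, "B": 1.0})
        res = verify_mixture(cand("A", "B"), ref, marker_set(["G1"]),
                             VerifyConfig(tau=0.8))
        assert res.chosen == ("A",)

    def test_tau_one_with_unique_max_equals_single_mode(self):
        ref = ref_from_scores({"A": 4.0, "B": 3.9, "C": 1.0})
        ms = marker_set(["G1"])
        single = verify(cand("A", "B", "C"), ref, ms)
        mix = verify_mixture(cand("A", "B", "C"), ref, ms, VerifyConfig(tau=1.0))
        assert mix.chosen == single.chosen

    def test_invalid_tau_rejected(self):
        with pytest.raises(ConfigurationError):
            VerifyConfig(tau=0.0)
        with pytest.raises(ConfigurationError):
            VerifyConfig(tau=1.5)
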