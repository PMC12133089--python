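import numpy as np
import pandas as pd
import pytest

from celltypeagent import (ConfigurationError, WorldParams, build_prompt,
                           load_reference, make_mixture_queries,
                           make_scripted_llm, make_world, parse_candidates,
                           score_candidate, tissue_slice)
from celltypeagent.synthetic import SyntheticWorld


def tiny_params(**kw):
    base = dict(n_tissues=1, n_types=2, n_genes=10, markers_per_type=3,
                foreground_mean=5.0, background_mean=0.5, noise_scale=0.0)
    base.update(kw)
    return WorldParams(**base)


class TestMakeWorld:
    def test_noise_free_scores_are_exact(self):
        w = make_world(tiny_params(), seed=7)
        (ms, truth), other = w.queries[0], w.queries[1][1][0]
        view = tissue_slice(w.reference, ms.tissue, ms.genes)
        assert score_candidate(view, truth[0], ms.genes).score == pytest.approx(5.0)
        assert score_candidate(view, other, ms.genes).score == pytest.approx(0.5)

    def test_sibling_score_is_planted_mean(self):
        # sibling shares 2 of 3 markers; its unshared marker sits at background
        w = make_world(tiny_params(n_sibling_pairs=1, sibling_shared_frac=2 / 3,
                                   sibling_bleed=0.0), seed=7)
        ms, truth = w.queries[0]
        sib = w.siblings[truth[0]]
        view = tissue_slice(w.reference, ms.tissue, ms.genes)
        assert score_candidate(view, sib, ms.genes).score == pytest.approx((5 + 5 + 0.5) / 3)
        assert score_candidate(view, truth[0], ms.genes).score == pytest.approx(5.0)

    def test_sibling_bleed_raises_unshared_marker_expression(self):
        w = make_world(tiny_params(n_sibling_pairs=1, sibling_bleed=1.0), seed=7)
        ms, truth = w.queries[0]
        view = tissue_slice(w.reference, ms.tissue, ms.genes)
        assert score_candidate(view, w.siblings[truth[0]], ms.genes).score == \
            pytest.approx(5.0)

    def test_same_seed_same_world(self):
        a, b = make_world(tiny_params(noise_scale=0.5), 3), make_world(
            tiny_params(noise_scale=0.5), 3)
        pd.testing.assert_frame_equal(a.reference.entries, b.reference.entries)
        assert [(ms.genes, t) for ms, t in a.queries] == \
            [(ms.genes, t) for ms, t in b.queries]

    def test_parameter_validation(self):
        with pytest.raises(ConfigurationError):
            make_world(tiny_params(foreground_mean=0.4))  # fg <= bg
        with pytest.raises(ConfigurationError):
            make_world(tiny_params(markers_per_type=0))
        with pytest.raises(ConfigurationError):
            make_world(tiny_params(n_genes=4))  # cannot host markers

    def test_single_type_degenerate_world(self):
        w = make_world(tiny_params(n_types=1, n_genes=5), seed=1)
        assert len(w.queries) == 1

    def test_contaminated_queries_append_background_genes(self):
        w = make_world(WorldParams(contamination=2), seed=1)
        marker_genes = {g for mks in w.truth_markers.values() for g in mks}
        for ms, truth in w.queries:
            extras = [g for g in ms.genes if g not in w.truth_markers[truth[0]]]
            assert len(extras) == 2
            assert not set(extras) & marker_genes

    def test_save_load_roundtrip(self, tmp_path, clean_world):
        clean_world.save(tmp_path / "w")
        again = SyntheticWorld.load(tmp_path / "w")
        pd.testing.assert_frame_equal(again.reference.entries,
                                      clean_world.reference.entries)
        ref = load_reference(tmp_path / "w" / "snapshot.tsv")
        assert ref.vocabulary == clean_world.reference.vocabulary


class TestMixtureQueries:
    def test_union_interleaved_by_rank(self, clean_world):
        a, b = sorted(clean_world.truth_markers)[:2]
        (ms, truth), = make_mixture_queries(clean_world, [(a, b)])
        assert truth == (a, b)
        assert set(ms.genes) == set(clean_world.truth_markers[a]) | \
            set(clean_world.truth_markers[b])
        assert ms.genes[0] == clean_world.truth_markers[a][0]
        assert ms.genes[1] == clean_world.truth_markers[b][0]

    def test_degenerate_pair(self, clean_world):
        a = sorted(clean_world.truth_markers)[0]
        (ms, truth), = make_mixture_queries(clean_world, [(a, a)])
        assert truth == (a,)
        assert ms.genes == clean_world.truth_markers[a]

    def test_unknown_type_rejected(self, clean_world):
        with pytest.raises(ConfigurationError):
            make_mixture_queries(clean_world, [("Q", "Q")])


class TestScriptedLLM:
    def responses(self, world, backend):
        out = []
        for ms, truth in world.queries:
            text = backend.complete(build_prompt(ms, k=3).text)
            out.append((parse_candidates(text, k=3), truth))
        return out

    def test_always_first_puts_truth_on_top(self, clean_world):
        backend = make_scripted_llm(clean_world, k=3, seed=5)
        for names, truth in self.responses(clean_world, backend):
            assert names[0] == truth[0]
            assert len(names) == 3 and len(set(names)) == 3

    def test_wrong_first_puts_truth_second(self, clean_world):
        backend = make_scripted_llm(clean_world, k=3,
                                    truth_rank_policy="wrong_first", seed=5)
        for names, truth in self.responses(clean_world, backend):
            assert names[1] == truth[0] and names[0] != truth[0]

    def test_absent_prob_one_omits_truth(self, clean_world):
        backend = make_scripted_llm(clean_world, k=3, seed=5, absent_prob=1.0)
        for names, truth in self.responses(clean_world, backend):
            assert truth[0] not in names

    def test_uniform_random_rank_stays_within_k(self, clean_world):
        backend = make_scripted_llm(clean_world, k=3,
                                    truth_rank_policy="uniform_random", seed=5)
        ranks = {names.index(truth[0])
                 for names, truth in self.responses(clean_world, backend)}
        assert ranks <= {0, 1, 2} and len(ranks) > 1

    def test_same_seed_identical_response_stream(self, clean_world):
        prompts = [build_prompt(ms, k=3).text for ms, _ in clean_world.queries]
        a = make_scripted_llm(clean_world, k=3, seed=9)
        b = make_scripted_llm(clean_world, k=3, seed=9)
        assert [a.complete(p) for p in prompts] == [b.complete(p) for p in prompts]

    def test_sibling_first_forces_the_confusable_type(self, sibling_world):
        backend = make_scripted_llm(sibling_world, k=3, seed=5,
                                    distractor_policy="sibling_first")
        for ms, truth in sibling_world.queries:
            names = parse_candidates(backend.complete(build_prompt(ms, k=3).text), k=3)
            assert sibling_world.siblings[truth[0]] in names

    def test_mixture_prompt_lists_both_components(self, clean_world):
        a, b = sorted(clean_world.truth_markers)[:2]
        (ms, truth), = make_mixture_queries(clean_world, [(a, b)])
        backend = make_scripted_llm(clean_world, k=3, seed=5)
        names = parse_candidates(backend.complete(build_prompt(ms, k=3, mode="mixture").text), k=3)
        assert set(truth) <= set(names)
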