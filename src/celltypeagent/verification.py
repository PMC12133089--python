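"""Stage 2 of the agent: verify LLM candidates against measured expression.

Each candidate cell type proposed by the LLM is scored as the arithmetic
mean of the reference mean-expression of the cluster's marker genes in that
cell type, within the cluster's tissue.  The final annotation is the
candidate with the highest average marker expression — grounding the call
in empirical data rather than the model's ranking alone, which is the
mechanism that suppresses hallucinated labels.

Mixture mode keeps every candidate whose score reaches a fraction ``tau``
of the best score, so a marker list combining several cell types can be
annotated with all of its components.

When no candidate can be scored (names outside the vocabulary, no marker
coverage) the agent still annotates: it falls back to the LLM's top-ranked
candidate and labels the decision ``fallback_llm_rank`` so the weaker
evidence is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError
from .llm import CandidateList
from .markers import MarkerSet
from .reference import (DEFAULT_FUZZY_THRESHOLD, NameMatch, ReferenceMatrix,
                        SynonymTable, TissueView, normalize_name, tissue_slice)

#: Minimum marker genes that must be present in the reference for a
#: candidate's score to be defined.  1 keeps sparse reference coverage
#: usable; raise it to guard against single-gene flukes.
DEFAULT_MIN_OVERLAP = 1

#: Mixture mode keeps candidates scoring at least tau * best score.  The
#: relative-to-max rule is scale-free across expression units.
DEFAULT_TAU = 0.8


@dataclass(frozen=True)
class VerifyConfig:
    """Tunable parameters of the verification stage."""

    min_overlap: int = DEFAULT_MIN_OVERLAP
    tau: float = DEFAULT_TAU
    fuzzy_threshold: float = DEFAULT_FUZZY_THRESHOLD
    synonyms: SynonymTable | None = None

    def __post_init__(self):
        if self.min_overlap < 1:
            raise ConfigurationError(f"min_overlap must be >= 1, got {self.min_overlap}")
        if not (0.0 < self.tau <= 1.0):
            raise ConfigurationError(f"tau must be in (0, 1], got {self.tau}")


@dataclass(frozen=True)
class CandidateScore:
    """Evidence gathered for one candidate.

    ``score`` is None (undefined) when fewer than ``min_overlap`` marker
    genes have a reference entry for the matched label.
    """

    candidate_name: str
    matched_label: str | None
    n_overlap: int
    score: float | None

    def __post_init__(self):
        if self.score is not None and self.score < 0:
            raise ValueError("a defined score must be >= 0")


@dataclass(frozen=True)
class VerificationResult:
    """Final decision for one cluster.

    ``chosen`` holds exactly one label in single mode and one or more in
    mixture mode (descending score).  ``decision`` is ``verified`` when the
    choice maximizes the expression score, ``fallback_llm_rank`` when no
    candidate was scorable and the LLM's top candidate was kept.
    """

    cluster_id: str
    scores: tuple[CandidateScore, ...]
    chosen: tuple[str, ...]
    decision: str  # verified | fallback_llm_rank
    tissue_fallback: bool = False

    @property
    def chosen_label(self) -> str:
        return self.chosen[0]


def score_candidate(view: TissueView, label: str, genes, min_overlap: int = DEFAULT_MIN_OVERLAP,
                    candidate_name: str | None = None) -> CandidateScore:
    """Mean reference expression of the marker genes for one label.

    ``n_overlap`` counts marker genes with an entry for ``label`` in the
    view; the score is the arithmetic mean over exactly those entries, and
    is undefined below ``min_overlap``.  Marker genes absent from the
    reference are ignored, not counted as zeros.
    """
    if min_overlap < 1:
        raise ConfigurationError(f"min_overlap must be >= 1, got {min_overlap}")
    row = view.entries.get(label, {})
    values = [row[g] for g in genes if g in row]
    n = len(values)
    score = sum(values) / n if n >= min_overlap else None
    return CandidateScore(candidate_name=candidate_name if candidate_name is not None else label,
                          matched_label=label, n_overlap=n, score=score)


def _score_all(candidates: CandidateList, ref: ReferenceMatrix,
               marker_set: MarkerSet, config: VerifyConfig):
    if not ref.vocabulary:
        raise ConfigurationError("reference vocabulary is empty")
    if not candidates.candidates:
        raise ConfigurationError(f"no candidates for cluster {candidates.cluster_id!r}")
    view = tissue_slice(ref, marker_set.tissue, marker_set.genes)
    scores: list[CandidateScore] = []
    for name in candidates.candidates:
        match = normalize_name(name, config.synonyms, ref.vocabulary,
                               fuzzy_threshold=config.fuzzy_threshold)
        if match.matched_label is None:
            scores.append(CandidateScore(name, None, 0, None))
        else:
            scores.append(score_candidate(view, match.matched_label, marker_set.genes,
                                          min_overlap=config.min_overlap,
                                          candidate_name=name))
    return view, scores


def _fallback(candidates: CandidateList, scores: list[CandidateScore],
              view: TissueView, cluster_id: str) -> VerificationResult:
    top = scores[0]
    chosen = top.matched_label if top.matched_label is not None else top.candidate_name
    return VerificationResult(cluster_id=cluster_id, scores=tuple(scores),
                              chosen=(chosen,), decision="fallback_llm_rank",
                              tissue_fallback=view.tissue_fallback)


def verify(candidates: CandidateList, ref: ReferenceMatrix, marker_set: MarkerSet,
           config: VerifyConfig | None = None) -> VerificationResult:
    """Choose the single candidate with the highest mean marker expression.

    Score ties resolve by better (lower-index) LLM rank, then
    lexicographically on the label: the database overrides the LLM prior
    only with strictly better evidence.  If nothing is scorable the LLM's
    top candidate is kept with ``decision="fallback_llm_rank"``.
    """
    config = config or VerifyConfig()
    view, scores = _score_all(candidates, ref, marker_set, config)
    scored = [(s, i) for i, s in enumerate(scores) if s.score is not None]
    if not scored:
        return _fallback(candidates, scores, view, candidates.cluster_id)
    best, _ = min(scored, key=lambda t: (-t[0].score, t[1], t[0].matched_label))
    return VerificationResult(cluster_id=candidates.cluster_id, scores=tuple(scores),
                              chosen=(best.matched_label,), decision="verified",
                              tissue_fallback=view.tissue_fallback)


def verify_mixture(candidates: CandidateList, ref: ReferenceMatrix,
                   marker_set: MarkerSet,
                   config: VerifyConfig | None = None) -> VerificationResult:
    """Keep every candidate whose score reaches ``tau`` x the best score.

    Chosen labels are ordered by descending score (ties by LLM rank).  With
    ``tau=1.0`` and a unique maximum this reduces to :func:`verify`.
    """
    config = config or VerifyConfig()
    view, scores = _score_all(candidates, ref, marker_set, config)
    scored = [(s, i) for i, s in enumerate(scores) if s.score is not None]
    if not scored:
        return _fallback(candidates, scores, view, candidates.cluster_id)
    best_score = max(s.score for s, _ in scored)
    keep = [(s, i) for s, i in scored if s.score >= config.tau * best_score]
    keep.sort(key=lambda t: (-t[0].score, t[1], t[0].matched_label))
    chosen, seen = [], set()
    for s, _ in keep:
        if s.matched_label not in seen:
            chosen.append(s.matched_label)
            seen.add(s.matched_label)
    return VerificationResult(cluster_id=candidates.cluster_id, scores=tuple(scores),
                              chosen=tuple(chosen), decision="verified",
                              tissue_fallback=view.tissue_fallback)
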