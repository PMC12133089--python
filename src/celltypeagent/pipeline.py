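"""End-to-end annotation runs and method baselines.

Ties the stages together: marker sets -> LLM candidate inference ->
expression verification, per cluster, with failure isolation (one bad
cluster never aborts the run).  Also provides the two ablation baselines
the agent is compared against:

* ``llm_only`` — trust the LLM's rank-1 candidate, no verification;
* ``db_only`` — skip the LLM and pick the vocabulary cell type with the
  highest mean marker expression, which is ambiguity-prone whenever
  several types share similarly high marker expression.

``run_benchmark`` runs any subset of the three methods on a synthetic
world's queries, grades them against the planted truth and tabulates
per-tissue and overall agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import CellTypeAgentError, ConfigurationError, EmptyInputError
from .evaluation import (AgreementReport, PartialRules, compare_methods,
                         grade_annotations)
from .llm import (DEFAULT_K, DEFAULT_MAX_RETRIES, AuditLog, LLMBackend,
                  infer_candidates)
from .markers import DEFAULT_MARKERS_PER_CLUSTER, MarkerSet
from .reference import (DEFAULT_FUZZY_THRESHOLD, ReferenceMatrix, SynonymTable,
                        normalize_name, tissue_slice)
from .verification import (DEFAULT_MIN_OVERLAP, DEFAULT_TAU, VerificationResult,
                           VerifyConfig, score_candidate, verify, verify_mixture)


@dataclass(frozen=True)
class AgentConfig:
    """All tunable parameters of one annotation run."""

    k: int = DEFAULT_K
    m: int = DEFAULT_MARKERS_PER_CLUSTER
    mode: str = "single"                       # single | mixture
    min_overlap: int = DEFAULT_MIN_OVERLAP
    tau: float = DEFAULT_TAU
    fuzzy_threshold: float = DEFAULT_FUZZY_THRESHOLD
    max_retries: int = DEFAULT_MAX_RETRIES
    temperature: float = 0.0
    synonyms: SynonymTable | None = None

    def verify_config(self) -> VerifyConfig:
        return VerifyConfig(min_overlap=self.min_overlap, tau=self.tau,
                            fuzzy_threshold=self.fuzzy_threshold,
                            synonyms=self.synonyms)


@dataclass
class AnnotationRun:
    """Results plus per-cluster failures of one annotation pass."""

    results: list[VerificationResult]
    failures: list[tuple[str, str]]  # (cluster_id, error message)

    def chosen(self) -> dict[str, tuple[str, ...]]:
        return {r.cluster_id: r.chosen for r in self.results}

    def to_frame(self, k: int = DEFAULT_K) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"cluster_id": r.cluster_id, "chosen": ";".join(r.chosen),
                   "decision": r.decision, "tissue_fallback": r.tissue_fallback}
            for i in range(k):
                s = r.scores[i] if i < len(r.scores) else None
                row[f"cand{i + 1}_name"] = s.candidate_name if s else ""
                row[f"cand{i + 1}_label"] = (s.matched_label or "") if s else ""
                row[f"cand{i + 1}_n_overlap"] = s.n_overlap if s else ""
                row[f"cand{i + 1}_score"] = (
                    round(s.score, 6) if s and s.score is not None else "")
            rows.append(row)
        return pd.DataFrame(rows)


def annotate_clusters(marker_sets: Sequence[MarkerSet], backend: LLMBackend,
                      ref: ReferenceMatrix, config: AgentConfig | None = None,
                      audit: AuditLog | None = None,
                      seed: int | None = None) -> AnnotationRun:
    """Run the full two-stage agent over a batch of clusters.

    Each cluster is trimmed to the top ``m`` markers, sent to the backend
    for ``k`` ranked candidates, and verified against the reference.
    Failures (unparseable responses after retries) are collected per
    cluster, never raised mid-batch.
    """
    config = config or AgentConfig()
    if not marker_sets:
        raise EmptyInputError("no marker sets to annotate")
    vconf = config.verify_config()
    results, failures = [], []
    for ms in marker_sets:
        trimmed = ms.top(config.m)
        try:
            cands = infer_candidates(backend, trimmed, k=config.k, mode=config.mode,
                                     max_retries=config.max_retries,
                                     temperature=config.temperature, seed=seed,
                                     audit=audit)
            if config.mode == "mixture":
                results.append(verify_mixture(cands, ref, trimmed, vconf))
            else:
                results.append(verify(cands, ref, trimmed, vconf))
        except CellTypeAgentError as exc:
            failures.append((ms.cluster_id, str(exc)))
    return AnnotationRun(results=results, failures=failures)


def llm_only_annotate(marker_sets: Sequence[MarkerSet], backend: LLMBackend,
                      ref: ReferenceMatrix | None = None,
                      config: AgentConfig | None = None,
                      seed: int | None = None) -> dict[str, tuple[str, ...]]:
    """Baseline: trust the LLM's top-ranked candidate, no verification.

    When a reference is supplied its vocabulary is used only to map the
    free-text name to a canonical label (so grading is comparable); the
    expression evidence is never consulted.
    """
    config = config or AgentConfig()
    out: dict[str, tuple[str, ...]] = {}
    for ms in marker_sets:
        trimmed = ms.top(config.m)
        cands = infer_candidates(backend, trimmed, k=config.k, mode=config.mode,
                                 max_retries=config.max_retries,
                                 temperature=config.temperature, seed=seed)
        top = cands.candidates[0]
        if ref is not None and ref.vocabulary:
            match = normalize_name(top, config.synonyms, ref.vocabulary,
                                   fuzzy_threshold=config.fuzzy_threshold)
            if match.matched_label is not None:
                top = match.matched_label
        out[ms.cluster_id] = (top,)
    return out


def db_only_annotate(marker_sets: Sequence[MarkerSet], ref: ReferenceMatrix,
                     config: AgentConfig | None = None) -> dict[str, tuple[str, ...]]:
    """Baseline: no LLM — score every vocabulary cell type and pick the max.

    Ties break lexicographically on the label.  This is the
    database-only ablation whose ambiguity (several types with similarly
    high average marker expression) motivates the LLM shortlisting stage.
    """
    config = config or AgentConfig()
    if not ref.vocabulary:
        raise ConfigurationError("reference vocabulary is empty")
    out: dict[str, tuple[str, ...]] = {}
    for ms in marker_sets:
        trimmed = ms.top(config.m)
        view = tissue_slice(ref, trimmed.tissue, trimmed.genes)
        best_label, best_score = None, None
        for label in sorted(ref.vocabulary):
            cs = score_candidate(view, label, trimmed.genes,
                                 min_overlap=config.min_overlap)
            if cs.score is None:
                continue
            if best_score is None or cs.score > best_score:
                best_label, best_score = label, cs.score
        out[ms.cluster_id] = (best_label,) if best_label is not None else ("unassigned",)
    return out


METHODS = ("agent", "llm_only", "db_only")


def run_benchmark(world, backend: LLMBackend,
                  methods: Sequence[str] = METHODS,
                  config: AgentConfig | None = None,
                  synonyms: SynonymTable | None = None,
                  partial_rules: PartialRules | None = None,
                  queries: Sequence[tuple[MarkerSet, tuple[str, ...]]] | None = None,
                  ) -> tuple[pd.DataFrame, dict[str, AgreementReport]]:
    """Run annotation methods on a world's queries and grade against truth.

    Returns the method x (per-tissue, overall) agreement table and the
    per-method :class:`AgreementReport` objects.  Tissues play the role of
    datasets in the aggregation.
    """
    config = config or AgentConfig()
    for m in methods:
        if m not in METHODS:
            raise ConfigurationError(f"unknown method {m!r}; choose from {METHODS}")
    qs = list(queries) if queries is not None else list(world.queries)
    if not qs:
        raise EmptyInputError("world has no queries")
    marker_sets = [ms for ms, _ in qs]
    truth = {ms.cluster_id: t for ms, t in qs}
    datasets = {ms.cluster_id: ms.tissue for ms, _ in qs}

    predictions: dict[str, dict[str, tuple[str, ...]]] = {}
    for method in methods:
        if method == "agent":
            run = annotate_clusters(marker_sets, backend, world.reference, config)
            if run.failures:
                raise CellTypeAgentError(
                    f"agent failed on clusters: {[c for c, _ in run.failures]}")
            predictions[method] = run.chosen()
        elif method == "llm_only":
            predictions[method] = llm_only_annotate(marker_sets, backend,
                                                    world.reference, config)
        else:
            predictions[method] = db_only_annotate(marker_sets, world.reference, config)

    reports = {m: grade_annotations(pred, truth, synonyms=synonyms,
                                    partial_rules=partial_rules, datasets=datasets)
               for m, pred in predictions.items()}
    return compare_methods(reports), reports
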