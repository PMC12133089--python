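"""Agreement grading of predicted annotations against manual truth.

Benchmarking an annotator means comparing its per-cluster labels with the
manual annotations of the original studies.  Agreement is graded on the
three-level convention used throughout the automated-annotation
literature: 1.0 for a fully matching label (exact or synonym), 0.5 for a
partially matching one (a declared broader/narrower pair such as
"T cell" vs "CD8-positive T cell", or a head-noun token subset), 0.0 for a
mismatch.  Dataset-level scores are unweighted means of cluster grades;
the overall score is the mean of dataset means so every dataset counts
equally regardless of its cluster count (a pooled mode is available).

Partial-match relations are supplied as data (a broader/narrower TSV), not
inferred from an ontology at run time, keeping grading deterministic and
offline.  The grading policy is pluggable: pass different level values to
:func:`grade` callers if a benchmark uses another rubric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AlignmentError, EmptyInputError
from .reference import SynonymTable, canonical_form


class PartialRules:
    """Declared broader/narrower cell-type pairs granting half credit."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._pairs = {frozenset((canonical_form(a), canonical_form(b)))
                       for a, b in pairs}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PartialRules":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["broader", "narrower"], dtype=str, comment="#")
        return cls(zip(df["broader"], df["narrower"]))

    def related(self, a: str, b: str) -> bool:
        return frozenset((canonical_form(a), canonical_form(b))) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)


def _head_noun_subset(a: str, b: str) -> bool:
    """True when one canonical form's tokens are a proper subset of the
    other's and both share the final (head-noun) token."""
    ta, tb = a.split(), b.split()
    if not ta or not tb or ta[-1] != tb[-1]:
        return False
    sa, sb = set(ta), set(tb)
    return sa < sb or sb < sa


def grade(predicted: str, truth: str,
          synonyms: SynonymTable | None = None,
          partial_rules: PartialRules | None = None) -> tuple[float, str]:
    """Grade one predicted label against one truth label.

    Returns ``(level, basis)`` with level in {1.0, 0.5, 0.0} and basis in
    {exact, synonym, partial, mismatch}.  Exact and synonym grading are
    symmetric in their arguments.
    """
    if not predicted.strip() or not truth.strip():
        raise ValueError("predicted and truth labels must be non-empty")
    cp, ct = canonical_form(predicted), canonical_form(truth)
    if cp == ct:
        return 1.0, "exact"
    if synonyms is not None:
        rp = synonyms.lookup(predicted)
        rt = synonyms.lookup(truth)
        cp2 = canonical_form(rp) if rp is not None else cp
        ct2 = canonical_form(rt) if rt is not None else ct
        if cp2 == ct2:
            return 1.0, "synonym"
    else:
        cp2, ct2 = cp, ct
    if partial_rules is not None and partial_rules.related(predicted, truth):
        return 0.5, "partial"
    if _head_noun_subset(cp, ct):
        return 0.5, "partial"
    return 0.0, "mismatch"


def grade_mixture(predicted: Iterable[str], truth: Iterable[str],
                  synonyms: SynonymTable | None = None,
                  partial_rules: PartialRules | None = None) -> tuple[float, str]:
    """Grade a predicted label set against a truth label set.

    Each truth label contributes its best grade against any predicted label
    (1.0 full, 0.5 partial, 0 otherwise); the level is the sum divided by
    the truth-set size.  On singleton sets this equals :func:`grade`.
    """
    predicted = list(predicted)
    truth = list(truth)
    if not predicted or not truth:
        raise ValueError("predicted and truth sets must be non-empty")
    if len(predicted) == 1 and len(truth) == 1:
        return grade(predicted[0], truth[0], synonyms, partial_rules)
    total = 0.0
    any_partial = False
    for t in truth:
        best = 0.0
        for p in predicted:
            level, _ = grade(p, t, synonyms, partial_rules)
            best = max(best, level)
            if best == 1.0:
                break
        if best == 0.5:
            any_partial = True
        total += best
    level = total / len(truth)
    basis = "exact" if level == 1.0 else ("mismatch" if level == 0.0 else "partial")
    if any_partial and basis == "exact":  # unreachable, kept for clarity of intent
        basis = "partial"
    return level, basis


@dataclass(frozen=True)
class ClusterGrade:
    """Graded agreement for one cluster."""

    cluster_id: str
    predicted: tuple[str, ...]
    truth: tuple[str, ...]
    level: float
    basis: str
    dataset: str = "dataset"


@dataclass
class AgreementReport:
    """Per-cluster grades plus the dataset-level mean agreement."""

    grades: list[ClusterGrade]

    @property
    def mean(self) -> float:
        if not self.grades:
            raise EmptyInputError("no graded clusters")
        return sum(g.level for g in self.grades) / len(self.grades)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"cluster_id": g.cluster_id, "dataset": g.dataset,
              "predicted": ";".join(g.predicted), "truth": ";".join(g.truth),
              "level": g.level, "basis": g.basis} for g in self.grades])


def grade_annotations(predicted: Mapping[str, Sequence[str] | str],
                      truth: Mapping[str, Sequence[str] | str],
                      synonyms: SynonymTable | None = None,
                      partial_rules: PartialRules | None = None,
                      datasets: Mapping[str, str] | None = None) -> AgreementReport:
    """Grade a full prediction table against a truth table.

    Values may be single labels or label sets (mixture mode); singleton
    sets dispatch to plain :func:`grade`.  Cluster sets must match exactly;
    a mismatch raises :class:`AlignmentError` listing the difference.
    """
    pk, tk = set(predicted), set(truth)
    if pk != tk:
        missing = tuple(sorted(tk - pk))
        extra = tuple(sorted(pk - tk))
        raise AlignmentError(
            f"cluster sets differ: missing from predictions {list(missing)}, "
            f"unknown to truth {list(extra)}", missing=missing, extra=extra)

    def as_set(v) -> tuple[str, ...]:
        if isinstance(v, str):
            return tuple(x.strip() for x in v.split(";") if x.strip())
        return tuple(v)

    grades = []
    for cid in sorted(predicted, key=str):
        p, t = as_set(predicted[cid]), as_set(truth[cid])
        level, basis = grade_mixture(p, t, synonyms, partial_rules)
        grades.append(ClusterGrade(cluster_id=cid, predicted=p, truth=t,
                                   level=level, basis=basis,
                                   dataset=(datasets or {}).get(cid, "dataset")))
    return AgreementReport(grades)


def aggregate(report: AgreementReport, pooled: bool = False) -> dict:
    """Aggregate cluster grades into per-dataset and overall means.

    By default every dataset is weighted equally (the overall score is the
    mean of dataset means); ``pooled=True`` averages over clusters
    directly.
    """
    if not report.grades:
        raise EmptyInputError("no graded clusters to aggregate")
    df = report.to_frame()
    group_means = df.groupby("dataset")["level"].mean().sort_index()
    overall = float(df["level"].mean()) if pooled else float(group_means.mean())
    return {"per_dataset": {k: float(v) for k, v in group_means.items()},
            "overall": overall, "n_clusters": int(len(df))}


def compare_methods(reports: Mapping[str, AgreementReport],
                    pooled: bool = False) -> pd.DataFrame:
    """Tabulate per-dataset and overall agreement for several annotators.

    All methods must be graded on identical cluster sets; rows are ordered
    by method name, columns by dataset name with ``overall`` last.
    """
    if not reports:
        raise EmptyInputError("no reports to compare")
    cluster_sets = {m: frozenset(g.cluster_id for g in r.grades)
                    for m, r in reports.items()}
    base = next(iter(cluster_sets.values()))
    for m, cs in cluster_sets.items():
        if cs != base:
            raise AlignmentError(
                f"method {m!r} graded on a different cluster set: "
                f"missing {sorted(base - cs)}, extra {sorted(cs - base)}",
                missing=tuple(sorted(base - cs)), extra=tuple(sorted(cs - base)))
    rows = {}
    for method in sorted(reports):
        agg = aggregate(reports[method], pooled=pooled)
        rows[method] = {**agg["per_dataset"], "overall": agg["overall"]}
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    cols = [c for c in sorted(table.columns) if c != "overall"] + ["overall"]
    return table[cols]
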