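"""Tissue-stratified mean-expression reference and cell-type name matching.

The verification stage grounds LLM-proposed labels in measured expression.
Its evidence base is a :class:`ReferenceMatrix`: mean expression per
(tissue, cell type, gene), the shape of an aggregate extracted from a large
public single-cell repository such as the CellxGene census (50 tissues,
700+ cell types).  The package ships a pinned local-snapshot format (long
TSV + JSON sidecar) so that census-derived and synthetic snapshots are
interchangeable and everything runs offline; a live client is specified
only as the :class:`ExpressionSource` contract.

LLM candidate names are free text ("Pericyte cells", "NK cell"), so this
module also normalizes names to the reference vocabulary: canonical-form
exact match, then synonym lookup, then conservative fuzzy matching.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import pandas as pd

from .errors import ConfigurationError, SnapshotFormatError, SnapshotLoadError

#: Default minimum normalized edit similarity for a fuzzy name match.
#: Accepts plural/hyphenation variants, rejects cross-type confusions.
DEFAULT_FUZZY_THRESHOLD = 0.85

_SNAPSHOT_COLUMNS = ("tissue", "cell_type", "gene", "mean_expr")


def canonical_form(name: str) -> str:
    """Canonicalize a cell-type (or tissue) name for matching.

    Lower-cases, maps ``_``/``-`` to spaces, collapses whitespace, strips a
    trailing "cell"/"cells" token, and singularizes the final token (drops a
    plain plural "s").  ``"Pericyte cells"`` and ``"pericytes"`` both map to
    ``"pericyte"``.
    """
    s = name.strip().lower()
    s = re.sub(r"[-_/]", " ", s)
    s = re.sub(r"\s+", " ", s).strip(" .,;:")
    tokens = s.split(" ")
    if len(tokens) > 1 and tokens[-1] in ("cell", "cells"):
        tokens = tokens[:-1]
    if tokens and len(tokens[-1]) > 3 and tokens[-1].endswith("s") \
            and not tokens[-1].endswith(("ss", "us", "is")):
        tokens[-1] = tokens[-1][:-1]
    return " ".join(tokens)


class SynonymTable:
    """Mapping from free-text aliases to canonical vocabulary labels.

    Loaded from a two-column TSV (``alias <tab> canonical``); lookups are on
    the canonical form of the alias, so case and plural variants of an alias
    resolve too.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        for alias, label in (mapping or {}).items():
            self._map[canonical_form(alias)] = label

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymTable":
        df = pd.read_csv(path, sep="\t", header=None, names=["alias", "canonical"],
                         dtype=str, comment="#")
        return cls(dict(zip(df["alias"], df["canonical"])))

    def lookup(self, query: str) -> str | None:
        return self._map.get(canonical_form(query))

    def __len__(self) -> int:
        return len(self._map)


@dataclass(frozen=True)
class NameMatch:
    """Result of normalizing one free-text name against a vocabulary."""

    query: str
    matched_label: str | None
    method: str  # exact | synonym | fuzzy | none
    similarity: float

    def __post_init__(self):
        if self.method == "exact" and self.similarity != 1.0:
            raise ValueError("exact match implies similarity 1.0")
        if self.method == "none" and self.matched_label is not None:
            raise ValueError("method 'none' implies no matched label")


def normalize_name(query: str, synonyms: SynonymTable | None,
                   vocabulary: Iterable[str],
                   fuzzy_threshold: float = DEFAULT_FUZZY_THRESHOLD) -> NameMatch:
    """Match a free-text cell-type name to a vocabulary label.

    Pipeline: (1) canonical-form exact match; (2) synonym lookup on the
    canonical form; (3) fuzzy match by normalized edit similarity, accepted
    only when the best score reaches ``fuzzy_threshold`` and is unique.
    No-match is a value (``method="none"``), not an error.
    """
    vocab = list(vocabulary)
    if not vocab:
        raise ConfigurationError("vocabulary must be non-empty")
    canon_to_label: dict[str, str] = {}
    for label in vocab:
        canon_to_label.setdefault(canonical_form(label), label)

    cq = canonical_form(query)
    if cq in canon_to_label:
        return NameMatch(query, canon_to_label[cq], "exact", 1.0)

    if synonyms is not None:
        target = synonyms.lookup(query)
        if target is not None:
            ct = canonical_form(target)
            if ct in canon_to_label:
                return NameMatch(query, canon_to_label[ct], "synonym", 1.0)

    best_label, best_sim, runner_up = None, 0.0, 0.0
    for canon, label in canon_to_label.items():
        sim = SequenceMatcher(None, cq, canon).ratio()
        if sim > best_sim:
            best_label, best_sim, runner_up = label, sim, best_sim
        elif sim > runner_up:
            runner_up = sim
    if best_label is not None and best_sim >= fuzzy_threshold and best_sim > runner_up:
        return NameMatch(query, best_label, "fuzzy", best_sim)
    return NameMatch(query, None, "none", 0.0)


@dataclass
class TissueView:
    """Expression restricted to one tissue and a gene list.

    ``entries[label][gene]`` is the mean expression of ``gene`` in cell type
    ``label``.  ``tissue_fallback`` flags that the requested tissue was
    absent and values are means over all tissues.
    """

    tissue: str
    genes: tuple[str, ...]
    entries: dict[str, dict[str, float]]
    tissue_fallback: bool = False

    def labels(self) -> list[str]:
        return list(self.entries)


class ExpressionSource(Protocol):
    """Contract for any mean-expression provider (snapshot or live client).

    A live census client would implement ``fetch_mean_expression`` by
    querying the remote service for (species, tissue, cell types, genes);
    the shipped implementation is the local :class:`ReferenceMatrix`.
    """

    def fetch_mean_expression(self, tissue: str, cell_types: Sequence[str],
                              genes: Sequence[str]) -> "TissueView": ...


class ReferenceMatrix:
    """Validated tissue-stratified mean-expression reference.

    Parameters
    ----------
    entries
        Long-format frame with columns tissue, cell_type, gene, mean_expr.
    species
        Species the snapshot was aggregated for.
    snapshot_meta
        Provenance: source name, version/date, expression unit.  The scorer
        consumes values as-is (typically mean log-normalized expression);
        the unit is declared here, never re-transformed.
    ontology_ids
        Optional mapping label -> Cell Ontology ID; metadata only, not used
        for matching.
    """

    def __init__(self, entries: pd.DataFrame, species: str = "Homo sapiens",
                 snapshot_meta: Mapping[str, str] | None = None,
                 ontology_ids: Mapping[str, str] | None = None):
        df = entries.loc[:, list(_SNAPSHOT_COLUMNS)].copy()
        df["mean_expr"] = pd.to_numeric(df["mean_expr"])
        bad = df.index[~(df["mean_expr"].ge(0) & df["mean_expr"].apply(math.isfinite))]
        if len(bad):
            raise SnapshotLoadError(
                f"mean_expr must be finite and >= 0; first offending row index {bad[0]}")
        dup = df.duplicated(subset=["tissue", "cell_type", "gene"])
        if dup.any():
            r = df[dup].iloc[0]
            raise SnapshotLoadError(
                f"duplicate (tissue, cell_type, gene) key: "
                f"({r.tissue!r}, {r.cell_type!r}, {r.gene!r})")
        self.entries = df.reset_index(drop=True)
        self.species = species
        self.snapshot_meta = dict(snapshot_meta or {})
        self.ontology_ids = dict(ontology_ids or {})
        self.vocabulary: frozenset[str] = frozenset(df["cell_type"].unique())

    def __len__(self) -> int:
        return len(self.entries)

    def tissues(self) -> list[str]:
        return sorted(self.entries["tissue"].unique())

    def fetch_mean_expression(self, tissue, cell_types, genes):
        view = tissue_slice(self, tissue, genes)
        keep = set(cell_types)
        view.entries = {k: v for k, v in view.entries.items() if k in keep}
        return view

    def to_tsv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the snapshot TSV (sorted for byte reproducibility) + sidecar."""
        path = Path(path)
        out = self.entries.sort_values(list(_SNAPSHOT_COLUMNS[:3])).reset_index(drop=True)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")
        if sidecar:
            meta = {"species": self.species, **self.snapshot_meta}
            path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_reference(path: str | Path) -> ReferenceMatrix:
    """Load a reference snapshot from long-format TSV.

    Expects header ``tissue  cell_type  gene  mean_expr``; an optional JSON
    sidecar next to the file (same stem, ``.json``) carries species, unit,
    source and version.  Negative, non-numeric or duplicated rows raise
    :class:`SnapshotLoadError` citing the row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"tissue": str, "cell_type": str, "gene": str})
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SnapshotFormatError(f"cannot read snapshot {path}: {exc}") from None
    missing = [c for c in _SNAPSHOT_COLUMNS if c not in df.columns]
    if missing:
        raise SnapshotFormatError(
            f"snapshot {path} is missing column(s) {missing}; expected {_SNAPSHOT_COLUMNS}")
    try:
        df["mean_expr"] = pd.to_numeric(df["mean_expr"])
    except (ValueError, TypeError):
        bad = df.index[pd.to_numeric(df["mean_expr"], errors="coerce").isna()][0]
        raise SnapshotLoadError(
            f"non-numeric mean_expr at data row {bad + 1} of {path}") from None
    neg = df.index[df["mean_expr"] < 0]
    if len(neg):
        raise SnapshotLoadError(f"negative mean_expr at data row {neg[0] + 1} of {path}")

    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    species = meta.pop("species", "Homo sapiens")
    return ReferenceMatrix(df, species=species, snapshot_meta=meta)


def tissue_slice(ref: ReferenceMatrix, tissue: str,
                 genes: Sequence[str]) -> TissueView:
    """Restrict the reference to one tissue and a gene list.

    Tissue names compare case-insensitively after whitespace collapse.  If
    the tissue is absent from the reference the view falls back to the mean
    over all tissues per (cell_type, gene) and sets ``tissue_fallback``.
    An empty gene list yields an empty view.
    """
    genes = tuple(genes)
    df = ref.entries
    want = canonical_form(tissue) if tissue else ""
    tissue_map = {canonical_form(t): t for t in df["tissue"].unique()}
    fallback = want not in tissue_map
    if not genes:
        return TissueView(tissue=tissue, genes=(), entries={}, tissue_fallback=fallback)
    sub = df[df["gene"].isin(genes)]
    if fallback:
        sub = (sub.groupby(["cell_type", "gene"], as_index=False)["mean_expr"].mean())
    else:
        sub = sub[sub["tissue"] == tissue_map[want]]
    entries: dict[str, dict[str, float]] = {}
    for label, gene, value in zip(sub["cell_type"], sub["gene"], sub["mean_expr"]):
        entries.setdefault(label, {})[gene] = float(value)
    return TissueView(tissue=tissue, genes=genes, entries=entries,
                      tissue_fallback=fallback)
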