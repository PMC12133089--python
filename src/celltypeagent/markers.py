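"""Reading differential-expression marker tables and selecting top markers.

Cell type annotation starts from the output of a differential-expression
run (Seurat ``FindAllMarkers``, ``scanpy.tl.rank_genes_groups`` or similar):
a long table with one row per (cluster, gene) and an effect-size or rank
column.  This module parses such tables into :class:`MarkerRecord` rows and
reduces them to one ordered :class:`MarkerSet` per cluster — the top *m*
genes by effect size — which is the unit the annotation agent consumes.

Differential expression itself is out of scope; only its output is read.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, EmptyInputError

logger = logging.getLogger(__name__)

#: Default number of markers kept per cluster. More markers generally
#: improve annotation quality; 10 is a common reporting depth for
#: FindAllMarkers-style tables and is configurable everywhere.
DEFAULT_MARKERS_PER_CLUSTER = 10

_MOUSE_HINTS = ("mus musculus", "mouse", "m. musculus")


def normalize_gene_symbol(gene: str, species: str) -> str:
    """Case-normalize a gene symbol by species convention.

    Human (HGNC) symbols are upper-case (``ACTA2``); mouse (MGI) symbols are
    capitalized (``Acta2``).  The reference snapshot must use the same
    convention for overlap counting to work.
    """
    g = gene.strip()
    s = species.strip().lower()
    if s in ("mus", "mm") or any(h in s for h in _MOUSE_HINTS):
        return g[:1].upper() + g[1:].lower()
    return g.upper()


@dataclass(frozen=True)
class MarkerRecord:
    """One (cluster, gene) row of a marker table.

    ``rank_key`` is oriented so that larger is better (an ascending rank
    column is negated at read time).
    """

    cluster_id: str
    gene: str
    rank_key: float

    def __post_init__(self):
        if not self.gene.strip():
            raise ValueError("gene symbol must be non-empty")


@dataclass(frozen=True)
class MarkerSet:
    """Ordered top marker genes for one cluster, with tissue/species context."""

    cluster_id: str
    tissue: str
    species: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) < 1:
            raise ValueError("a MarkerSet needs at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("marker genes must be unique within a cluster")

    def top(self, m: int) -> "MarkerSet":
        """Prefix of the ``m`` highest-ranked markers (all, if fewer exist)."""
        if m < 1:
            raise ConfigurationError(f"m must be >= 1, got {m}")
        if m >= len(self.genes):
            return self
        return replace(self, genes=self.genes[:m])


@dataclass(frozen=True)
class MarkerTableDialect:
    """Column mapping for a marker table.

    ``ascending=True`` means smaller values are better (an explicit rank
    column where 1 is the top gene); the default suits effect-size columns
    such as ``avg_log2FC`` where larger is better.
    """

    cluster_col: str = "cluster"
    gene_col: str = "gene"
    rank_col: str = "avg_log2FC"
    ascending: bool = False

    @classmethod
    def from_mapping(cls, mapping: dict) -> "MarkerTableDialect":
        known = {k: v for k, v in mapping.items()
                 if k in ("cluster_col", "gene_col", "rank_col", "ascending")}
        return cls(**known)


def read_marker_table(path: str | Path,
                      dialect: MarkerTableDialect | dict | None = None) -> list[MarkerRecord]:
    """Read a TSV/CSV marker table into :class:`MarkerRecord` rows.

    Rows with an empty gene symbol are skipped.  A duplicated
    (cluster, gene) pair keeps the row with the higher rank_key and emits a
    warning.  A missing mapped column raises :class:`ConfigurationError`
    naming the column; a file with no rows raises :class:`EmptyInputError`.
    """
    if dialect is None:
        dialect = MarkerTableDialect()
    elif isinstance(dialect, dict):
        dialect = MarkerTableDialect.from_mapping(dialect)

    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"marker table {path} is empty") from None
    except csv.Error:
        # sniffing fails on empty or header-only files; fall back to the extension
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        try:
            df = pd.read_csv(path, sep=sep)
        except pd.errors.EmptyDataError:
            raise EmptyInputError(f"marker table {path} is empty") from None
    if df.empty:
        raise EmptyInputError(f"marker table {path} has no data rows")

    for attr in ("cluster_col", "gene_col", "rank_col"):
        col = getattr(dialect, attr)
        if col not in df.columns:
            raise ConfigurationError(
                f"marker table {path} is missing the mapped {attr.removesuffix('_col')} "
                f"column {col!r} (present: {list(df.columns)})")

    try:
        rank_values = pd.to_numeric(df[dialect.rank_col])
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(
            f"rank column {dialect.rank_col!r} is not numeric: {exc}") from None
    if dialect.ascending:
        rank_values = -rank_values

    best: dict[tuple[str, str], MarkerRecord] = {}
    order: list[tuple[str, str]] = []
    for cluster, gene, rank in zip(df[dialect.cluster_col].astype(str),
                                   df[dialect.gene_col], rank_values):
        if pd.isna(gene) or not str(gene).strip():
            continue
        gene = str(gene).strip()
        key = (cluster, gene)
        rec = MarkerRecord(cluster_id=cluster, gene=gene, rank_key=float(rank))
        if key in best:
            warnings.warn(
                f"duplicate marker row for cluster {cluster!r} gene {gene!r}; "
                "keeping the higher-ranked one", stacklevel=2)
            if rec.rank_key > best[key].rank_key:
                best[key] = rec
        else:
            best[key] = rec
            order.append(key)
    return [best[k] for k in order]


def top_markers(records: Iterable[MarkerRecord], m: int = DEFAULT_MARKERS_PER_CLUSTER,
                tissue: str = "", species: str = "Homo sapiens") -> list[MarkerSet]:
    """Build one :class:`MarkerSet` per cluster with its ``m`` top markers.

    Genes are ordered by descending ``rank_key``; ties keep input order.
    Clusters holding fewer than ``m`` markers return all of them (a note is
    logged).  Gene symbols are case-normalized by species convention.
    Cluster order follows first appearance in ``records``.
    """
    if m < 1:
        raise ConfigurationError(f"m must be >= 1, got {m}")
    records = list(records)
    if not records:
        raise EmptyInputError("no marker records supplied")

    by_cluster: dict[str, list[MarkerRecord]] = {}
    for rec in records:
        by_cluster.setdefault(rec.cluster_id, []).append(rec)

    out = []
    for cluster_id, recs in by_cluster.items():
        ranked = sorted(recs, key=lambda r: -r.rank_key)  # stable: ties keep input order
        if len(ranked) < m:
            logger.info("cluster %s has only %d markers (requested %d)",
                        cluster_id, len(ranked), m)
        genes = []
        for r in ranked[:m]:
            g = normalize_gene_symbol(r.gene, species)
            if g not in genes:
                genes.append(g)
        out.append(MarkerSet(cluster_id=cluster_id, tissue=tissue,
                             species=species, genes=tuple(genes)))
    return out
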