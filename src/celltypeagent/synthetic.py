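"""Synthetic test worlds: planted-marker references and scripted LLMs.

Real benchmarking of a cell type annotator needs curated scRNA-seq
datasets, a reference census extract and a live LLM.  This module builds
fully offline stand-ins with known ground truth:

* a reference matrix where each cell type overexpresses its designated
  marker genes (foreground mean) against a low background, with optional
  Gaussian noise truncated at zero — the fixture models aggregated mean
  expression, not per-cell counts;
* *sibling* type pairs that share a fraction of their marker sets and can
  additionally express each other's remaining markers at an elevated
  level (``sibling_bleed``), emulating the parent/child ambiguity between
  e.g. mural cells and pericytes where several types show similarly high
  average marker expression;
* marker-set queries whose true label(s) are known, including mixture
  queries that combine two cell types' markers;
* scripted LLM backends that answer those queries with the truth planted
  at a configurable rank among vocabulary distractors, deterministically
  given a seed.

Everything is bit-reproducible: generators take explicit seeds, and the
scripted backend derives its per-prompt random stream from (seed, CRC32 of
the prompt), so identical prompts always receive identical responses.
Worlds serialize to the ordinary snapshot TSV + truth TSV formats, so the
CLI consumes synthetic and real snapshots identically.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .llm import ScriptedBackend
from .markers import MarkerSet
from .reference import ReferenceMatrix


@dataclass(frozen=True)
class WorldParams:
    """Generation parameters for a synthetic world.

    ``sibling_bleed`` interpolates a sibling's expression of its partner's
    unshared markers between background (0.0) and foreground (1.0); at 1.0
    the two profiles are indistinguishable on each other's markers, the
    fully ambiguous mural-vs-pericyte regime.
    """

    n_tissues: int = 1
    n_types: int = 20            # per tissue
    n_genes: int = 200
    markers_per_type: int = 3
    foreground_mean: float = 5.0
    background_mean: float = 0.5
    noise_scale: float = 0.0
    n_sibling_pairs: int = 0
    sibling_shared_frac: float = 2.0 / 3.0
    sibling_bleed: float = 0.0
    n_queries: int | None = None  # default: one per cell type
    contamination: int = 0        # background genes appended per query
    interleave_sibling_markers: bool = False
    species: str = "Homo sapiens"

    def validate(self) -> None:
        if not self.foreground_mean > self.background_mean >= 0:
            raise ConfigurationError(
                f"need foreground_mean > background_mean >= 0, got "
                f"{self.foreground_mean} and {self.background_mean}")
        if self.markers_per_type < 1:
            raise ConfigurationError("markers_per_type must be >= 1")
        if min(self.n_tissues, self.n_types, self.n_genes) < 1:
            raise ConfigurationError("n_tissues, n_types, n_genes must be >= 1")
        if self.n_genes < self.n_types * self.markers_per_type:
            raise ConfigurationError(
                f"n_genes={self.n_genes} cannot host {self.n_types} types x "
                f"{self.markers_per_type} markers")
        if 2 * self.n_sibling_pairs > self.n_types:
            raise ConfigurationError("too many sibling pairs for n_types")
        if not (0.0 <= self.sibling_shared_frac <= 1.0):
            raise ConfigurationError("sibling_shared_frac must be in [0, 1]")
        if not (0.0 <= self.sibling_bleed <= 1.0):
            raise ConfigurationError("sibling_bleed must be in [0, 1]")
        if self.noise_scale < 0 or self.contamination < 0:
            raise ConfigurationError("noise_scale and contamination must be >= 0")


@dataclass
class SyntheticWorld:
    """A generated reference plus queries with known truth."""

    params: WorldParams
    seed: int
    reference: ReferenceMatrix
    truth_markers: dict[str, tuple[str, ...]]
    queries: list[tuple[MarkerSet, tuple[str, ...]]]
    siblings: dict[str, str]          # label -> partner label
    tissue_of: dict[str, str]         # label -> tissue name

    def truth_table(self) -> dict[str, tuple[str, ...]]:
        return {ms.cluster_id: truth for ms, truth in self.queries}

    def save(self, outdir: str | Path) -> None:
        """Serialize to snapshot TSV (+ JSON sidecar), truth TSV, marker
        table TSV and a manifest recording params and seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.reference.to_tsv(outdir / "snapshot.tsv")
        truth_rows = [{"cluster_id": ms.cluster_id, "annotation": ";".join(truth),
                       "dataset": ms.tissue}
                      for ms, truth in self.queries]
        pd.DataFrame(truth_rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        marker_rows = [{"cluster": ms.cluster_id, "gene": g,
                        "avg_log2FC": float(len(ms.genes) - i), "tissue": ms.tissue}
                       for ms, _ in self.queries for i, g in enumerate(ms.genes)]
        pd.DataFrame(marker_rows).to_csv(outdir / "markers.tsv", sep="\t", index=False)
        manifest = {"seed": self.seed, "params": dataclasses.asdict(self.params)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    @classmethod
    def load(cls, outdir: str | Path) -> "SyntheticWorld":
        """Regenerate a world from its manifest (generation is deterministic)."""
        manifest = json.loads((Path(outdir) / "manifest.json").read_text())
        return make_world(WorldParams(**manifest["params"]), seed=manifest["seed"])


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))  # equal-width names: no substring collisions
    return [f"GENE{i:0{width}d}" for i in range(n)]


def _type_label(t: int, j: int, n_types: int) -> str:
    width = max(2, len(str(n_types - 1)))
    return f"type_{t}_{j:0{width}d}"


def make_world(params: WorldParams | None = None, seed: int = 0) -> SyntheticWorld:
    """Build a synthetic world.

    Generation order (fixed, so equal seeds give byte-identical worlds):
    gene names; per tissue — marker block assignment, sibling rewiring,
    base expression matrix, one noise draw for the whole matrix; finally
    query construction with contamination draws in query order.

    Marker blocks are disjoint: type ``j`` owns genes
    ``[j*mpt, (j+1)*mpt)``.  Sibling pairs are types (0,1), (2,3), …; the
    second member of a pair replaces the first ``round(frac*mpt)`` of its
    own block with its partner's, so the pair shares that many markers
    (shared markers ranked first in both sets).
    """
    params = params or WorldParams()
    params.validate()
    rng = np.random.default_rng(seed)
    p = params
    genes = _gene_names(p.n_genes)
    fg, bg = p.foreground_mean, p.background_mean
    bleed_expr = bg + p.sibling_bleed * (fg - bg)

    frames = []
    truth_markers: dict[str, tuple[str, ...]] = {}
    siblings: dict[str, str] = {}
    tissue_of: dict[str, str] = {}
    all_labels: list[str] = []

    n_shared = int(round(p.sibling_shared_frac * p.markers_per_type))
    for t in range(p.n_tissues):
        tissue = f"tissue_{t}"
        labels = [_type_label(t, j, p.n_types) for j in range(p.n_types)]
        blocks = {j: genes[j * p.markers_per_type:(j + 1) * p.markers_per_type]
                  for j in range(p.n_types)}
        markers = {j: list(blocks[j]) for j in range(p.n_types)}
        for i in range(p.n_sibling_pairs):
            a, b = 2 * i, 2 * i + 1
            markers[b] = blocks[a][:n_shared] + blocks[b][n_shared:]
            if p.interleave_sibling_markers:
                # rank order alternates shared and type-specific markers, so
                # a length-m prefix carries some discriminating signal even
                # when the top marker is shared
                for j, own_unique in ((a, blocks[a][n_shared:]),
                                      (b, blocks[b][n_shared:])):
                    shared = blocks[a][:n_shared]
                    inter = []
                    for x in range(max(len(shared), len(own_unique))):
                        inter += shared[x:x + 1] + own_unique[x:x + 1]
                    markers[j] = inter
            siblings[labels[a]] = labels[b]
            siblings[labels[b]] = labels[a]

        base = np.full((p.n_types, p.n_genes), bg)
        gene_idx = {g: i for i, g in enumerate(genes)}
        for j in range(p.n_types):
            for g in markers[j]:
                base[j, gene_idx[g]] = fg
        for i in range(p.n_sibling_pairs):
            a, b = 2 * i, 2 * i + 1
            for j, partner in ((a, b), (b, a)):
                for g in markers[partner]:
                    if g not in markers[j]:
                        base[j, gene_idx[g]] = bleed_expr
        if p.noise_scale > 0:
            base = np.maximum(0.0, base + rng.normal(0.0, p.noise_scale, base.shape))

        frames.append(pd.DataFrame({
            "tissue": np.repeat(tissue, p.n_types * p.n_genes),
            "cell_type": np.repeat(labels, p.n_genes),
            "gene": np.tile(genes, p.n_types),
            "mean_expr": base.ravel(),
        }))
        for j, label in enumerate(labels):
            truth_markers[label] = tuple(markers[j])
            tissue_of[label] = tissue
            all_labels.append(label)

    reference = ReferenceMatrix(
        pd.concat(frames, ignore_index=True), species=p.species,
        snapshot_meta={"source": "synthetic planted-marker world",
                       "unit": "mean log-normalized expression",
                       "version": f"seed={seed}"})

    background_pool = [g for g in genes
                       if not any(g in m for m in truth_markers.values())]
    n_queries = p.n_queries if p.n_queries is not None else len(all_labels)
    queries: list[tuple[MarkerSet, tuple[str, ...]]] = []
    for q in range(n_queries):
        label = all_labels[q % len(all_labels)]
        qgenes = list(truth_markers[label])
        if p.contamination:
            if len(background_pool) < p.contamination:
                raise ConfigurationError(
                    "not enough pure-background genes for requested contamination")
            extra = rng.choice(background_pool, size=p.contamination, replace=False)
            qgenes += list(extra)
        ms = MarkerSet(cluster_id=f"q{q:04d}", tissue=tissue_of[label],
                       species=p.species, genes=tuple(qgenes))
        queries.append((ms, (label,)))

    return SyntheticWorld(params=p, seed=seed, reference=reference,
                          truth_markers=truth_markers, queries=queries,
                          siblings=siblings, tissue_of=tissue_of)


def make_mixture_queries(world: SyntheticWorld,
                         pairs: Sequence[tuple[str, str]],
                         seed: int = 0) -> list[tuple[MarkerSet, tuple[str, ...]]]:
    """Queries combining the marker genes of two cell types.

    The marker set interleaves the two types' planted markers by rank
    (a1, b1, a2, b2, …); truth is the pair.  A degenerate pair (A, A)
    yields A's markers with singleton truth.  Construction is
    deterministic; ``seed`` is accepted for interface symmetry with the
    other generators.
    """
    queries = []
    for idx, (a, b) in enumerate(pairs):
        for label in (a, b):
            if label not in world.truth_markers:
                raise ConfigurationError(f"unknown cell type {label!r}")
        if a == b:
            genes, truth = list(world.truth_markers[a]), (a,)
        else:
            ga, gb = world.truth_markers[a], world.truth_markers[b]
            genes = []
            for i in range(max(len(ga), len(gb))):
                for g in (ga[i:i + 1] + gb[i:i + 1]):
                    if g not in genes:
                        genes.append(g)
            truth = (a, b)
        ms = MarkerSet(cluster_id=f"mix{idx:04d}", tissue=world.tissue_of[a],
                       species=world.params.species, genes=tuple(genes))
        queries.append((ms, truth))
    return queries


_POLICIES = ("always_first", "uniform_random", "wrong_first")


def make_scripted_llm(world: SyntheticWorld, k: int = 3,
                      truth_rank_policy: str = "always_first",
                      distractor_policy: str = "uniform",
                      seed: int = 0, absent_prob: float = 0.0) -> ScriptedBackend:
    """A deterministic mock LLM answering this world's prompts.

    The backend recovers the query from the marker genes embedded in the
    prompt, then emits a numbered ``k``-item list with the true label(s) at
    a policy-determined rank and vocabulary distractors elsewhere:

    * ``always_first`` — truth at rank 1;
    * ``uniform_random`` — truth uniformly at rank 1..k;
    * ``wrong_first`` — a distractor at rank 1, truth at rank 2 (the
      LLM-confidently-wrong regime the verification stage must repair);
    * ``absent_prob`` — with this probability the truth is omitted
      entirely (hallucination regime).

    ``distractor_policy``: ``uniform`` samples in-tissue vocabulary without
    replacement; ``sibling_first`` additionally forces the truth's sibling
    (when it has one) to be among the candidates — the hard, confusable
    shortlist.  Responses depend only on (seed, prompt), so equal seeds
    give byte-identical response streams.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if truth_rank_policy not in _POLICIES:
        raise ConfigurationError(
            f"unknown truth_rank_policy {truth_rank_policy!r}; one of {_POLICIES}")
    if distractor_policy not in ("uniform", "sibling_first"):
        raise ConfigurationError(f"unknown distractor_policy {distractor_policy!r}")
    if not (0.0 <= absent_prob <= 1.0):
        raise ConfigurationError("absent_prob must be in [0, 1]")

    world_genes = sorted({g for ms in world.truth_markers.values() for g in ms}
                         | set(world.reference.entries["gene"].unique()))
    by_tissue: dict[str, list[str]] = {}
    for label, tissue in world.tissue_of.items():
        by_tissue.setdefault(tissue, []).append(label)
    vocabulary = sorted(world.tissue_of)

    def respond(prompt: str) -> str:
        found = {g for g in world_genes if g in prompt}
        rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(prompt.encode())])
        # identify the query by marker overlap; with few markers several
        # types may tie, and a tied-but-not-picked type stays on the
        # shortlist as a plausible confusion for verification to resolve
        fracs = {label: len(set(mks) & found) / len(mks)
                 for label, mks in world.truth_markers.items()
                 if set(mks) & found}
        confusions: list[str] = []
        if fracs:
            fmax = max(fracs.values())
            tied = sorted(l for l, f in fracs.items() if f == fmax)
            if fmax >= 1.0:
                truths = tied          # full matches: mixture components
            else:
                truths = [tied[int(rng.integers(0, len(tied)))]]
                confusions = [l for l in tied if l not in truths]
        else:
            truths = []

        names: list[str] = []
        include_truth = truths and not (absent_prob > 0 and rng.random() < absent_prob)
        if include_truth:
            if len(truths) > 1:
                names = truths[:k]
            elif truth_rank_policy == "always_first":
                names = truths[:]
            elif truth_rank_policy == "wrong_first":
                names = [None, truths[0]][: k] if k > 1 else [None]  # type: ignore
            else:  # uniform_random
                pos = int(rng.integers(0, k))
                names = [None] * pos + [truths[0]]  # type: ignore

        tissue = world.tissue_of[truths[0]] if truths else None
        forced: list[str] = list(confusions)
        if distractor_policy == "sibling_first":
            forced += [world.siblings[t] for t in truths
                       if t in world.siblings
                       and world.siblings[t] not in truths + forced]
        pool = [l for l in (by_tissue.get(tissue, vocabulary) if tissue else vocabulary)
                if l not in truths and l not in forced]
        order = forced + ([str(x) for x in rng.permutation(pool)] if pool else [])

        out: list[str] = []
        di = 0
        for slot in names:
            if slot is None:
                out.append(order[di] if di < len(order) else vocabulary[di % len(vocabulary)])
                di += 1
            else:
                out.append(slot)
        while len(out) < k and di < len(order):
            out.append(order[di])
            di += 1
        out = out[:k]
        return "\n".join(f"{i + 1}. {name}" for i, name in enumerate(out))

    return ScriptedBackend(respond, identity=f"scripted[{truth_rank_policy}/seed={seed}]")
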