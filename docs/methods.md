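# Methods

## The annotation model

`celltypeagent` annotates scRNA-seq clusters in two stages. Stage 1 asks
a language model for a ranked shortlist of `k` candidate cell types given
the cluster's top `m` marker genes, tissue and species. Stage 2 scores
each candidate against a tissue-stratified mean-expression reference and
keeps the candidate with the highest mean marker expression.

For a cluster with marker genes `G` in tissue `t`, the score of a
candidate label `c` is the arithmetic mean of the reference values
`x̄(t, c, g)` over the overlap `G_c = {g ∈ G : (t, c, g) in reference}`.
Markers absent from the reference for `c` are ignored, not counted as
zeros: reference coverage varies by label, and penalizing missing entries
would conflate "not measured" with "not expressed". Marker genes are not
weighted by their differential-expression rank — the statistic is a plain
average — because any weighting scheme would add a free parameter without
an obvious calibration.

Assumptions the model makes:

* the reference's mean expression per (tissue, cell type, gene) is
  comparable across cell types within a tissue (same normalization);
  values are consumed as-is, with the unit declared in snapshot metadata
  (typically mean log-normalized counts), never re-transformed;
* the LLM shortlist contains the true type most of the time — the
  verifier can only choose among candidates, so stage 2 repairs wrong
  *rankings*, not wrong *shortlists* (the fallback below handles the
  latter);
* cluster markers are informative for exactly one type (single mode) or
  a small union of types (mixture mode).

### Decision rules and degenerate inputs

* Score ties resolve by better LLM rank, then lexicographically on the
  label. The database overrides the LLM prior only with strictly better
  evidence; equal evidence defers to the prior. Lexicographic order is a
  deterministic last resort that in practice never fires (candidate
  ranks are unique).
* If no candidate is scorable — every name unmatched in the vocabulary,
  or no marker coverage — the agent still annotates: it keeps the LLM's
  top candidate and labels the decision `fallback_llm_rank`, preserving
  an audit trail rather than failing silently.
* If the requested tissue is absent from the reference, scoring falls
  back to the mean over all tissues per (cell type, gene) and sets a
  `tissue_fallback` flag on the result.
* Mixture mode keeps every candidate with score ≥ `tau` × best score,
  ordered by descending score. The relative-to-max rule is scale-free
  across expression units. With `tau = 1` and a unique maximum it
  reduces to single mode.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 3 | candidates requested per cluster; a small shortlist that still gives verification room to overturn the top rank |
| `m` | 10 | markers per cluster; common FindAllMarkers reporting depth, more markers generally help (see the sweep below) |
| `min_overlap` | 1 | marker genes required in the reference for a score to be defined; 1 keeps sparse coverage usable, raise to guard against single-gene flukes |
| `tau` | 0.8 | mixture-mode retention threshold, fraction of the best score |
| `fuzzy_threshold` | 0.85 | minimum normalized edit similarity for a fuzzy name match; accepts plural/hyphenation variants, rejects cross-type confusions |
| `max_retries` | 2 | extra LLM attempts after an unparseable response, with a format reminder appended |
| `temperature` | 0.0 | deterministic decoding for remote backends |

All expression values are in the snapshot's declared unit; scores are in
the same unit.

## Name normalization and grading

LLM names are free text, so matching to the reference vocabulary runs a
three-step pipeline: canonical-form exact match (lower-case, collapse
whitespace and hyphens/underscores, strip a trailing "cell"/"cells"
token, singularize the final token), then synonym-table lookup on the
canonical form, then fuzzy matching by normalized edit similarity
(stdlib `difflib`), accepted only when the best score reaches the
threshold and is unique. No-match is a value, not an error.

Agreement with manual truth is graded 1.0 (exact or synonym match), 0.5
(partial: a declared broader/narrower pair, or a head-noun token-subset
such as "T cell" vs "CD8-positive T cell"), 0.0 otherwise — the
three-level convention standard in LLM-annotation benchmarking, exposed
as a pluggable policy. Mixture predictions are graded per truth
component (best grade per component, averaged over the truth set), so a
singleton reduces to the plain grade. Dataset-level scores weight
datasets equally (mean of dataset means); a pooled-cluster mode is
available by flag. Partial relations are supplied as data (TSV), not
inferred from an ontology at run time, keeping grading deterministic and
offline.

## The synthetic worlds

The generator (`make_world`) emulates the *aggregated* reference, not raw
data: each cell type's designated markers sit at a foreground mean
(default 5.0) and everything else at a background mean (default 0.5),
with optional additive Gaussian noise truncated at zero (the simplest
model that exercises the ranking behavior of a mean-based scorer).
Defaults: 1 tissue × 20 types × 200 genes, 3 markers per type.

*Sibling pairs* model the mural/pericyte-style ambiguity: two types share
`sibling_shared_frac` of their markers (default 2/3), and
`sibling_bleed` sets how strongly each expresses the partner's remaining
markers, interpolating between background (0, fully separable — a
sibling scores (5+5+0.5)/3 ≈ 3.5 on the truth's markers under the
defaults) and foreground (1, indistinguishable mean expression — the
regime where a database-only argmax degenerates to a coin flip while an
LLM shortlist that excludes the sibling stays clean). The
`interleave_sibling_markers` option alternates shared and type-specific
markers in rank order, so a length-`m` marker prefix carries partial
discriminating signal at intermediate `m` — used by the marker-count
sweep, where all-shared prefixes would make `m = 1` and `m = 3`
information-equivalent.

Scripted LLM backends answer a world's prompts deterministically
(per-prompt stream seeded by (seed, CRC32(prompt))). They recover the
query from the marker genes in the prompt by maximal marker-set overlap;
overlap ties — which arise exactly when the prompt's markers cannot
distinguish sibling types — are resolved randomly, with the tied losers
kept on the shortlist as plausible confusions, mimicking an LLM that
lists all similar types and leaving the decision to verification.
Truth-rank policies (`always_first`, `uniform_random`, `wrong_first`,
omission with probability `absent_prob`) set candidate quality;
distractors are drawn from the in-tissue vocabulary, optionally forcing
the sibling onto the shortlist (`sibling_first`).

What the worlds do **not** model: per-cell count matrices, clustering
noise, batch effects, marker lists contaminated by genes of *other*
specific types, reference coverage gaps, or free-text naming noise in
the LLM output (scripted backends emit vocabulary labels verbatim).
Passing tests therefore demonstrate the correctness of the decision
machinery and the claimed failure-mode separations under controlled
evidence — not performance on real tissues, which depends on LLM quality
and census coverage.

## Study conditions used by the acceptance script

Problem sizes are chosen to estimate each property tightly at desk
scale: 1000 random views for scorer-oracle agreement; 200 queries on the
separable world; 50 seeded ambiguous worlds (noise 0.2, all types
paired, bleed 1.0) for the agent-vs-ablation orderings with a
wrong-first LLM; 30 seeded noisy worlds (10 markers/type, shared
fraction 0.7, bleed 0.5, noise 1.0, interleaved ranks, sibling forced
onto the shortlist) for the m = 1/3/10 sweep. All randomness derives
from the `--seed` argument.

## Known limitations

* The verifier can only pick among LLM candidates; a shortlist that
  omits the truth caps accuracy (the `absent_prob` policy measures
  this).
* Mean-of-means scoring ignores expression variance and cell counts
  behind each reference mean; a label backed by 10 cells weighs as much
  as one backed by 10⁶.
* The live-census client is specified as a contract
  (`ExpressionSource`) only; the shipped implementation is the local
  snapshot, so results are pinned to a snapshot version by design.
* Prompt augmentation with literature excerpts or gene summaries is
  deliberately out of scope: long grounding texts tend to dominate the
  model's own knowledge and degrade ranking quality, besides inflating
  cost.
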