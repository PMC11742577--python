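# Methods

This note documents the models, rules and numerical conventions the
package implements, the design decisions taken where the problem left the
design open, and what the synthetic fixtures do and do not demonstrate.

## Reference database and header codec

The annotation payload of each reference protein — product name, GO terms
split by domain (MF/BP/CC), Pfam and InterPro ids, protein-existence level
(1–5), the knowledgebase's own OrthoDB group (`ukb`) and the Zen-mapped
group — is encoded in its FASTA description as space-separated `key=value`
tokens. Free-text values are percent-escaped (space → `%20`, `=` → `%3D`,
`%` → `%25`, plus tab/newline → `%09`/`%0A` so a header always stays one
line); list values are `;`-joined (list elements are identifiers, which
never contain `;`). The codec is a bijection on the encoded fields:
`decode(encode(r))` is the identity, property-tested on adversarial and
unicode names. This makes the reference FASTA greppable and lets the
aligner's tabular output carry the full payload without a second lookup.

The flat-file reader supports the minimal line-type subset that carries
those layers (`ID`, `AC`, `DE`, `OX`, `DR` for GO/Pfam/InterPro/OrthoDB,
`PE`, `SQ` + sequence lines). It is deliberately tolerant: a record missing
an accession or sequence is skipped with a warning rather than aborting the
stream, a malformed GO id drops only that term, and unknown line types
(`FT`, `CC`, `OS`, …) are ignored — parsing results are invariant under
their injection. The primary accession is the first token of the first
`AC` line; secondary accessions are discarded and take part in no join.
Source classification (`sprot` vs `trembl`) follows the `Reviewed` /
`Unreviewed` flag on the `ID` line.

## Zen mapping

Thresholds (defaults): identity ≥ 50 %, E-value < 10⁻⁶, coverage ≥ 75 % of
both query and target. The wording of the underlying protocol makes the
E-value bound strict and the identity/coverage bounds inclusive, and the
tests pin exactly that: identity 50.0 passes, E-value exactly 10⁻⁶ fails,
coverage 0.7499 fails, 0.75 passes.

Coverage is span-based by default, `(qend − qstart + 1)/qlen` (and the
target analogue), which is robust to internal gaps and matches
target/query coverage as alignment tools usually define it; whether the
original pipeline used span-based or aligned-column coverage is not
knowable from its description, so an `aligned` mode
(`aln_length / length`) is provided behind the same threshold object.

Best-hit selection is fully deterministic: maximal bit score, ties broken
by minimal E-value, then lexicographically smallest target id. The original
tool's tie behaviour is unknown (likely file order); determinism was chosen
so that reruns and permuted inputs give identical mappings
(permutation-invariance is property-tested).

Parental-OG expansion follows child → parent OG pairs (including the
starting OG itself) until an OG whose `at<taxid>` level matches the
requested taxonomic level; cycles raise an error. Concordance between two
accession → OG maps is restricted to accessions present in both maps whose
OGs both resolve at the requested level, mirroring how a
subset-with-parental-correspondence comparison is constructed; the
percentage is `100 · n_exact / n_compared` and an empty comparison set is
an error rather than 0 %.

The coverage report counts, per source (`sprot`, `trembl`, `total`),
accessions with a knowledgebase OG before and after *additively* applying
a Zen map (a record counts "after" if it has either), so coverage after
Zen can only grow.

## Annotation merging

The main table has 16 base columns
(`Query, Accession, Product_Name, OrthoDB, OrthoDB_Desc, UKB_OrthoDB,
GO_BP, GO_MF, GO_CC, Evidence_existence, InterPro, Pfam, Identity, Length,
Evalue, Score`); with orthology-mapper results, 12 more
(`Zen_OrthoDB, Zen_OrthoDB_Desc, ODB_OG, ODB_Description, ODB_GO_MF,
ODB_GO_BP, ODB_EC, ODB_COG_category, ODB_KEGG_ko, ODB_Interpro,
ODB_evalue, ODB_score`) are appended after the base block — the upstream
description lists which columns are added but not their position, so the
appended order was fixed here and is asserted verbatim by the tests.

Merge rules (exhaustively enumerated over all 16 presence/absence
combinations in the tests):

- `OrthoDB` = mapper OG when present, else Zen OG ("prioritise", not
  "exclusive" — genes assigned an OG only by Zen remain annotated);
  without mapper results, `OrthoDB` = Zen OG.
- `GO_MF`/`GO_BP` are filled from the mapper's inferences only when the
  UniProt-derived list is empty — fill-only-when-empty, never a union. The
  rule is worded for absent values, so a partially present list is left
  untouched. `GO_CC` is never propagated (only BP and MF are named by the
  propagation rule).
- Multi-valued cells are `;`-joined without spaces; an empty cell is the
  empty string, not `NA`, so cells round-trip unambiguously.

The orthology-mapper file format is not standardised upstream; a permissive
11-column TSV dialect (`query, og, description, go_mf, go_bp, ec, cog,
kegg_ko, interpro, evalue, score`) is read here, keeping the best row per
query (score ↓, then E-value ↑). DNA input / translated search is the
external aligner's job; the merge consumes tabular hits only.

The output bundle mirrors the established layout: main TSV
(`<Project>_Hayai_annotation_v3.2.tsv`), `unaligned.fasta` (queries absent
from the best-hit map, input order and sequences preserved), four
term-count TSVs (GO-MF/BP/CC, InterPro; a row counts once per distinct
term in its cell), four top-50 horizontal bar charts (PDF; cosmetic and
excluded from correctness tests), a log, and optionally a
`<Project>_HayaiAnnotation_v3.2.zip`. All text outputs are byte-identical
across reruns.

## Co-occurrence network

Per species, a gene with effective OG *o* and *k* distinct GO ids of the
chosen domain contributes 1 to each of the *k* (o, go) pairs; duplicate
ids within a cell count once, because the quantity is "genes per OG–GO
pair". Gene rows first pass the `Identity ≥ min_identity` filter. The
Network Dataset is the union of pairs over both species, absolute counts,
zero where a species lacks the pair, sorted by (og, go).

The effective OG follows the selected priority (`orthologer` or `zen`)
with fallback to the other source; only the `OrthoDB`/`OrthoDB_Desc`
interpretation changes with priority. Tables from a Zen-only run (16
columns) are handled by falling back to their `OrthoDB` column.

The log-scale threshold reads "(ln + 1)" as `ln(count + 1)` — the only
reading defined at count 0 — and by default retains pairs with
`|ln(c₁+1) − ln(c₂+1)| ≥ T`, highlighting between-species differences;
`T = 0` retains everything, and retention is monotone (nested) in `T`. The
threshold direction is not specified upstream, so a `keep=similar` mode
retains the complement instead; `diff` is the default.

Graph construction is seeded by one GO term: candidate OGs are those
paired with it, candidate GO terms all terms paired with those OGs. Nodes
are keyed by `(kind, truncated label)` — GO descriptions truncated to 30
characters, OG descriptions to 20 with an `odb:` prefix — so OGs whose
truncated descriptions collide collapse into one node and parallel OG→GO
edges appear, which is treated as a feature for comparing similarly
described groups (an id-keyed mode is provided for analyses where that is
unwanted). The node count is capped at 100; the cap keeps the seed GO
first, then OGs by total count (c₁+c₂) descending, then GO terms by
connected total count descending, ties by id — the upstream description
states only the cap, so this deterministic trimming order is the package's
choice. Unresolved GO descriptions display the id itself; descriptions come
from a small user-supplied 2-column id→name table.

## Synthetic fixtures

The generators emulate the *structure* of real inputs, not their biology:
flat-file records with random annotation layers, alignment hits
constructed to straddle every threshold boundary (each hit's keep/reject
status is fixed by construction, not by running the filter — a rejected
hit breaks exactly one dimension, at the boundary with configurable
probability), and two-species annotation tables that realize planted
(og, go, c₁, c₂) counts exactly: per OG, gene *j* carries every GO whose
planted count is ≥ *j*, which realizes any non-negative integer table while
producing genes bearing multiple GO terms. Decoy genes (OG without GO, GO
without OG) are planted to verify they contribute nothing. The concordance
fixture plants agreement on a 100-accession population (so rates 0, 0.25,
0.6 and 1.0 are exactly realizable), with a third of agreeing entries
agreeing only after parental-OG expansion.

Default problem sizes (30 reference records, 20 targets, ~60 genes per
species, 12 OGs, 20 GO terms, 100 concordance accessions) are small
structured instances that exercise every rule and boundary; the oracle
tests sweep up to 200 genes per species. Passing tests therefore
demonstrate the correctness of the filtering, propagation, merging and
counting rules — they do not demonstrate annotation accuracy on real
proteomes, which depends on the reference databases and aligner
sensitivity, nor alignment quality itself (alignments are consumed, not
computed). One fixed seed drives a private random stream; identical specs
yield byte-identical files.

## Numerical and degenerate-input conventions

- Empty hit list → empty filter result; empty best-hit map → empty Zen map.
- Zero records (coverage) or an empty comparison set (concordance) raise
  errors instead of emitting undefined percentages.
- Negative network thresholds, unknown GO domains/layers and cyclic OG
  pair graphs raise `ValueError`.
- Floats in emitted tables use `%g` formatting; counts are exact integers
  throughout (no transformation is stored in the Network Dataset).
- All writers emit `\n` line endings and sorted or input-order rows so
  reruns are byte-identical.

## Known limitations

- The flat-file reader is a minimal-dialect reader, not a full
  flat-file-format implementation (no `FT`/`CC` semantics, no isoforms).
- Alignment and orthology inference are out of scope: the package consumes
  tabular outputs of external tools and never recomputes them.
- GO propagation ignores the ontology graph (no ancestor closure); terms
  are transferred as flat id lists.
- The interactive browser front-end of the original tool is not
  reproduced; graphs are exported as tables/JSON/GraphML instead.
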