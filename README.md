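# ogn — ortholog-group annotation transfer and OG–GO co-occurrence networks

`ogn` is a library and command-line tool for functional annotation of plant
protein sets and for comparative annotation analysis between two species.
It is aimed at genome-annotation teams and database curators who want to
(1) transfer functional annotation layers — product names, Gene Ontology
(GO) terms, Pfam and InterPro signatures, protein-existence (PE) levels and
OrthoDB orthologous-group (OG) ids — from a reference knowledgebase to new
protein sequences by best-hit alignment, and (2) compare how OG/GO
annotations are distributed across two species through a bipartite
co-occurrence network, e.g. to spot candidate gene-loss events or to
propagate functions to uncharacterized genes.

## The method

**Zen mapping (best-hit OG transfer).** Given tabular protein-alignment
hits (BLAST/DIAMOND `outfmt 6` extended with `qlen`/`slen`), a hit is
accepted when

- sequence identity ≥ 50 %,
- E-value < 10⁻⁶, and
- alignment coverage ≥ 75 % of **both** the query and the target,
  computed span-based: `qcov = (qend − qstart + 1)/qlen` (an
  aligned-column mode is available).

Among accepted hits, each query's best hit (highest bit score, ties broken
by lower E-value, then lexicographic target id) donates its OrthoDB OG id
(`<group>at<taxid>`, e.g. `1531455at33090` = Viridiplantae level). The
resulting accession → OG map can be compared against an independent OG
annotation at a common taxonomic level by *parental-OG expansion*
(following child → parent OG links until the requested level, e.g.
Viridiplantae taxid 33090 or Eukaryota taxid 2759), reporting the
exact-match concordance `100 · n_exact / n_compared`.

**Annotation merging.** Each aligned query receives the annotation payload
encoded in its best hit's reference FASTA header, producing the main
annotation table (16 columns `Query … Score`). When orthology-mapper
(OrthoLoger-style) results are supplied, 12 further columns are added; the
`OrthoDB` column then prioritises the mapper's OG with fallback to the Zen
OG, and empty `GO_MF`/`GO_BP` cells are filled (never unioned) from the
mapper's GO inferences; `GO_CC` is never propagated.

**Co-occurrence network.** For two annotated species, every gene with an
effective OG *o* and *k* distinct GO ids (MF or BP domain) contributes one
count to each of the *k* (o, go) pairs of its species. Pairs can be
filtered by the log-scale difference `|ln(c₁+1) − ln(c₂+1)| ≥ T`. A network
seeded at one GO term connects its OGs (orange, `odb:`-prefixed,
descriptions truncated to 20 characters) to all their GO terms (blue,
30 characters), edges directed OG → GO and labelled `f1:<c₁>, f2:<c₂>`,
capped at 100 nodes.

## Worked example

Generate a seeded synthetic fixture (flat file, OG-labelled targets,
alignment hits with known truth), run Zen mapping, and inspect it:

```bash
ogn simulate --preset zen --seed 9 --out demo
ogn zen-map --hits demo/hits.tsv --target-og demo/target_og.tsv --out demo/zen.tsv
```

```
INFO ogn: hits=55 kept=25 queries_mapped=16 -> demo/zen.tsv
```

55 synthetic hits straddle the acceptance thresholds; 25 pass the
identity/E-value/reciprocal-coverage filter and 16 queries receive an OG
from their best surviving hit (`demo/zen.tsv`, one
`accession  og  description` line each, matching `demo/truth_zen.tsv`
exactly). The two-species network module on the packaged annotation-gap
preset:

```bash
ogn simulate --preset case-3-5-3 --seed 9 --out demo-net
ogn network --f1 demo-net/f1_Hayai_annotation_v3.2.tsv \
            --f2 demo-net/f2_Hayai_annotation_v3.2.tsv \
            --domain MF --priority orthologer \
            --seed-go GO:0000030 --go-names demo-net/go_names.tsv --out demo-net/out
```

```
INFO ogn: network dataset: 5 OG-GO pairs
INFO ogn: graph: 4 nodes, 3 edges (seed GO:0000030)
```

The Network Dataset (`demo-net/out/network_dataset.tsv`) contains the row
`42661at33090  GPI mannosyltransferase 2  GO:0000030  mannosyltransferase
activity  1  0`: the OG carries mannosyltransferase activity in species 1
but not in species 2 (`counts_f2 = 0`), the pattern used to flag candidate
annotation gaps or gene loss. The seeded graph links `odb:GPI
mannosyltransfer` to the three molecular-function terms of that OG.

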