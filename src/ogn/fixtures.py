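"""Seeded synthetic fixtures for every input format the pipeline consumes.

The generators are structural, not biological: they emit parseable UniProt-
style flat files, OG-labelled target tables, alignment hits straddling every
acceptance-threshold boundary, and two-species annotation tables realizing
exact planted co-occurrence counts. Each generator also returns the ground
truth its construction implies (which hits must survive filtering, which OG
each query must receive, the exact co-occurrence table), so pipeline tests
compare recovered results against planted bookkeeping rather than against
the code under test.

One integer seed drives a private ``random.Random`` stream; identical specs
produce byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .annotate import WITH_ORTHOLOGER_COLUMNS
from .network import CoocRecord
from .zen import OgPair, ZenMapping

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_WORDS = (
    "kinase", "esterase", "lipase", "transferase", "synthase", "reductase",
    "hydrolase", "binding", "domain", "putative", "chloroplastic", "GDSL",
    "mannosyltransferase", "tubulin", "complex", "component", "uncharacterized",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one deterministic fixture build."""

    seed: int = 0
    n_records: int = 30
    n_targets: int = 20
    n_genes_per_species: int = 60
    og_pool: int = 12
    go_pool: int = 20
    planted_cooc: tuple[tuple[str, str, int, int], ...] | None = None
    planted_concordance_rate: float = 1.0
    n_concordance: int = 100  # chosen so the planted rates are exactly realizable
    boundary_hit_fraction: float = 0.5


# ---------------------------------------------------------------------------
# Reference + hits (flat file, target OG table, alignment rows)
# ---------------------------------------------------------------------------

@dataclass
class ReferenceFixture:
    """Flat-file text, target-OG table, alignment hits, and their truth."""

    dat_text: str
    target_og_tsv: str
    hits_tsv: str
    #: one flag per hit row: must it survive threshold filtering?
    keep_flags: list[bool]
    #: accession -> (og, desc) that best-hit propagation must produce
    expected_zen: ZenMapping

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "dat": out / "reference.dat",
            "target_og": out / "target_og.tsv",
            "hits": out / "hits.tsv",
            "truth_keep": out / "truth_keep.tsv",
            "truth_zen": out / "truth_zen.tsv",
        }
        paths["dat"].write_text(self.dat_text, encoding="utf-8")
        paths["target_og"].write_text(self.target_og_tsv, encoding="utf-8")
        paths["hits"].write_text(self.hits_tsv, encoding="utf-8")
        paths["truth_keep"].write_text(
            "".join(f"{i}\t{int(k)}\n" for i, k in enumerate(self.keep_flags)),
            encoding="utf-8",
        )
        paths["truth_zen"].write_text(
            "".join(
                f"{acc}\t{og}\t{desc}\n"
                for acc, (og, desc) in sorted(self.expected_zen.items())
            ),
            encoding="utf-8",
        )
        return paths


def _random_go(rng: random.Random, spec: FixtureSpec) -> tuple[str, str]:
    idx = rng.randrange(1, spec.go_pool + 1)
    go_id = f"GO:{idx:07d}"
    domain = ("F", "P", "C")[idx % 3]
    return go_id, domain


def _record_dat(rng: random.Random, spec: FixtureSpec, i: int) -> tuple[str, str, bool]:
    """One flat-file record; returns (text, accession, has_ukb_og)."""
    acc = f"Q{i:05d}"
    reviewed = rng.random() < 0.3
    name = " ".join(rng.sample(_WORDS, 3)).capitalize()
    seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randrange(40, 81)))
    lines = [
        f"ID   {acc}_ARATH   {'Reviewed' if reviewed else 'Unreviewed'};   {len(seq)} AA.",
        f"AC   {acc};",
        f"DE   RecName: Full={name};",
        "OS   Arabidopsis thaliana (Mouse-ear cress).",
        "OX   NCBI_TaxID=3702;",
    ]
    for _ in range(rng.randrange(0, 4)):
        go_id, aspect = _random_go(rng, spec)
        lines.append(f"DR   GO; {go_id}; {aspect}:synthetic term; IEA:Synthetic.")
    for _ in range(rng.randrange(0, 3)):
        lines.append(f"DR   Pfam; PF{rng.randrange(1, 99999):05d}; Synth; 1.")
    for _ in range(rng.randrange(0, 3)):
        lines.append(f"DR   InterPro; IPR{rng.randrange(1, 999999):06d}; Synth.")
    has_og = rng.random() < 0.4
    if has_og:
        lines.append(f"DR   OrthoDB; {rng.randrange(1, 9999)}at2759; -.")
    lines.append(f"PE   {rng.randrange(1, 6)}: Evidence at protein level;")
    lines.append(f"SQ   SEQUENCE   {len(seq)} AA;  0 MW;  0000000000000000 CRC64;")
    for j in range(0, len(seq), 60):
        lines.append("     " + seq[j : j + 60])
    lines.append("//")
    return "\n".join(lines) + "\n", acc, has_og


def _boundary_hit(
    rng: random.Random,
    query: str,
    target: str,
    keep: bool,
    bitscore: float,
    boundary_fraction: float = 0.5,
) -> tuple[list[str], bool]:
    """Construct a hit whose filter outcome is fixed by construction.

    A keeper sits at or inside every threshold (identity >= 50, E-value
    < 1e-6, both coverages >= 0.75); a rejected hit starts from a keeper
    and breaks exactly one dimension. With probability ``boundary_fraction``
    the varied values sit exactly on a boundary (identity 50.0 or 49.99,
    E-value exactly 1e-6, coverage 0.75 or 0.7475).
    """
    qlen = slen = 400
    at_boundary = rng.random() < boundary_fraction
    pident = 50.0 if at_boundary else rng.choice([62.5, 88.2, 99.9])
    evalue = 9.9e-7 if at_boundary else rng.choice([1e-12, 1e-40])
    qcov = 0.75 if at_boundary else rng.choice([0.9, 1.0])
    tcov = 0.75 if at_boundary else rng.choice([0.85, 1.0])
    if not keep:
        dim = rng.randrange(4)
        if dim == 0:
            pident = 49.99 if at_boundary else 12.0
        elif dim == 1:
            evalue = 1e-6 if at_boundary else 1e-3
        elif dim == 2:
            qcov = 0.7475 if at_boundary else 0.5
        else:
            tcov = 0.7475 if at_boundary else 0.25
    qstart, sstart = 1, 1
    qend = round(qcov * qlen)
    send = round(tcov * slen)
    aln = max(qend - qstart + 1, send - sstart + 1)
    row = [
        query, target, f"{pident:.2f}", str(aln), "0", "0",
        str(qstart), str(qend), str(sstart), str(send),
        f"{evalue:.3g}", f"{bitscore:.1f}", str(qlen), str(slen),
    ]
    return row, keep


def simulate_reference_and_hits(spec: FixtureSpec) -> ReferenceFixture:
    """Flat-file records, an OG-labelled target table, and boundary hits.

    Every query with at least one surviving hit is guaranteed a unique
    highest-bitscore survivor, so the expected Zen mapping is fixed by
    construction.
    """
    rng = random.Random(spec.seed)
    dat_parts, accessions = [], []
    for i in range(spec.n_records):
        text, acc, _ = _record_dat(rng, spec, i)
        dat_parts.append(text)
        accessions.append(acc)

    targets = {}
    for i in range(spec.n_targets):
        level = rng.choice([33090, 33090, 33090, 38820, 4479])
        og = f"{1000 + i}at{level}"
        desc = " ".join(rng.sample(_WORDS, 2))
        targets[f"T{i:04d}"] = (og, desc)
    target_og_tsv = "".join(
        f"{t}\t{og}\t{desc}\n" for t, (og, desc) in sorted(targets.items())
    )

    hit_rows: list[list[str]] = []
    keep_flags: list[bool] = []
    expected_zen: ZenMapping = {}
    target_ids = sorted(targets)
    bitscore = 1000.0
    for acc in accessions:
        n_hits = rng.randrange(0, 5)
        chosen = [rng.choice(target_ids) for _ in range(n_hits)]
        keeps = [rng.random() < 0.5 for _ in range(n_hits)]
        # descending unique bitscores within a query: the first keeper wins
        best_assigned = False
        for tgt, keep in zip(chosen, keeps):
            bitscore -= rng.uniform(0.5, 3.0)
            row, kept = _boundary_hit(
                rng, acc, tgt, keep, bitscore, spec.boundary_hit_fraction
            )
            hit_rows.append(row)
            keep_flags.append(kept)
            if kept and not best_assigned:
                expected_zen[acc] = targets[tgt]
                best_assigned = True
    hits_tsv = "".join("\t".join(r) + "\n" for r in hit_rows)
    return ReferenceFixture(
        dat_text="".join(dat_parts),
        target_og_tsv=target_og_tsv,
        hits_tsv=hits_tsv,
        keep_flags=keep_flags,
        expected_zen=expected_zen,
    )


# ---------------------------------------------------------------------------
# Concordance fixture (two OG maps with a planted exact-match rate)
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceFixture:
    zen_a: ZenMapping
    map_b: dict[str, str]
    pairs: list[OgPair]
    level_taxid: int
    n_compared: int
    n_exact: int


def simulate_concordance(spec: FixtureSpec) -> ConcordanceFixture:
    """Two accession->OG maps agreeing at exactly the planted rate.

    All entries resolve at Viridiplantae level (33090); a third of the
    agreeing entries agree only after child->parent expansion, exercising
    the parental-OG path.
    """
    rng = random.Random(spec.seed + 101)
    n = spec.n_concordance
    n_exact = round(spec.planted_concordance_rate * n)
    zen_a: ZenMapping = {}
    map_b: dict[str, str] = {}
    pairs: list[OgPair] = []
    for i in range(n):
        acc = f"C{i:05d}"
        parent = f"{5000 + i}at33090"
        if i < n_exact:
            if i % 3 == 0:
                child = f"{7000 + i}at4479"
                pairs.append(OgPair(child, parent))
                zen_a[acc] = (child, "planted agree via parent")
                map_b[acc] = parent
            else:
                zen_a[acc] = (parent, "planted agree")
                map_b[acc] = parent
        else:
            other = f"{6000 + i}at33090"
            zen_a[acc] = (parent, "planted disagree")
            map_b[acc] = other
    rng.shuffle(pairs)
    return ConcordanceFixture(
        zen_a=zen_a,
        map_b=map_b,
        pairs=pairs,
        level_taxid=33090,
        n_compared=n,
        n_exact=n_exact,
    )


# ---------------------------------------------------------------------------
# Two-species annotation tables realizing planted co-occurrence counts
# ---------------------------------------------------------------------------

#: descriptions used for planted OGs; two collide after 20-char truncation
_OG_DESCS = (
    "GDSL esterase/lipase At1g71691",
    "Gamma-tubulin complex component",
    "CRAL-TRIO lipid binding domain",
    "Shared truncated description alpha",
    "Shared truncated description beta",
    "uncharacterized protein",
    "SAM-dependent methyltransferase",
)


@dataclass
class AnnotationPairFixture:
    f1_tsv: str
    f2_tsv: str
    truth_cooc: list[CoocRecord]
    go_names: dict[str, str]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "f1": out / "f1_Hayai_annotation_v3.2.tsv",
            "f2": out / "f2_Hayai_annotation_v3.2.tsv",
            "truth_cooc": out / "truth_cooc.tsv",
            "go_names": out / "go_names.tsv",
        }
        paths["f1"].write_text(self.f1_tsv, encoding="utf-8")
        paths["f2"].write_text(self.f2_tsv, encoding="utf-8")
        paths["truth_cooc"].write_text(
            "og_id\tog_desc\tgo_id\tgo_desc\tcounts_f1\tcounts_f2\n"
            + "".join(
                f"{r.og_id}\t{r.og_desc}\t{r.go_id}\t{r.go_desc}\t{r.count_f1}\t{r.count_f2}\n"
                for r in self.truth_cooc
            ),
            encoding="utf-8",
        )
        paths["go_names"].write_text(
            "".join(f"{g}\t{n}\n" for g, n in sorted(self.go_names.items())),
            encoding="utf-8",
        )
        return paths


def random_planted_cooc(
    rng: random.Random, spec: FixtureSpec
) -> tuple[tuple[str, str, int, int], ...]:
    """A random planted (og, go, count_f1, count_f2) table from the pools."""
    ogs = [f"{8000 + i}at33090" for i in range(spec.og_pool)]
    gos = [f"GO:{i:07d}" for i in range(1, spec.go_pool + 1)]
    planted: list[tuple[str, str, int, int]] = []
    seen: set[tuple[str, str]] = set()
    n_pairs = rng.randrange(spec.og_pool, spec.og_pool * 3)
    for _ in range(n_pairs):
        og, go = rng.choice(ogs), rng.choice(gos)
        if (og, go) in seen:
            continue
        seen.add((og, go))
        c1 = rng.randrange(0, 5)
        c2 = rng.randrange(0, 5)
        if c1 + c2 == 0:
            c1 = 1
        planted.append((og, go, c1, c2))
    return tuple(sorted(planted))


def _validate_planted(
    planted: Sequence[tuple[str, str, int, int]]
) -> None:
    seen = set()
    for og, go, c1, c2 in planted:
        if (og, go) in seen:
            raise ValueError(f"unrealizable planted counts: duplicate pair ({og}, {go})")
        seen.add((og, go))
        if not (isinstance(c1, int) and isinstance(c2, int)) or c1 < 0 or c2 < 0:
            raise ValueError(f"unrealizable planted counts for ({og}, {go}): {c1}, {c2}")
        if c1 + c2 == 0:
            raise ValueError(f"unrealizable planted counts for ({og}, {go}): both zero")


def _species_rows(
    rng: random.Random,
    planted: Sequence[tuple[str, str, int, int]],
    og_descs: dict[str, str],
    species_idx: int,
    prefix: str,
) -> list[dict[str, str]]:
    """Realize one species' planted counts as main-table gene rows.

    Per OG, gene *j* (1-based) carries every GO whose planted count is at
    least *j*; the (og, go) gene count then equals the planted count while
    genes carry multiple GO terms.
    """
    by_og: dict[str, list[tuple[str, int]]] = {}
    for og, go, c1, c2 in planted:
        count = (c1, c2)[species_idx]
        by_og.setdefault(og, []).append((go, count))
    rows: list[dict[str, str]] = []
    gene_no = 0
    for og in sorted(by_og):
        max_count = max((c for _, c in by_og[og]), default=0)
        for j in range(1, max_count + 1):
            gos = sorted(go for go, c in by_og[og] if c >= j)
            gene_no += 1
            rows.append(
                _gene_row(
                    rng,
                    query=f"{prefix}_G{gene_no:05d}",
                    og=og,
                    og_desc=og_descs[og],
                    go_mf=gos,
                )
            )
    # decoys: a gene with an OG but no domain GO terms, and one with GO
    # terms but no OG; neither may contribute a pair
    gene_no += 1
    rows.append(
        _gene_row(rng, f"{prefix}_G{gene_no:05d}", "9999at33090", "decoy og", [])
    )
    gene_no += 1
    rows.append(_gene_row(rng, f"{prefix}_G{gene_no:05d}", "", "", ["GO:0099999"]))
    rng.shuffle(rows)
    return rows


def _gene_row(
    rng: random.Random, query: str, og: str, og_desc: str, go_mf: list[str]
) -> dict[str, str]:
    row = {col: "" for col in WITH_ORTHOLOGER_COLUMNS}
    row.update(
        Query=query,
        Accession=f"A{rng.randrange(0, 10**5):05d}",
        Product_Name=og_desc or "synthetic protein",
        OrthoDB=og,
        OrthoDB_Desc=og_desc,
        GO_MF=";".join(go_mf),
        GO_BP="",
        GO_CC="",
        Evidence_existence=str(rng.randrange(1, 6)),
        Identity=f"{rng.uniform(80.0, 100.0):.1f}",
        Length=str(rng.randrange(100, 500)),
        Evalue=f"{rng.uniform(1e-50, 1e-10):.3g}",
        Score=f"{rng.uniform(100, 900):.1f}",
        Zen_OrthoDB=og,
        Zen_OrthoDB_Desc=og_desc,
        ODB_OG=og,
        ODB_Description=og_desc,
    )
    return row


def _rows_to_tsv(rows: list[dict[str, str]]) -> str:
    header = "\t".join(WITH_ORTHOLOGER_COLUMNS)
    body = "".join(
        "\t".join(row[col] for col in WITH_ORTHOLOGER_COLUMNS) + "\n" for row in rows
    )
    return header + "\n" + body


def simulate_annotation_pair(spec: FixtureSpec) -> AnnotationPairFixture:
    """Two species' main tables realizing planted co-occurrence counts.

    When ``spec.planted_cooc`` is ``None`` a random planted table is drawn
    from the OG/GO pools; it always includes a species-2-absent pair
    (count_f2 = 0) and two OGs whose descriptions collide after 20-character
    truncation, both paired with a shared GO term.
    """
    rng = random.Random(spec.seed + 202)
    if spec.planted_cooc is None:
        planted = list(random_planted_cooc(rng, spec))
        planted.append(("8800at33090", "GO:0005000", 2, 0))
        planted.append(("9101at33090", "GO:0006000", 1, 1))
        planted.append(("9102at33090", "GO:0006000", 2, 1))
        planted = sorted(set(planted))
    else:
        planted = sorted(spec.planted_cooc)
    _validate_planted(planted)

    og_descs: dict[str, str] = {}
    for i, og in enumerate(sorted({og for og, *_ in planted})):
        og_descs[og] = _OG_DESCS[i % len(_OG_DESCS)] + f" {i}"
    # force the 20-char label collision pair when present
    if "9101at33090" in og_descs and "9102at33090" in og_descs:
        og_descs["9101at33090"] = "Shared truncated description alpha"
        og_descs["9102at33090"] = "Shared truncated description beta"

    go_names = {p[1]: f"synthetic term {int(p[1][3:])}" for p in planted}
    f1_rows = _species_rows(rng, planted, og_descs, 0, "F1")
    f2_rows = _species_rows(rng, planted, og_descs, 1, "F2")
    truth = [
        CoocRecord(og, og_descs[og], go, go_names[go], c1, c2)
        for og, go, c1, c2 in planted
    ]
    return AnnotationPairFixture(
        f1_tsv=_rows_to_tsv(f1_rows),
        f2_tsv=_rows_to_tsv(f2_rows),
        truth_cooc=truth,
        go_names=go_names,
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: planted pattern of a between-species annotation gap: one OG carries three
#: molecular-function terms in species 1 but only two in species 2
CASE_GO_GAP = (
    ("42661at33090", "GO:0000009", 1, 1),
    ("42661at33090", "GO:0000030", 1, 0),
    ("42661at33090", "GO:0004376", 1, 1),
    ("3538at33090", "GO:0043015", 2, 2),
    ("3538at33090", "GO:0051011", 2, 1),
)

_CASE_GO_NAMES = {
    "GO:0000009": "alpha-1,6-mannosyltransferase activity",
    "GO:0000030": "mannosyltransferase activity",
    "GO:0004376": "glycolipid mannosyltransferase activity",
    "GO:0043015": "gamma-tubulin binding",
    "GO:0051011": "microtubule minus-end binding",
}

_CASE_OG_DESCS = {
    "42661at33090": "GPI mannosyltransferase 2",
    "3538at33090": "Gamma-tubulin complex component",
}


def case_go_gap_fixture(seed: int = 0) -> AnnotationPairFixture:
    """The packaged annotation-gap preset (``case-3-5-3`` on the CLI)."""
    spec = FixtureSpec(seed=seed, planted_cooc=CASE_GO_GAP)
    fx = simulate_annotation_pair(spec)
    renamed = [
        CoocRecord(
            r.og_id,
            _CASE_OG_DESCS.get(r.og_id, r.og_desc),
            r.go_id,
            _CASE_GO_NAMES.get(r.go_id, r.go_desc),
            r.count_f1,
            r.count_f2,
        )
        for r in fx.truth_cooc
    ]
    # rebuild the tables with the case descriptions
    rng = random.Random(seed + 202)
    og_descs = dict(_CASE_OG_DESCS)
    f1_rows = _species_rows(rng, list(CASE_GO_GAP), og_descs, 0, "F1")
    f2_rows = _species_rows(rng, list(CASE_GO_GAP), og_descs, 1, "F2")
    return AnnotationPairFixture(
        f1_tsv=_rows_to_tsv(f1_rows),
        f2_tsv=_rows_to_tsv(f2_rows),
        truth_cooc=renamed,
        go_names=dict(_CASE_GO_NAMES),
    )


PRESETS = ("zen", "annotate", "network", "case-3-5-3")


def generate_preset(preset: str, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Materialize one named fixture preset under ``out_dir``."""
    spec = FixtureSpec(seed=seed)
    if preset == "zen":
        return simulate_reference_and_hits(spec).write(out_dir)
    if preset == "annotate":
        fx = simulate_reference_and_hits(spec)
        return fx.write(out_dir)
    if preset == "network":
        return simulate_annotation_pair(spec).write(out_dir)
    if preset == "case-3-5-3":
        return case_go_gap_fixture(seed).write(out_dir)
    raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
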