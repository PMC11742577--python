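"""Zen mapping: threshold-filtered best-hit transfer of OrthoDB group ids.

A query protein receives the orthologous-group (OG) id of its best
alignment hit against the OG-labelled reference, provided the hit clears
three thresholds: sequence identity of at least 50 %, E-value strictly
below 1e-6, and alignment coverage of at least 75 % of *both* the query and
the target sequence. Coverage is span-based by default,
``(qend - qstart + 1) / qlen`` (robust to internal gaps); an
aligned-column mode (``aln_length / len``) is available.

The module also resolves OGs to parental groups at a chosen taxonomic
level through child->parent OG pairs, computes the exact-match concordance
between two accession->OG maps at that level, and tabulates how much an
additive Zen map expands OG coverage over the knowledgebase's own
assignments.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .refdata import UniProtRecord, og_level

ZenMapping = dict[str, tuple[str, str]]
"""accession -> (og_id, og_description); at most one OG per accession."""


@dataclass(frozen=True)
class AlignmentHit:
    """One tabular protein-alignment row (outfmt-6 dialect with lengths).

    Coordinates are 1-based inclusive; ``qlen``/``slen`` are the full
    query/subject sequence lengths.
    """

    query_id: str
    target_id: str
    pident: float
    aln_length: int
    qstart: int
    qend: int
    sstart: int
    send: int
    qlen: int
    slen: int
    evalue: float
    bitscore: float

    @property
    def qcov(self) -> float:
        return (self.qend - self.qstart + 1) / self.qlen

    @property
    def tcov(self) -> float:
        return (self.send - self.sstart + 1) / self.slen


@dataclass(frozen=True)
class ZenThresholds:
    """Alignment-acceptance thresholds.

    Identity and coverage are inclusive bounds (>=); the E-value bound is
    exclusive (<). ``coverage_mode`` selects span-based coverage from
    alignment coordinates (default) or aligned-column coverage
    ``aln_length / length``.
    """

    min_identity: float = 50.0
    max_evalue_exclusive: float = 1e-6
    min_coverage: float = 0.75
    coverage_mode: str = "span"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError("min_identity must be in [0, 100]")
        if not 0.0 < self.min_coverage <= 1.0:
            raise ValueError("min_coverage must be in (0, 1]")
        if self.coverage_mode not in ("span", "aligned"):
            raise ValueError(f"unknown coverage_mode: {self.coverage_mode!r}")

    def accepts(self, hit: AlignmentHit) -> bool:
        if self.coverage_mode == "span":
            qcov, tcov = hit.qcov, hit.tcov
        else:
            qcov = hit.aln_length / hit.qlen
            tcov = hit.aln_length / hit.slen
        return (
            hit.pident >= self.min_identity
            and hit.evalue < self.max_evalue_exclusive
            and qcov >= self.min_coverage
            and tcov >= self.min_coverage
        )


@dataclass(frozen=True)
class OgPair:
    """A child->parent link between OGs at different taxonomic levels."""

    child_og: str
    parent_og: str


@dataclass(frozen=True)
class ConcordanceReport:
    n_compared: int
    n_exact: int

    @property
    def pct_exact(self) -> float:
        return 100.0 * self.n_exact / self.n_compared


@dataclass(frozen=True)
class CoverageSourceRow:
    source: str
    n_accessions: int
    n_with_ukb_og: int
    n_with_og_after_zen: int

    @property
    def pct_ukb(self) -> float:
        return 100.0 * self.n_with_ukb_og / self.n_accessions if self.n_accessions else 0.0

    @property
    def pct_after_zen(self) -> float:
        return 100.0 * self.n_with_og_after_zen / self.n_accessions if self.n_accessions else 0.0


@dataclass(frozen=True)
class CoverageReport:
    """OG-assignment coverage before and after additive Zen mapping."""

    rows: tuple[CoverageSourceRow, ...] = field(default_factory=tuple)

    def by_source(self, source: str) -> CoverageSourceRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def filter_hits(
    hits: Iterable[AlignmentHit], thresholds: ZenThresholds | None = None
) -> list[AlignmentHit]:
    """Keep hits passing identity/E-value/reciprocal-coverage thresholds.

    Input order is preserved; an empty input yields an empty list.
    """
    t = thresholds or ZenThresholds()
    return [h for h in hits if t.accepts(h)]


def best_hit_per_query(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Select one hit per query: highest bitscore, then lowest E-value, then
    lexicographically smallest target id (fully deterministic)."""
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.query_id] = hit
    return best


def _hit_rank(hit: AlignmentHit) -> tuple[float, float, str]:
    return (-hit.bitscore, hit.evalue, hit.target_id)


def propagate_ids(
    best: Mapping[str, AlignmentHit],
    target_og: Mapping[str, tuple[str, str]],
) -> ZenMapping:
    """Propagate each best-hit target's OG id and description to the query."""
    mapping: ZenMapping = {}
    for query, hit in best.items():
        if hit.target_id not in target_og:
            raise KeyError(f"best-hit target {hit.target_id!r} has no OG entry")
        mapping[query] = target_og[hit.target_id]
    return mapping


def map_to_parent_og(
    og: str, pairs: Iterable[OgPair], level_taxid: int
) -> str | None:
    """Resolve ``og`` (or an ancestor along child->parent links) at the
    requested taxonomic level; ``None`` if no ancestor sits at that level."""
    parent_of = {p.child_og: p.parent_og for p in pairs}
    current: str | None = og
    seen: set[str] = set()
    while current is not None:
        if current in seen:
            raise ValueError(f"cycle in OG pairs at {current!r}")
        seen.add(current)
        if og_level(current) == level_taxid:
            return current
        current = parent_of.get(current)
    return None


def concordance(
    a: ZenMapping,
    b: Mapping[str, str],
    pairs: Iterable[OgPair],
    level_taxid: int,
) -> ConcordanceReport:
    """Exact-match rate between two accession->OG maps at one taxonomic level.

    Only accessions present in both maps whose OGs *both* resolve at
    ``level_taxid`` (directly or via parental-OG expansion) are compared.
    """
    pair_list = list(pairs)
    n_compared = 0
    n_exact = 0
    for acc, (og_a, _) in a.items():
        og_b = b.get(acc)
        if og_b is None:
            continue
        res_a = map_to_parent_og(og_a, pair_list, level_taxid)
        res_b = map_to_parent_og(og_b, pair_list, level_taxid)
        if res_a is None or res_b is None:
            continue
        n_compared += 1
        if res_a == res_b:
            n_exact += 1
    if n_compared == 0:
        raise ValueError("nothing comparable: no accession resolves in both maps")
    return ConcordanceReport(n_compared=n_compared, n_exact=n_exact)


def coverage_report(
    records: Iterable[UniProtRecord], zen: ZenMapping
) -> CoverageReport:
    """Per-source OG coverage before (knowledgebase only) and after adding Zen."""
    counts = {
        src: [0, 0, 0] for src in ("sprot", "trembl", "total")
    }  # [n, with_ukb, after_zen]
    n_records = 0
    for rec in records:
        n_records += 1
        has_ukb = bool(rec.ukb_orthodb)
        has_after = has_ukb or rec.accession in zen
        for src in (rec.source, "total"):
            c = counts[src]
            c[0] += 1
            c[1] += has_ukb
            c[2] += has_after
    if n_records == 0:
        raise ValueError("coverage report requires at least one record")
    rows = tuple(
        CoverageSourceRow(src, *counts[src]) for src in ("sprot", "trembl", "total")
    )
    return CoverageReport(rows=rows)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

#: column order of the extended outfmt-6 dialect
HITS_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore qlen slen"
).split()


def read_hits_tsv(source: str | IO[str]) -> list[AlignmentHit]:
    """Read 14-column tab-separated alignment hits (outfmt 6 + qlen/slen)."""
    close = False
    if isinstance(source, str):
        source = open(source, encoding="utf-8")
        close = True
    try:
        hits = []
        for row in csv.reader(source, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 14:
                raise ValueError(f"expected 14 columns, got {len(row)}: {row!r}")
            hits.append(
                AlignmentHit(
                    query_id=row[0],
                    target_id=row[1],
                    pident=float(row[2]),
                    aln_length=int(row[3]),
                    qstart=int(row[6]),
                    qend=int(row[7]),
                    sstart=int(row[8]),
                    send=int(row[9]),
                    evalue=float(row[10]),
                    bitscore=float(row[11]),
                    qlen=int(row[12]),
                    slen=int(row[13]),
                )
            )
        return hits
    finally:
        if close:
            source.close()


def read_target_og_tsv(source: str | IO[str]) -> dict[str, tuple[str, str]]:
    """Read the 3-column ``seq_id  og_id  description`` target table."""
    close = False
    if isinstance(source, str):
        source = open(source, encoding="utf-8")
        close = True
    try:
        table = {}
        for row in csv.reader(source, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            table[row[0]] = (row[1], row[2] if len(row) > 2 else "")
        return table
    finally:
        if close:
            source.close()


def write_zen_tsv(mapping: ZenMapping, out: str | IO[str]) -> None:
    """Write a Zen mapping as 3-column TSV, sorted by accession."""
    close = False
    if isinstance(out, str):
        out = open(out, "w", encoding="utf-8", newline="")
        close = True
    try:
        w = csv.writer(out, delimiter="\t", lineterminator="\n")
        for acc in sorted(mapping):
            og, desc = mapping[acc]
            w.writerow([acc, og, desc])
    finally:
        if close:
            out.close()


def read_zen_tsv(source: str | IO[str]) -> ZenMapping:
    close = False
    if isinstance(source, str):
        source = open(source, encoding="utf-8")
        close = True
    try:
        mapping: ZenMapping = {}
        for row in csv.reader(source, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            mapping[row[0]] = (row[1], row[2] if len(row) > 2 else "")
        return mapping
    finally:
        if close:
            source.close()


def read_og_pairs_tsv(source: str | IO[str]) -> list[OgPair]:
    """Read the 2-column child->parent OG pairs table."""
    close = False
    if isinstance(source, str):
        source = open(source, encoding="utf-8")
        close = True
    try:
        return [
            OgPair(row[0], row[1])
            for row in csv.reader(source, delimiter="\t")
            if row and not row[0].startswith("#")
        ]
    finally:
        if close:
            source.close()
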