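"""Reference-database construction: UniProt flat-file parsing, annotated
FASTA headers, and taxonomy subsetting.

The reference database used for annotation transfer is a protein FASTA file
whose headers carry every annotation layer needed downstream (product name,
GO terms split by domain, Pfam/InterPro cross-references, protein-existence
level, UniProtKB's own OrthoDB group and the Zen-mapped group). Layers are
encoded as ``key=value`` tokens with percent-escaping so that decoding an
encoded header reproduces every field exactly.

Only the line types that carry those layers are read from the flat file
(ID, AC, DE, OX, DR, PE, SQ); everything else is ignored. The tolerant,
per-record error handling here (skip a defective record, keep parsing) is
the reason a dedicated reader exists instead of a full-compliance parser.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"^GO:\d{7}$")
PFAM_ID_RE = re.compile(r"^PF\d{5}$")
INTERPRO_ID_RE = re.compile(r"^IPR\d{6}$")
OG_ID_RE = re.compile(r"^(\d+)at(\d+)$")

#: DR GO aspect letter -> GO domain
GO_DOMAINS = {"F": "MF", "P": "BP", "C": "CC"}


def og_level(og_id: str) -> int:
    """Taxonomic level encoded in an OrthoDB group id ``<group>at<taxid>``."""
    m = OG_ID_RE.match(og_id)
    if not m:
        raise ValueError(f"not an OrthoDB group id: {og_id!r}")
    return int(m.group(2))


@dataclass(frozen=True)
class GoTerm:
    """A Gene Ontology term with its domain (MF, BP or CC)."""

    go_id: str
    domain: str
    description: str = ""

    def __post_init__(self) -> None:
        if not GO_ID_RE.match(self.go_id):
            raise ValueError(f"malformed GO id: {self.go_id!r}")
        if self.domain not in ("MF", "BP", "CC"):
            raise ValueError(f"unknown GO domain: {self.domain!r}")


@dataclass
class UniProtRecord:
    """One reference protein with its annotation layers."""

    accession: str
    source: str = "trembl"  # "sprot" (reviewed) or "trembl"
    product_name: str = ""
    pe_level: int | None = None
    taxid: int | None = None
    go_terms: list[GoTerm] = field(default_factory=list)
    pfam_ids: list[str] = field(default_factory=list)
    interpro_ids: list[str] = field(default_factory=list)
    ukb_orthodb: list[str] = field(default_factory=list)
    sequence: str = ""

    def go_ids(self, domain: str) -> list[str]:
        return [t.go_id for t in self.go_terms if t.domain == domain]


@dataclass(frozen=True)
class TaxNode:
    """One node of the NCBI taxonomy; the root points at itself."""

    taxid: int
    parent_taxid: int


# ---------------------------------------------------------------------------
# Flat-file ("dat") parsing
# ---------------------------------------------------------------------------

_DE_RECNAME = re.compile(r"RecName:\s*Full=([^;{]+)")
_DE_SUBNAME = re.compile(r"SubName:\s*Full=([^;{]+)")
_OX_TAXID = re.compile(r"NCBI_TaxID=(\d+)")
_PE_LEVEL = re.compile(r"^(\d)")
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYXBZJUO]*$")


def _open_text(source: str | IO[str]) -> IO[str]:
    if isinstance(source, str):
        if source.endswith(".gz"):
            return io.TextIOWrapper(gzip.open(source, "rb"), encoding="utf-8")
        return open(source, encoding="utf-8")
    return source


def parse_uniprot_dat(source: str | IO[str]) -> list[UniProtRecord]:
    """Parse UniProt-style flat-file records into :class:`UniProtRecord`.

    ``source`` is a path (optionally ``.gz``) or an open text stream holding
    a concatenation of records terminated by ``//`` lines. Records missing
    an accession or a sequence are skipped with a warning; malformed GO ids
    drop only the offending term; unrecognised line types are ignored.
    """
    handle = _open_text(source)
    records: list[UniProtRecord] = []
    for raw in _iter_record_lines(handle):
        rec = _parse_record(raw)
        if rec is not None:
            records.append(rec)
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            logger.warning("duplicate accession in flat file: %s", rec.accession)
        seen.add(rec.accession)
    return records


def _iter_record_lines(handle: IO[str]) -> Iterator[list[str]]:
    block: list[str] = []
    for line in handle:
        line = line.rstrip("\n")
        if line.strip() == "//":
            if block:
                yield block
            block = []
        elif line:
            block.append(line)
    if block:
        yield block


def _parse_record(lines: list[str]) -> UniProtRecord | None:
    accession = ""
    source_db = "trembl"
    product = ""
    pe: int | None = None
    taxid: int | None = None
    gos: list[GoTerm] = []
    pfams: list[str] = []
    iprs: list[str] = []
    ogs: list[str] = []
    seq_parts: list[str] = []
    in_seq = False

    for line in lines:
        code, _, rest = line[:2], line[2:5], line[5:]
        if in_seq and line.startswith("     "):
            seq_parts.append(line.replace(" ", ""))
            continue
        in_seq = False
        if code == "ID":
            source_db = "sprot" if "Reviewed" in rest else "trembl"
        elif code == "AC":
            if not accession:
                first = rest.split(";")[0].strip()
                accession = first
        elif code == "DE":
            if not product:
                m = _DE_RECNAME.search(rest) or _DE_SUBNAME.search(rest)
                if m:
                    product = m.group(1).strip()
        elif code == "OX":
            m = _OX_TAXID.search(rest)
            if m:
                taxid = int(m.group(1))
        elif code == "PE":
            m = _PE_LEVEL.match(rest.strip())
            if m:
                pe = int(m.group(1))
        elif code == "DR":
            _parse_dr(rest, gos, pfams, iprs, ogs)
        elif code == "SQ":
            in_seq = True
        # all other line types (FT, CC, OS, ...) deliberately ignored

    if not accession or not seq_parts:
        logger.warning(
            "skipping record missing %s (accession=%r)",
            "AC" if not accession else "SQ",
            accession or "?",
        )
        return None
    sequence = "".join(seq_parts)
    return UniProtRecord(
        accession=accession,
        source=source_db,
        product_name=product,
        pe_level=pe,
        taxid=taxid,
        go_terms=gos,
        pfam_ids=pfams,
        interpro_ids=iprs,
        ukb_orthodb=ogs,
        sequence=sequence,
    )


def _parse_dr(
    rest: str,
    gos: list[GoTerm],
    pfams: list[str],
    iprs: list[str],
    ogs: list[str],
) -> None:
    parts = [p.strip().rstrip(".") for p in rest.split(";")]
    if not parts:
        return
    db = parts[0]
    if db == "GO" and len(parts) >= 3:
        go_id = parts[1]
        aspect, _, desc = parts[2].partition(":")
        domain = GO_DOMAINS.get(aspect)
        if not GO_ID_RE.match(go_id) or domain is None:
            logger.warning("skipping malformed GO cross-reference: %r", rest)
            return
        gos.append(GoTerm(go_id, domain, desc))
    elif db == "Pfam" and len(parts) >= 2:
        pfams.append(parts[1])
    elif db == "InterPro" and len(parts) >= 2:
        iprs.append(parts[1])
    elif db == "OrthoDB" and len(parts) >= 2:
        ogs.append(parts[1])


# ---------------------------------------------------------------------------
# Annotated-header codec
# ---------------------------------------------------------------------------

#: token order in the encoded header (after the accession)
HEADER_KEYS = (
    "name",
    "zen",
    "zen_desc",
    "ukb",
    "go_mf",
    "go_bp",
    "go_cc",
    "pe",
    "ipr",
    "pfam",
    "src",
)

_ESCAPES = {" ": "%20", "=": "%3D", "%": "%25", "\t": "%09", "\n": "%0A"}
_UNESCAPES = {v[1:]: k for k, v in _ESCAPES.items()}
_ESCAPE_RE = re.compile(r"[ =%\t\n]")
_UNESCAPE_RE = re.compile(r"%(20|3D|25|09|0A)")


def escape_value(value: str) -> str:
    """Percent-escape the header delimiters (space, ``=``, ``%``) in a value."""
    return _ESCAPE_RE.sub(lambda m: _ESCAPES[m.group(0)], value)


def unescape_value(value: str) -> str:
    return _UNESCAPE_RE.sub(lambda m: _UNESCAPES[m.group(1)], value)


def encode_header(
    record: UniProtRecord, zen_og: str = "", zen_desc: str = ""
) -> str:
    """Render the annotation layers of ``record`` as header tokens.

    The result is the FASTA description: space-separated ``key=value``
    tokens; list values are ``;``-joined; free-text values are
    percent-escaped so the encoding round-trips exactly.
    """
    fields = {
        "name": escape_value(record.product_name),
        "zen": escape_value(zen_og),
        "zen_desc": escape_value(zen_desc),
        "ukb": ";".join(record.ukb_orthodb),
        "go_mf": ";".join(record.go_ids("MF")),
        "go_bp": ";".join(record.go_ids("BP")),
        "go_cc": ";".join(record.go_ids("CC")),
        "pe": "" if record.pe_level is None else str(record.pe_level),
        "ipr": ";".join(record.interpro_ids),
        "pfam": ";".join(record.pfam_ids),
        "src": record.source,
    }
    return " ".join(f"{k}={fields[k]}" for k in HEADER_KEYS)


@dataclass
class HeaderFields:
    """Decoded annotation payload of one reference-database entry."""

    accession: str
    product_name: str = ""
    zen_og: str = ""
    zen_desc: str = ""
    ukb_orthodb: list[str] = field(default_factory=list)
    go_mf: list[str] = field(default_factory=list)
    go_bp: list[str] = field(default_factory=list)
    go_cc: list[str] = field(default_factory=list)
    pe_level: int | None = None
    interpro_ids: list[str] = field(default_factory=list)
    pfam_ids: list[str] = field(default_factory=list)
    source: str = "trembl"


def decode_header(accession: str, description: str) -> HeaderFields:
    """Invert :func:`encode_header` (``decode(encode(r))`` is the identity)."""
    tokens: dict[str, str] = {}
    for tok in description.split(" "):
        if "=" in tok:
            k, _, v = tok.partition("=")
            tokens[k] = v

    def _list(key: str) -> list[str]:
        v = tokens.get(key, "")
        return v.split(";") if v else []

    pe_raw = tokens.get("pe", "")
    return HeaderFields(
        accession=accession,
        product_name=unescape_value(tokens.get("name", "")),
        zen_og=unescape_value(tokens.get("zen", "")),
        zen_desc=unescape_value(tokens.get("zen_desc", "")),
        ukb_orthodb=_list("ukb"),
        go_mf=_list("go_mf"),
        go_bp=_list("go_bp"),
        go_cc=_list("go_cc"),
        pe_level=int(pe_raw) if pe_raw else None,
        interpro_ids=_list("ipr"),
        pfam_ids=_list("pfam"),
        source=tokens.get("src", "trembl"),
    )


def build_reference(
    records: Iterable[UniProtRecord],
    zen: Mapping[str, tuple[str, str]],
    out: str | IO[str],
) -> int:
    """Write the annotated reference FASTA (60-column wrap).

    ``zen`` maps a subset of accessions to ``(og_id, description)``; records
    without an entry carry an empty ``zen=`` token. Returns the number of
    entries written. Duplicate accessions are an error.
    """
    seen: set[str] = set()
    seq_records = []
    for rec in records:
        if rec.accession in seen:
            raise ValueError(f"duplicate accession: {rec.accession}")
        seen.add(rec.accession)
        og, desc = zen.get(rec.accession, ("", ""))
        seq_records.append(
            SeqRecord(
                Seq(rec.sequence),
                id=rec.accession,
                description=encode_header(rec, og, desc),
            )
        )
    if isinstance(out, str):
        with open(out, "w", encoding="utf-8") as fh:
            n = SeqIO.write(seq_records, fh, "fasta")
    else:
        n = SeqIO.write(seq_records, out, "fasta")
    return n


def read_reference(source: str | IO[str]) -> dict[str, HeaderFields]:
    """Decode an annotated reference FASTA into ``accession -> payload``."""
    payload: dict[str, HeaderFields] = {}
    for rec in SeqIO.parse(source, "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].lstrip(" ")
        payload[rec.id] = decode_header(rec.id, desc)
    return payload


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

def read_taxonomy_nodes(source: str | IO[str]) -> list[TaxNode]:
    """Read the ``nodes.dmp`` dialect (``taxid | parent | ...``), columns 1-2."""
    handle = _open_text(source)
    nodes = []
    for line in handle:
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split("|")]
        nodes.append(TaxNode(int(parts[0]), int(parts[1])))
    return nodes


def select_descendant_taxa(nodes: Iterable[TaxNode], root_taxid: int) -> set[int]:
    """Taxids of ``root_taxid`` and every node whose parent chain reaches it."""
    children: dict[int, list[int]] = {}
    taxids = set()
    for n in nodes:
        taxids.add(n.taxid)
        if n.parent_taxid != n.taxid:
            children.setdefault(n.parent_taxid, []).append(n.taxid)
    if root_taxid not in taxids:
        raise ValueError(f"root taxid {root_taxid} not present in nodes")
    selected = {root_taxid}
    stack = [root_taxid]
    while stack:
        for child in children.get(stack.pop(), ()):
            if child not in selected:
                selected.add(child)
                stack.append(child)
    return selected
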