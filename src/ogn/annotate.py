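"""Main annotation table: merge best-hit payloads with orthology-mapper rows.

Each aligned query receives the annotation layers decoded from its best
hit's reference header (accession, product name, GO terms, Pfam, InterPro,
protein-existence level, knowledgebase OG, Zen OG) plus the alignment
statistics. When orthology-mapper (OrthoLoger-style) results are supplied,
the ``OrthoDB`` column prioritises the mapper's OG (``ODB_OG``) and falls
back to the Zen OG, and empty UniProt-derived GO_MF / GO_BP cells are
filled from the mapper's GO inferences. Propagation is fill-only-when-empty
(never a union) and GO_CC is never propagated.

Multi-valued cells are ``;``-joined without spaces; an empty cell is the
empty string.
"""

from __future__ import annotations

import csv
import logging
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .refdata import HeaderFields
from .zen import AlignmentHit

logger = logging.getLogger(__name__)

#: column order of the main TSV without orthology-mapper results
BASE_COLUMNS = (
    "Query",
    "Accession",
    "Product_Name",
    "OrthoDB",
    "OrthoDB_Desc",
    "UKB_OrthoDB",
    "GO_BP",
    "GO_MF",
    "GO_CC",
    "Evidence_existence",
    "InterPro",
    "Pfam",
    "Identity",
    "Length",
    "Evalue",
    "Score",
)

#: columns added when orthology-mapper results are merged in
ORTHOLOGER_COLUMNS = (
    "Zen_OrthoDB",
    "Zen_OrthoDB_Desc",
    "ODB_OG",
    "ODB_Description",
    "ODB_GO_MF",
    "ODB_GO_BP",
    "ODB_EC",
    "ODB_COG_category",
    "ODB_KEGG_ko",
    "ODB_Interpro",
    "ODB_evalue",
    "ODB_score",
)

WITH_ORTHOLOGER_COLUMNS = BASE_COLUMNS + ORTHOLOGER_COLUMNS

SEP = ";"

#: main-table column holding each GO domain / the InterPro layer
LAYER_COLUMNS = {
    "GO-MF": "GO_MF",
    "GO-BP": "GO_BP",
    "GO-CC": "GO_CC",
    "InterPro": "InterPro",
}


@dataclass(frozen=True)
class OrthologerRow:
    """One orthology-mapper result row (one best row per query)."""

    query_id: str
    odb_og: str = ""
    odb_description: str = ""
    odb_go_mf: tuple[str, ...] = ()
    odb_go_bp: tuple[str, ...] = ()
    odb_ec: str = ""
    odb_cog_category: str = ""
    odb_kegg_ko: str = ""
    odb_interpro: str = ""
    odb_evalue: float = 0.0
    odb_score: float = 0.0


def read_orthologer_tsv(source: str | IO[str]) -> dict[str, OrthologerRow]:
    """Read 11-column orthology-mapper results (permissive: short rows are
    padded). When a query appears more than once, the best row is retained
    (highest score, then lowest E-value)."""
    close = False
    if isinstance(source, str):
        source = open(source, encoding="utf-8")
        close = True
    try:
        best: dict[str, OrthologerRow] = {}
        for raw in csv.reader(source, delimiter="\t"):
            if not raw or raw[0].startswith("#") or raw[0] == "query_id":
                continue
            row = list(raw) + [""] * (11 - len(raw))
            rec = OrthologerRow(
                query_id=row[0],
                odb_og=row[1],
                odb_description=row[2],
                odb_go_mf=tuple(x for x in row[3].split(SEP) if x),
                odb_go_bp=tuple(x for x in row[4].split(SEP) if x),
                odb_ec=row[5],
                odb_cog_category=row[6],
                odb_kegg_ko=row[7],
                odb_interpro=row[8],
                odb_evalue=float(row[9]) if row[9] else 0.0,
                odb_score=float(row[10]) if row[10] else 0.0,
            )
            cur = best.get(rec.query_id)
            if cur is None or (-rec.odb_score, rec.odb_evalue) < (
                -cur.odb_score,
                cur.odb_evalue,
            ):
                best[rec.query_id] = rec
        return best
    finally:
        if close:
            source.close()


def merge_annotations(
    best: Mapping[str, AlignmentHit],
    payload: Mapping[str, HeaderFields],
    ortho: Mapping[str, OrthologerRow] | None = None,
    use_orthologer: bool = False,
) -> list[dict[str, str]]:
    """Build main-table rows, one per aligned query.

    ``payload`` must cover every best-hit target. With ``use_orthologer``,
    ``OrthoDB`` takes the mapper OG when present (falling back to the Zen
    OG) and empty GO_MF/GO_BP cells are filled from the mapper; without it,
    ``OrthoDB`` is the Zen OG and the row has only the 16 base columns.
    """
    ortho = ortho or {}
    rows: list[dict[str, str]] = []
    for query, hit in best.items():
        fields = payload.get(hit.target_id)
        if fields is None:
            raise KeyError(f"no reference payload for target {hit.target_id!r}")
        row = {
            "Query": query,
            "Accession": fields.accession,
            "Product_Name": fields.product_name,
            "UKB_OrthoDB": SEP.join(fields.ukb_orthodb),
            "GO_BP": SEP.join(fields.go_bp),
            "GO_MF": SEP.join(fields.go_mf),
            "GO_CC": SEP.join(fields.go_cc),
            "Evidence_existence": "" if fields.pe_level is None else str(fields.pe_level),
            "InterPro": SEP.join(fields.interpro_ids),
            "Pfam": SEP.join(fields.pfam_ids),
            "Identity": _fmt_float(hit.pident),
            "Length": str(hit.aln_length),
            "Evalue": _fmt_evalue(hit.evalue),
            "Score": _fmt_float(hit.bitscore),
        }
        if not use_orthologer:
            row["OrthoDB"] = fields.zen_og
            row["OrthoDB_Desc"] = fields.zen_desc
            rows.append({col: row[col] for col in BASE_COLUMNS})
            continue
        orow = ortho.get(query)
        if orow is not None and orow.odb_og:
            row["OrthoDB"] = orow.odb_og
            row["OrthoDB_Desc"] = orow.odb_description
        else:
            row["OrthoDB"] = fields.zen_og
            row["OrthoDB_Desc"] = fields.zen_desc
        if orow is not None:
            if not row["GO_MF"]:
                row["GO_MF"] = SEP.join(orow.odb_go_mf)
            if not row["GO_BP"]:
                row["GO_BP"] = SEP.join(orow.odb_go_bp)
        row["Zen_OrthoDB"] = fields.zen_og
        row["Zen_OrthoDB_Desc"] = fields.zen_desc
        row["ODB_OG"] = orow.odb_og if orow else ""
        row["ODB_Description"] = orow.odb_description if orow else ""
        row["ODB_GO_MF"] = SEP.join(orow.odb_go_mf) if orow else ""
        row["ODB_GO_BP"] = SEP.join(orow.odb_go_bp) if orow else ""
        row["ODB_EC"] = orow.odb_ec if orow else ""
        row["ODB_COG_category"] = orow.odb_cog_category if orow else ""
        row["ODB_KEGG_ko"] = orow.odb_kegg_ko if orow else ""
        row["ODB_Interpro"] = orow.odb_interpro if orow else ""
        row["ODB_evalue"] = _fmt_evalue(orow.odb_evalue) if orow else ""
        row["ODB_score"] = _fmt_float(orow.odb_score) if orow else ""
        rows.append({col: row[col] for col in WITH_ORTHOLOGER_COLUMNS})
    return rows


def _fmt_float(x: float) -> str:
    return f"{x:g}"


def _fmt_evalue(x: float) -> str:
    return f"{x:g}"


def term_counts(
    rows: Iterable[Mapping[str, str]],
    layer: str,
    top_n: int = 50,
    names: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count rows carrying each term of one annotation layer.

    A row contributes once per distinct term in its cell. Returns the full
    table and the top-``top_n`` subset; both are sorted by count descending
    then term id ascending (ties at the cut retain the lexicographically
    smaller id). ``layer`` is one of ``GO-MF``, ``GO-BP``, ``GO-CC``,
    ``InterPro``.
    """
    if layer not in LAYER_COLUMNS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {sorted(LAYER_COLUMNS)}")
    col = LAYER_COLUMNS[layer]
    names = names or {}
    counts: dict[str, int] = {}
    for row in rows:
        cell = row.get(col, "")
        for term in set(t for t in cell.split(SEP) if t):
            counts[term] = counts.get(term, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(
        [(t, names.get(t, ""), c) for t, c in ordered],
        columns=["term_id", "description", "count"],
    )
    return table, table.head(top_n).reset_index(drop=True)


def rows_to_frame(rows: Sequence[Mapping[str, str]], use_orthologer: bool) -> pd.DataFrame:
    cols = list(WITH_ORTHOLOGER_COLUMNS if use_orthologer else BASE_COLUMNS)
    return pd.DataFrame(list(rows), columns=cols).fillna("")


def read_main_tsv(source: str | IO[str]) -> list[dict[str, str]]:
    """Read a main annotation TSV back into row dicts (either variant)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    return df.to_dict(orient="records")


def write_outputs(
    rows: Sequence[Mapping[str, str]],
    query_fasta: str | IO[str],
    best: Mapping[str, AlignmentHit],
    out_dir: str | Path,
    project: str = "Project",
    use_orthologer: bool = False,
    go_names: Mapping[str, str] | None = None,
    make_zip: bool = False,
    top_n: int = 50,
) -> dict[str, Path]:
    """Write the annotation bundle and return the paths written.

    The bundle contains the main TSV (``<project>_Hayai_annotation_v3.2.tsv``),
    ``unaligned.fasta`` with the query sequences absent from ``best`` (input
    order and sequences preserved), four term-count TSVs, four top-term bar
    charts (PDF), a log file, and optionally a ZIP of all of the above.
    Reruns on identical inputs are byte-identical for all text outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    main_path = out / f"{project}_Hayai_annotation_v3.2.tsv"
    rows_to_frame(rows, use_orthologer).to_csv(
        main_path, sep="\t", index=False, lineterminator="\n"
    )
    paths["main"] = main_path

    queries = list(SeqIO.parse(query_fasta, "fasta"))
    unaligned = [q for q in queries if q.id not in best]
    una_path = out / "unaligned.fasta"
    with open(una_path, "w", encoding="utf-8") as fh:
        SeqIO.write(unaligned, fh, "fasta")
    paths["unaligned"] = una_path

    for layer in ("GO-MF", "GO-BP", "GO-CC", "InterPro"):
        table, top = term_counts(rows, layer, top_n=top_n, names=go_names)
        slug = layer.lower().replace("-", "_")
        count_path = out / f"{project}_{slug}_counts.tsv"
        table.to_csv(count_path, sep="\t", index=False, lineterminator="\n")
        paths[f"counts_{slug}"] = count_path
        plot_path = out / f"{project}_{slug}_top{top_n}.pdf"
        _plot_top_terms(top, layer, plot_path)
        paths[f"plot_{slug}"] = plot_path

    log_path = out / f"{project}_annotation.log"
    with open(log_path, "w", encoding="utf-8") as fh:
        fh.write(f"project\t{project}\n")
        fh.write(f"queries\t{len(queries)}\n")
        fh.write(f"aligned\t{len(rows)}\n")
        fh.write(f"unaligned\t{len(unaligned)}\n")
        fh.write(f"orthologer\t{use_orthologer}\n")
    paths["log"] = log_path

    if make_zip:
        zip_path = out / f"{project}_HayaiAnnotation_v3.2.zip"
        with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
            for key, p in sorted(paths.items()):
                zf.write(p, arcname=p.name)
        paths["zip"] = zip_path
    return paths


def _plot_top_terms(top: pd.DataFrame, layer: str, path: Path) -> None:
    # plots are cosmetic; the tested surface is the count tables
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, max(2, 0.22 * max(len(top), 1))))
    if len(top):
        labels = [
            f"{t} {d[:40]}" if d else t
            for t, d in zip(top["term_id"], top["description"])
        ]
        ax.barh(range(len(top)), top["count"], color="#d95f02")
        ax.set_yticks(range(len(top)))
        ax.set_yticklabels(labels, fontsize=6)
        ax.invert_yaxis()
    ax.set_xlabel("genes")
    ax.set_title(f"Top {len(top)} {layer} terms")
    fig.tight_layout()
    fig.savefig(path, metadata={"CreationDate": None})
    plt.close(fig)
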