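import io
import random

import pytest

from ogn import annotate, fixtures, network, refdata, zen


@pytest.fixture
def toy_dat() -> str:
    return (
        "ID   Q00001_ARATH   Reviewed;   3 AA.\n"
        "AC   Q00001;\n"
        "DE   RecName: Full=Toy kinase;\n"
        "OS   Arabidopsis thaliana.\n"
        "OX   NCBI_TaxID=3702;\n"
        "DR   GO; GO:0000030; F:mannosyltransferase activity; IEA:InterPro.\n"
        "DR   Pfam; PF00012; Toy; 1.\n"
        "DR   InterPro; IPR000001; Toy.\n"
        "DR   OrthoDB; 42661at33090; -.\n"
        "PE   1;\n"
        "SQ   SEQUENCE   3 AA;  331 MW;  0000000000000000 CRC64;\n"
        "     MKV\n"
        "//\n"
    )


@pytest.fixture
def toy_records(toy_dat):
    return refdata.parse_uniprot_dat(io.StringIO(toy_dat))


def make_hit(
    query_id="q1",
    target_id="t1",
    pident=90.0,
    evalue=1e-20,
    bitscore=200.0,
    qcov=0.9,
    tcov=0.9,
    qlen=400,
    slen=400,
):
    """Hit with span coverage set exactly via the end coordinates."""
    qend = round(qcov * qlen)
    send = round(tcov * slen)
    return zen.AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        pident=pident,
        aln_length=max(qend, send),
        qstart=1,
        qend=qend,
        sstart=1,
        send=send,
        qlen=qlen,
        slen=slen,
        evalue=evalue,
        bitscore=bitscore,
    )


def brute_force_cooc(f1_rows, f2_rows, params):
    """Independent triple-loop enumeration of OG-GO pair gene counts."""
    col = {"MF": "GO_MF", "BP": "GO_BP"}[params.domain]
    counts = {}
    for idx, rows in enumerate((f1_rows, f2_rows)):
        for row in rows:
            if row.get("Identity") and float(row["Identity"]) < params.min_identity:
                continue
            if params.priority == "orthologer":
                og = row.get("ODB_OG", "") or row.get(
                    "Zen_OrthoDB", row.get("OrthoDB", "")
                )
            else:
                og = row.get("Zen_OrthoDB", row.get("OrthoDB", "")) or row.get(
                    "ODB_OG", ""
                )
            if not og:
                continue
            for go in set(g for g in row.get(col, "").split(";") if g):
                key = (og, go)
                if key not in counts:
                    counts[key] = [0, 0]
                counts[key][idx] += 1
    return {k: tuple(v) for k, v in counts.items()}


def random_annotation_rows(rng: random.Random, n_genes, n_ogs, n_gos):
    """Random with-orthologer main-table rows for oracle comparisons."""
    ogs = [f"{i}at33090" for i in range(1, n_ogs + 1)]
    gos = [f"GO:{i:07d}" for i in range(1, n_gos + 1)]
    rows = []
    for i in range(n_genes):
        row = {c: "" for c in annotate.WITH_ORTHOLOGER_COLUMNS}
        row["Query"] = f"g{i}"
        row["Identity"] = f"{rng.uniform(30, 100):.1f}"
        if rng.random() < 0.8:
            row["ODB_OG"] = rng.choice(ogs)
            row["ODB_Description"] = f"desc of {row['ODB_OG']}"
        if rng.random() < 0.8:
            row["Zen_OrthoDB"] = rng.choice(ogs)
            row["Zen_OrthoDB_Desc"] = f"desc of {row['Zen_OrthoDB']}"
        terms = rng.sample(gos, rng.randrange(0, min(5, n_gos)))
        row["GO_MF"] = ";".join(terms)
        row["GO_BP"] = ";".join(rng.sample(gos, rng.randrange(0, min(3, n_gos))))
        rows.append(row)
    return rows
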