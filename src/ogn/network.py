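"""Two-species OG-GO co-occurrence dataset and bipartite network.

Starting from two main annotation tables (species f1 and f2), every gene
with an effective orthologous group contributes one count to each
(OG, GO) pair formed with the distinct GO ids of the chosen domain (MF or
BP) on that gene. The Network Dataset is the union of pairs over both
species with absolute per-species gene counts. A log-scale threshold
``|ln(c1+1) - ln(c2+1)| >= T`` optionally keeps only pairs whose abundance
differs between the species (or, in ``similar`` mode, pairs within T).

A network is seeded from one GO term: its OGs become orange "odb:"-prefixed
source nodes, every GO term attached to those OGs becomes a target node,
and directed OG->GO edges carry the per-species counts as
``f1:<c1>, f2:<c2>`` labels. Nodes are keyed by truncated display label
(GO descriptions to 30 characters, OG descriptions to 20), so OGs whose
truncated descriptions collide collapse into one node and parallel edges
appear — a deliberate aid for comparing similarly described groups. The
graph is capped at 100 nodes, keeping the seed GO, then the
highest-count OGs, then the highest-count GO terms.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx

DOMAIN_COLUMNS = {"MF": "GO_MF", "BP": "GO_BP"}


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of the co-occurrence analysis.

    ``min_identity`` filters genes on the alignment Identity column;
    ``domain`` selects GO Molecular Function or Biological Process (CC is
    not offered); ``priority`` chooses which OG source wins when both the
    orthology mapper and Zen assign one; ``threshold`` is the ln(count+1)
    difference bound; ``keep`` retains pairs whose abundance differs
    (``diff``, default) or is similar (``similar``); ``key_mode`` keys
    graph nodes by truncated label (default, allows collisions) or by id.
    """

    min_identity: float = 0.0
    domain: str = "MF"
    priority: str = "orthologer"
    threshold: float = 0.0
    node_cap: int = 100
    go_label_len: int = 30
    og_label_len: int = 20
    keep: str = "diff"
    key_mode: str = "label"

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_COLUMNS:
            raise ValueError("domain must be 'MF' or 'BP'")
        if self.priority not in ("orthologer", "zen"):
            raise ValueError("priority must be 'orthologer' or 'zen'")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.keep not in ("diff", "similar"):
            raise ValueError("keep must be 'diff' or 'similar'")
        if self.key_mode not in ("label", "id"):
            raise ValueError("key_mode must be 'label' or 'id'")


@dataclass(frozen=True)
class CoocRecord:
    """One (OG, GO) pair with absolute per-species gene counts."""

    og_id: str
    og_desc: str
    go_id: str
    go_desc: str
    count_f1: int
    count_f2: int

    def log_difference(self) -> float:
        return abs(math.log(self.count_f1 + 1) - math.log(self.count_f2 + 1))


def effective_og(
    row: Mapping[str, str], priority: str = "orthologer"
) -> tuple[str, str] | None:
    """The OG (and description) a gene contributes under a priority rule.

    The priority source's OG is used when present, else the other source's;
    ``None`` when neither assigns one. Rows from a Zen-only table (no
    ``Zen_OrthoDB`` column) fall back to their ``OrthoDB`` column.
    """
    zen_og = row.get("Zen_OrthoDB", row.get("OrthoDB", ""))
    zen_desc = row.get("Zen_OrthoDB_Desc", row.get("OrthoDB_Desc", ""))
    odb_og = row.get("ODB_OG", "")
    odb_desc = row.get("ODB_Description", "")
    if priority == "orthologer":
        ordered = ((odb_og, odb_desc), (zen_og, zen_desc))
    else:
        ordered = ((zen_og, zen_desc), (odb_og, odb_desc))
    for og, desc in ordered:
        if og:
            return og, desc
    return None


def _gene_pairs(
    rows: Iterable[Mapping[str, str]], p: NetworkParams
) -> Iterable[tuple[str, str, frozenset[str]]]:
    """(og, desc, distinct domain-GO ids) per contributing gene."""
    col = DOMAIN_COLUMNS[p.domain]
    for row in rows:
        ident = row.get("Identity", "")
        try:
            if ident != "" and float(ident) < p.min_identity:
                continue
        except ValueError:
            continue
        eff = effective_og(row, p.priority)
        if eff is None:
            continue
        gos = frozenset(g for g in row.get(col, "").split(";") if g)
        if gos:
            yield eff[0], eff[1], gos


def cooc_dataset(
    f1_rows: Iterable[Mapping[str, str]],
    f2_rows: Iterable[Mapping[str, str]],
    params: NetworkParams | None = None,
    go_names: Mapping[str, str] | None = None,
) -> list[CoocRecord]:
    """All OG-GO co-occurrences over two species with per-species counts.

    A gene with effective OG *o* and *k* distinct GO ids of the chosen
    domain contributes one count to each of the *k* (o, go) pairs of its
    species. Pairs seen in only one species carry 0 for the other. The
    result is sorted by (og_id, go_id).
    """
    p = params or NetworkParams()
    go_names = go_names or {}
    counts: dict[tuple[str, str], list[int]] = {}
    og_desc: dict[str, str] = {}
    for species_idx, rows in enumerate((f1_rows, f2_rows)):
        for og, desc, gos in _gene_pairs(rows, p):
            if og not in og_desc and desc:
                og_desc[og] = desc
            for go in gos:
                counts.setdefault((og, go), [0, 0])[species_idx] += 1
    return [
        CoocRecord(
            og_id=og,
            og_desc=og_desc.get(og, ""),
            go_id=go,
            go_desc=go_names.get(go, ""),
            count_f1=c[0],
            count_f2=c[1],
        )
        for (og, go), c in sorted(counts.items())
    ]


def apply_log_threshold(
    cooc: Iterable[CoocRecord], threshold: float, keep: str = "diff"
) -> list[CoocRecord]:
    """Filter pairs by |ln(c1+1) - ln(c2+1)| against ``threshold``.

    ``diff`` keeps pairs at or above the threshold (T=0 keeps everything);
    ``similar`` keeps pairs at or below it. Counts stay absolute.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if keep == "diff":
        return [r for r in cooc if r.log_difference() >= threshold]
    if keep == "similar":
        return [r for r in cooc if r.log_difference() <= threshold]
    raise ValueError("keep must be 'diff' or 'similar'")


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def _og_label(rec: CoocRecord, p: NetworkParams) -> str:
    text = rec.og_desc if rec.og_desc else rec.og_id
    return "odb:" + text[: p.og_label_len]


def _go_label(rec: CoocRecord, p: NetworkParams) -> str:
    text = rec.go_desc if rec.go_desc else rec.go_id
    return text[: p.go_label_len]


def build_graph(
    cooc: Sequence[CoocRecord], seed_go: str, params: NetworkParams | None = None
) -> nx.MultiDiGraph:
    """Seeded bipartite OG->GO network around one GO term.

    Candidate OGs are those paired with ``seed_go``; candidate GO terms are
    all terms paired with any candidate OG. The node count is capped at
    ``node_cap`` (seed GO always retained, then OGs by total count, then GO
    terms by connected total count; ties broken by id). With label keying,
    OGs whose truncated labels collide share one node, producing parallel
    edges. Edges are labelled ``f1:<c1>, f2:<c2>``.
    """
    p = params or NetworkParams()
    by_go: dict[str, list[CoocRecord]] = {}
    by_og: dict[str, list[CoocRecord]] = {}
    for rec in cooc:
        by_go.setdefault(rec.go_id, []).append(rec)
        by_og.setdefault(rec.og_id, []).append(rec)
    if seed_go not in by_go:
        raise ValueError(f"seed GO term {seed_go!r} absent from the co-occurrence table")

    candidate_ogs = sorted({rec.og_id for rec in by_go[seed_go]})
    candidate_records = [rec for og in candidate_ogs for rec in by_og[og]]

    og_total = {og: 0 for og in candidate_ogs}
    go_total: dict[str, int] = {}
    for rec in candidate_records:
        og_total[rec.og_id] += rec.count_f1 + rec.count_f2
        go_total[rec.go_id] = go_total.get(rec.go_id, 0) + rec.count_f1 + rec.count_f2

    og_meta = {og: next(r for r in by_og[og]) for og in candidate_ogs}
    go_meta = {go: next(r for r in recs) for go, recs in by_go.items()}

    def og_key(og: str) -> tuple[str, str]:
        if p.key_mode == "id":
            return ("OG", og)
        return ("OG", _og_label(og_meta[og], p))

    def go_key(go: str) -> tuple[str, str]:
        if p.key_mode == "id":
            return ("GO", go)
        return ("GO", _go_label(go_meta[go], p))

    # node selection under the cap: seed GO, then OGs, then other GO terms
    node_keys: set[tuple[str, str]] = {go_key(seed_go)}
    kept_ogs: set[str] = set()
    for og in sorted(candidate_ogs, key=lambda o: (-og_total[o], o)):
        key = og_key(og)
        if key in node_keys or len(node_keys) < p.node_cap:
            node_keys.add(key)
            kept_ogs.add(og)
    kept_gos: set[str] = {seed_go}
    candidate_gos = sorted(
        {rec.go_id for rec in candidate_records if rec.og_id in kept_ogs}
    )
    for go in sorted(candidate_gos, key=lambda g: (-go_total[g], g)):
        key = go_key(go)
        if key in node_keys or len(node_keys) < p.node_cap:
            node_keys.add(key)
            kept_gos.add(go)

    graph = nx.MultiDiGraph(seed_go=seed_go, domain=p.domain)
    for og in sorted(kept_ogs):
        key = og_key(og)
        if key not in graph:
            graph.add_node(key, kind="OG", label=key[1])
    seed_key = go_key(seed_go)
    graph.add_node(seed_key, kind="GO", label=seed_key[1], seed=True)
    for go in sorted(kept_gos):
        key = go_key(go)
        if key not in graph:
            graph.add_node(key, kind="GO", label=key[1])
    for rec in candidate_records:
        if rec.og_id in kept_ogs and rec.go_id in kept_gos:
            graph.add_edge(
                og_key(rec.og_id),
                go_key(rec.go_id),
                label=f"f1:{rec.count_f1}, f2:{rec.count_f2}",
                og_id=rec.og_id,
                go_id=rec.go_id,
                count_f1=rec.count_f1,
                count_f2=rec.count_f2,
            )
    return graph


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

COOC_COLUMNS = ("og_id", "og_desc", "go_id", "go_desc", "counts_f1", "counts_f2")


def write_cooc_tsv(cooc: Iterable[CoocRecord], out: str | IO[str]) -> None:
    close = False
    if isinstance(out, str):
        out = open(out, "w", encoding="utf-8", newline="")
        close = True
    try:
        w = csv.writer(out, delimiter="\t", lineterminator="\n")
        w.writerow(COOC_COLUMNS)
        for r in cooc:
            w.writerow([r.og_id, r.og_desc, r.go_id, r.go_desc, r.count_f1, r.count_f2])
    finally:
        if close:
            out.close()


def read_cooc_tsv(source: str | IO[str]) -> list[CoocRecord]:
    close = False
    if isinstance(source, str):
        source = open(source, encoding="utf-8")
        close = True
    try:
        reader = csv.reader(source, delimiter="\t")
        header = next(reader, None)
        records = []
        for row in reader:
            if not row:
                continue
            records.append(
                CoocRecord(row[0], row[1], row[2], row[3], int(row[4]), int(row[5]))
            )
        return records
    finally:
        if close:
            source.close()


def read_go_names_tsv(source: str | IO[str]) -> dict[str, str]:
    """Read a 2-column GO id -> name table."""
    close = False
    if isinstance(source, str):
        source = open(source, encoding="utf-8")
        close = True
    try:
        return {
            row[0]: row[1]
            for row in csv.reader(source, delimiter="\t")
            if len(row) >= 2 and not row[0].startswith("#")
        }
    finally:
        if close:
            source.close()


def export_graph(
    graph: nx.MultiDiGraph, out_dir: str | Path, basename: str = "network",
    graphml: bool = False,
) -> dict[str, Path]:
    """Write nodes/edges TSVs and a JSON document (optionally GraphML)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    nodes_path = out / f"{basename}_nodes.tsv"
    with open(nodes_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["node_key", "kind", "label"])
        for key, data in sorted(graph.nodes(data=True)):
            w.writerow([f"{key[0]}|{key[1]}", data["kind"], data["label"]])
    paths["nodes"] = nodes_path

    edges_path = out / f"{basename}_edges.tsv"
    with open(edges_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["src", "dst", "label", "og_id", "go_id"])
        for u, v, data in sorted(
            graph.edges(data=True), key=lambda e: (e[0], e[1], e[2]["og_id"], e[2]["go_id"])
        ):
            w.writerow([f"{u[0]}|{u[1]}", f"{v[0]}|{v[1]}", data["label"], data["og_id"], data["go_id"]])
    paths["edges"] = edges_path

    doc = {
        "seed_go": graph.graph.get("seed_go"),
        "domain": graph.graph.get("domain"),
        "nodes": [
            {"key": f"{k[0]}|{k[1]}", "kind": d["kind"], "label": d["label"]}
            for k, d in sorted(graph.nodes(data=True))
        ],
        "edges": [
            {
                "src": f"{u[0]}|{u[1]}",
                "dst": f"{v[0]}|{v[1]}",
                "label": d["label"],
                "count_f1": d["count_f1"],
                "count_f2": d["count_f2"],
            }
            for u, v, d in sorted(
                graph.edges(data=True),
                key=lambda e: (e[0], e[1], e[2]["og_id"], e[2]["go_id"]),
            )
        ],
    }
    json_path = out / f"{basename}.json"
    json_path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    paths["json"] = json_path

    if graphml:
        flat = nx.MultiDiGraph()
        for k, d in graph.nodes(data=True):
            flat.add_node(f"{k[0]}|{k[1]}", **{kk: vv for kk, vv in d.items()})
        for u, v, d in graph.edges(data=True):
            flat.add_edge(f"{u[0]}|{u[1]}", f"{v[0]}|{v[1]}", **d)
        gml_path = out / f"{basename}.graphml"
        nx.write_graphml(flat, gml_path)
        paths["graphml"] = gml_path
    return paths
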