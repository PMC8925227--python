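"""Assembly and export of the lncRNA-mediated regulatory network.

Typed nodes (mirna, lncrna, gene, go_term, pathway) and directed typed
edges (mirna_targets_lnc, lnc_targets_gene, gene_annotated_term) are
assembled from the upstream DE, common-target, miRNA-link and enrichment
results.  Regulation direction is stored as a node attribute together with
the conventional colour encoding (up -> red, down -> green); annotation
terms enter the network at p < 0.05.  Only nodes with at least one edge are
kept.  Exports (SIF, GraphML, node/edge TSV) are byte-deterministic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentResult
from .targeting import CommonTargetSet

__all__ = ["build_network", "export_network", "NODE_TYPES", "EDGE_TYPES"]

NODE_TYPES = ("mirna", "lncrna", "gene", "go_term", "pathway")
EDGE_TYPES = ("mirna_targets_lnc", "lnc_targets_gene", "gene_annotated_term")

_COLORS = {"up": "red", "down": "green", "none": "black"}


def _regulation(flag: str) -> str:
    return flag if flag in ("up", "down") else "none"


def build_network(
    delncs: Mapping[str, str],
    dems: Mapping[str, str],
    common: CommonTargetSet,
    mirna_links: pd.DataFrame,
    enrichment: Sequence[EnrichmentResult],
    term_map: pd.DataFrame | None = None,
    term_p: float = 0.05,
) -> nx.DiGraph:
    """Build the regulator -> regulated network.

    ``delncs``/``dems`` map feature id -> DE direction ("up"/"down").
    ``mirna_links`` is the DEM->DElncRNA link table; ``term_map`` (gene_id,
    term_id, namespace, name) connects common-target genes to terms whose
    enrichment p-value is below ``term_p``.  Nodes without edges are
    dropped; a link or annotation referencing an unknown id raises.
    """
    g = nx.DiGraph()
    edges: list[tuple[str, str, dict]] = []

    # lncRNA -> gene edges from the common-target supporting links
    for gene in common.gene_ids:
        member = common.members[gene]
        by_lnc: dict[str, set[str]] = {}
        for link in member["cis"]:
            by_lnc.setdefault(link.lnc_id, set()).add("cis")
        for link in member["trans"]:
            by_lnc.setdefault(link.lnc_id, set()).add("trans")
        for lnc_id in sorted(by_lnc):
            if lnc_id not in delncs:
                raise ValueError(f"target link references unknown DElncRNA {lnc_id!r}")
            modes = by_lnc[lnc_id]
            attrs = {
                "edge_type": "lnc_targets_gene",
                "mode": "common" if len(modes) == 2 else next(iter(modes)),
            }
            for link in member["cis"]:
                if link.lnc_id == lnc_id:
                    attrs["distance"] = int(link.distance)
                    break
            for link in member["trans"]:
                if link.lnc_id == lnc_id:
                    attrs["r"] = float(link.r)
                    break
            edges.append((lnc_id, gene, attrs))

    # miRNA -> lncRNA edges
    if len(mirna_links):
        for row in mirna_links.sort_values(["mirna_id", "lnc_id"]).itertuples():
            if row.mirna_id not in dems:
                raise ValueError(f"link references unknown DEM {row.mirna_id!r}")
            if row.lnc_id not in delncs:
                raise ValueError(f"link references unknown DElncRNA {row.lnc_id!r}")
            edges.append(
                (
                    row.mirna_id,
                    row.lnc_id,
                    {
                        "edge_type": "mirna_targets_lnc",
                        "expectation": float(row.expectation),
                    },
                )
            )

    # gene -> term edges for significantly enriched terms
    sig_terms = {r.term_id: r for r in enrichment if r.pvalue < term_p}
    if term_map is not None and sig_terms:
        sub = term_map[
            term_map["term_id"].isin(sig_terms)
            & term_map["gene_id"].isin(set(common.gene_ids))
        ]
        for row in sub.sort_values(["gene_id", "term_id"]).itertuples():
            edges.append(
                (
                    row.gene_id,
                    row.term_id,
                    {"edge_type": "gene_annotated_term"},
                )
            )

    # nodes: only endpoints of the collected edges (isolated nodes dropped)
    used = {e[0] for e in edges} | {e[1] for e in edges}
    for lnc_id in sorted(set(delncs) & used):
        reg = _regulation(delncs[lnc_id])
        g.add_node(lnc_id, node_type="lncrna", regulation=reg, color=_COLORS[reg])
    for mid in sorted(set(dems) & used):
        reg = _regulation(dems[mid])
        g.add_node(mid, node_type="mirna", regulation=reg, color=_COLORS[reg])
    for gene in sorted(set(common.gene_ids) & used):
        reg = _regulation(common.members[gene]["de_flag"])
        g.add_node(gene, node_type="gene", regulation=reg, color="black")
    for term_id in sorted(set(sig_terms) & used):
        res = sig_terms[term_id]
        g.add_node(
            term_id,
            node_type="pathway" if res.namespace == "pathway" else "go_term",
            regulation="none",
            color="blue" if res.namespace != "pathway" else "green",
            pvalue=float(res.pvalue),
        )

    for src, tgt, attrs in edges:
        if src not in g or tgt not in g:
            missing = src if src not in g else tgt
            raise ValueError(f"edge references unknown node {missing!r}")
        g.add_edge(src, tgt, **attrs)

    validate_network(g)
    return g


def validate_network(g: nx.DiGraph) -> None:
    """Referential/typing integrity checks, run on every build."""
    expected = {
        "mirna_targets_lnc": ("mirna", "lncrna"),
        "lnc_targets_gene": ("lncrna", "gene"),
        "gene_annotated_term": ("gene", ("go_term", "pathway")),
    }
    for node, data in g.nodes(data=True):
        if data.get("node_type") not in NODE_TYPES:
            raise ValueError(f"node {node!r} has invalid type {data.get('node_type')!r}")
    for u, v, data in g.edges(data=True):
        et = data.get("edge_type")
        if et not in expected:
            raise ValueError(f"edge ({u}, {v}) has invalid type {et!r}")
        src_t, tgt_t = expected[et]
        if g.nodes[u]["node_type"] != src_t:
            raise ValueError(f"edge ({u}, {v}): source type mismatch for {et}")
        tgt_ok = (
            g.nodes[v]["node_type"] in tgt_t
            if isinstance(tgt_t, tuple)
            else g.nodes[v]["node_type"] == tgt_t
        )
        if not tgt_ok:
            raise ValueError(f"edge ({u}, {v}): target type mismatch for {et}")


def export_network(
    g: nx.DiGraph,
    formats: Iterable[str],
    outdir: str | Path,
    prefix: str = "network",
) -> dict[str, Path]:
    """Write the network as SIF and/or GraphML and/or node+edge TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for fmt in formats:
        if fmt == "sif":
            path = outdir / f"{prefix}.sif"
            lines = [
                f"{u}\t{d['edge_type']}\t{v}"
                for u, v, d in sorted(g.edges(data=True))
            ]
            path.write_text("".join(line + "\n" for line in lines))
            written["sif"] = path
        elif fmt == "graphml":
            path = outdir / f"{prefix}.graphml"
            h = nx.DiGraph()
            h.add_nodes_from(sorted(g.nodes(data=True)))
            h.add_edges_from(sorted(g.edges(data=True)))
            nx.write_graphml(h, path, named_key_ids=True)
            written["graphml"] = path
        elif fmt == "tsv":
            npath = outdir / f"{prefix}_nodes.tsv"
            epath = outdir / f"{prefix}_edges.tsv"
            nodes = pd.DataFrame(
                [
                    {
                        "id": n,
                        "node_type": d["node_type"],
                        "regulation": d.get("regulation", "none"),
                        "color": d.get("color", ""),
                        "pvalue": d.get("pvalue", ""),
                    }
                    for n, d in sorted(g.nodes(data=True))
                ],
                columns=["id", "node_type", "regulation", "color", "pvalue"],
            )
            edges = pd.DataFrame(
                [
                    {
                        "source": u,
                        "target": v,
                        "edge_type": d["edge_type"],
                        "mode": d.get("mode", ""),
                        "expectation": d.get("expectation", ""),
                        "r": d.get("r", ""),
                        "distance": d.get("distance", ""),
                    }
                    for u, v, d in sorted(g.edges(data=True))
                ],
                columns=["source", "target", "edge_type", "mode",
                         "expectation", "r", "distance"],
            )
            nodes.to_csv(npath, sep="\t", index=False)
            edges.to_csv(epath, sep="\t", index=False)
            written["nodes_tsv"] = npath
            written["edges_tsv"] = epath
        else:
            raise ValueError(f"unknown export format {fmt!r}")
    return written
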