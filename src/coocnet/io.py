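"""Tabular and graph output writers.

All writers are atomic (write to a temp file, then rename), use UTF-8, and
keep a stable column and row order so identical runs produce byte-identical
outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .reconstruction import extract_entity_subnetworks

PUBMED_URL = "https://pubmed.ncbi.nlm.nih.gov/{pmid}/"

EDGE_COLUMNS = ["source", "target", "type_pair", "X", "p", "padj", "w", "pmids"]
NODE_COLUMNS = ["entity", "type", "subgraph_id", "b", "d", "W"]


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    tmp.replace(path)


def _edge_frame(graph: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v in sorted(map(tuple, map(sorted, graph.edges()))):
        data = graph.edges[u, v]
        ku = graph.nodes[u].get("kind", "gene")
        kv = graph.nodes[v].get("kind", "gene")
        rows.append(
            {
                "source": u,
                "target": v,
                "type_pair": "-".join(sorted((ku, kv))),
                "X": data.get("X", ""),
                "p": data.get("p", ""),
                "padj": data.get("padj", ""),
                "w": data.get("w", ""),
                "pmids": data.get("pmids", ""),
            }
        )
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def _node_frame(graph: nx.Graph) -> pd.DataFrame:
    component_of: dict = {}
    for i, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0] if c else "")
    ):
        for node in comp:
            component_of[node] = i
    rows = []
    for node in sorted(graph.nodes()):
        data = graph.nodes[node]
        rows.append(
            {
                "entity": node,
                "type": data.get("kind", "gene"),
                "subgraph_id": component_of.get(node, ""),
                "b": data.get("b", ""),
                "d": data.get("d", ""),
                "W": data.get("W", ""),
            }
        )
    return pd.DataFrame(rows, columns=NODE_COLUMNS)


def export_network_tables(graph: nx.Graph, out_dir: str | Path, tag: str = "network") -> list[Path]:
    """nodes.tsv / edges.tsv plus gene-only and mesh-only variants + GraphML."""
    out_dir = Path(out_dir)
    written: list[Path] = []
    gene_net, mesh_net = extract_entity_subnetworks(graph)
    for name, g in (
        (tag, graph),
        (f"{tag}_genes", gene_net),
        (f"{tag}_mesh", mesh_net),
    ):
        nodes_path = out_dir / f"{name}_nodes.tsv"
        edges_path = out_dir / f"{name}_edges.tsv"
        _atomic_write(nodes_path, _node_frame(g).to_csv(sep="\t", index=False))
        _atomic_write(edges_path, _edge_frame(g).to_csv(sep="\t", index=False))
        written += [nodes_path, edges_path]
    graphml_path = out_dir / f"{tag}.graphml"
    graphml_path.parent.mkdir(parents=True, exist_ok=True)
    tmp = graphml_path.with_name(graphml_path.name + ".tmp")
    nx.write_graphml(graph, tmp)
    tmp.replace(graphml_path)
    written.append(graphml_path)
    return written


def load_network_tables(nodes_path: str | Path, edges_path: str | Path) -> nx.Graph:
    """Reload a network exported by :func:`export_network_tables`."""
    nodes = pd.read_csv(nodes_path, sep="\t", dtype={"entity": str})
    edges = pd.read_csv(edges_path, sep="\t", dtype={"source": str, "target": str, "pmids": str})
    graph = nx.Graph()
    for row in nodes.itertuples():
        attrs = {"kind": row.type}
        for name in ("b", "d", "W"):
            value = getattr(row, name)
            if pd.notna(value) and value != "":
                attrs[name] = float(value)
        graph.add_node(row.entity, **attrs)
    for row in edges.itertuples():
        graph.add_edge(
            row.source,
            row.target,
            X=int(row.X),
            p=float(row.p),
            padj=float(row.padj),
            w=float(row.w),
            wt=1.0 - float(row.w),
            pmids="" if pd.isna(row.pmids) else str(row.pmids),
        )
    return graph


def export_literature_links(graph: nx.Graph, out_dir: str | Path, tag: str = "") -> Path:
    """Per edge: source, target, semicolon-joined PubMed URLs, sorted rows."""
    out_dir = Path(out_dir)
    rows = []
    for u, v in sorted(map(tuple, map(sorted, graph.edges()))):
        pmids = [p for p in graph.edges[u, v].get("pmids", "").split(";") if p]
        rows.append(
            {
                "source": u,
                "target": v,
                "links": ";".join(PUBMED_URL.format(pmid=p) for p in pmids),
            }
        )
    frame = pd.DataFrame(rows, columns=["source", "target", "links"])
    prefix = f"{tag}_" if tag else ""
    path = out_dir / f"{prefix}Complete_edges_literature_links.tsv"
    _atomic_write(path, frame.to_csv(sep="\t", index=False))
    return path


def write_manifest(manifest: dict, out_dir: str | Path) -> Path:
    path = Path(out_dir) / "run_manifest.json"
    _atomic_write(path, json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def export_run(result, config, out_dir: str | Path) -> None:
    """Dump every iteration's artifacts plus the run manifest."""
    out_dir = Path(out_dir)
    for it in result.iterations:
        it_dir = out_dir / f"iteration_{it.index}"
        export_network_tables(it.network, it_dir)
        export_literature_links(it.network, it_dir)
        _atomic_write(
            it_dir / "queries.txt",
            "".join(
                f"iteration_{it.index}\tgraphlet_{i}\t{q}\n"
                for i, q in enumerate(it.queries)
            ),
        )
    write_manifest(result.manifest(config), out_dir)
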