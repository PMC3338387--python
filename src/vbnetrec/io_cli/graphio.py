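"""Network graph export: edge-list TSV (lossless), GraphML and SIF."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = ["write_graph", "read_edge_tsv"]

_FORMATS = ("edge-tsv", "graphml", "sif")


def write_graph(graph: nx.Graph, path: str | Path, fmt: str = "edge-tsv") -> None:
    """Write the typed, scored graph. 'edge-tsv' round-trips losslessly;
    GraphML carries role/score/provenance attributes; SIF uses the
    non-directed relation token 'nd'."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "edge-tsv":
        rows = [
            {
                "node_a": a,
                "node_b": b,
                "role_a": graph.nodes[a].get("role", ""),
                "role_b": graph.nodes[b].get("role", ""),
                "p_hat_sym": d.get("p_hat_sym", ""),
                "provenance": d.get("provenance", ""),
            }
            for a, b, d in sorted(graph.edges(data=True))
        ]
        df = pd.DataFrame(rows, columns=["node_a", "node_b", "role_a", "role_b",
                                         "p_hat_sym", "provenance"])
        # isolated vertices (e.g. edge-less phenotypes) kept on comment lines
        isolated = sorted(n for n in graph.nodes if graph.degree(n) == 0)
        with path.open("w") as fh:
            for node in isolated:
                fh.write(f"#node\t{node}\t{graph.nodes[node].get('role', '')}\n")
            df.to_csv(fh, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        with path.open("w") as fh:
            for a, b in sorted(graph.edges()):
                fh.write(f"{a}\tnd\t{b}\n")
            for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
                fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}; choose from {_FORMATS}")


def read_edge_tsv(path: str | Path) -> nx.Graph:
    """Inverse of write_graph(..., 'edge-tsv')."""
    path = Path(path)
    g = nx.Graph()
    header_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#node\t"):
                _, node, role = line.rstrip("\n").split("\t")
                g.add_node(node, role=role)
            else:
                header_lines.append(line)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(header_lines)), sep="\t")
    for row in df.itertuples(index=False):
        g.add_edge(
            str(row.node_a),
            str(row.node_b),
            p_hat_sym=float(row.p_hat_sym),
            provenance=str(row.provenance),
        )
        g.nodes[str(row.node_a)]["role"] = str(row.role_a)
        g.nodes[str(row.node_b)]["role"] = str(row.role_b)
    return g
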