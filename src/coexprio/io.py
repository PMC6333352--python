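"""Plain-text readers/writers shared by every pipeline stage.

All tabular artifacts are tab-separated with a header row; gene sets use the
GMT convention (name, description, then one gene per column); graphs are
three-column edge lists (gene_a, gene_b, source).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

_FLOAT_FMT = "%.10g"


def read_expression(path) -> pd.DataFrame:
    """Genes x samples matrix; first column holds gene symbols."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_edge_table(path) -> pd.DataFrame:
    """Edge list with columns gene_a, gene_b and optional source."""
    df = pd.read_csv(path, sep="\t")
    if "source" not in df.columns:
        df["source"] = Path(str(path)).stem
    return df


def write_graph(graph: nx.Graph, path) -> None:
    rows = [
        (a, b, ";".join(sorted(data.get("sources", ["unknown"]))))
        for a, b, data in sorted(graph.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1])))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "source"]).to_csv(path, sep="\t", index=False)


def read_seeds(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_seeds(seeds, path) -> None:
    with open(path, "w") as fh:
        for s in seeds:
            fh.write(f"{s}\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = descriptions.get(name, name)
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
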