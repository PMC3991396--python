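"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices and design tables travel as TSV, gene sets as GMT,
networks as GraphML plus edge-list TSV, ground truth and manifests as JSON.
All floats are written with a fixed format so identical runs produce
byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import ExpressionMatrix

FLOAT_FMT = "%.10g"


def write_expression_tsv(matrix: ExpressionMatrix, expr_path, design_path) -> None:
    """Write genes-in-rows expression TSV and the sample annotation TSV."""
    matrix.values.to_csv(expr_path, sep="\t", index_label="gene", float_format=FLOAT_FMT)
    matrix.design.to_csv(design_path, sep="\t", index_label="sample_id")


def read_expression_tsv(expr_path, design_path) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    design.index = design.index.astype(str)
    design["is_baseline"] = design["is_baseline"].astype(bool)
    return ExpressionMatrix(values, design)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: ``name <tab> description <tab> member...`` per line.

    Duplicate set names are an error; blank lines are skipped.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: GMT needs >= 2 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate gene-set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([str(name), description, *map(str, genes)]) + "\n")


def write_edge_list(graph: nx.Graph, path, weight: str = "weight") -> None:
    """Edge-list TSV: source, target, weight — sorted for reproducibility."""
    rows = []
    for u, v, data in graph.edges(data=True):
        a, b = sorted((str(u), str(v)))
        rows.append((a, b, data.get(weight, 1.0)))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    """GraphML export; container-valued attributes are flattened to strings
    (GraphML supports scalars only)."""
    out = graph.copy()
    for holder in [out.graph, *(d for _, d in out.nodes(data=True)), *(d for _, _, d in out.edges(data=True))]:
        for key, value in list(holder.items()):
            if isinstance(value, (list, tuple, set, frozenset, dict)):
                holder[key] = ",".join(map(str, value)) if not isinstance(value, dict) else str(value)
    nx.write_graphml(out, path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
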