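"""Readers and writers for the on-disk formats.

Tables are wide UTF-8 TSV: header row ``gene`` followed by sample ids, one
row per gene.  Blank cells mean "not assessed" and become NaN.  Pathways are
a small JSON dialect (nodes / edges / families); gene lists are plain text,
one HUGO symbol per line with ``#`` comments.  Gene symbols are matched
case-sensitively and never aliased.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CNVTable,
    DataType,
    ExpressionMatrix,
    FlagTable,
    GeneList,
    Pathway,
    PathwayEdge,
    PathwayNode,
    ValidationError,
)

_TRUE_TOKENS = {"1", "true"}
_FALSE_TOKENS = {"0", "false"}


def _read_wide_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-samples TSV as strings, preserving blanks as NaN."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for s in header:  # pandas mangles duplicate columns, so check the raw header
        if s in seen:
            raise ValidationError(f"{path.name}: duplicate sample id {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False,
                     na_values=[""])
    df.columns = header
    dup_genes = [g for g, c in df.index.value_counts().items() if c > 1]
    if dup_genes:
        raise ValidationError(f"{path.name}: duplicate gene symbol {dup_genes[0]!r}")
    return df


def _to_numeric(df: pd.DataFrame, path: Path, *, nonneg: bool) -> pd.DataFrame:
    out = np.full(df.shape, np.nan)
    raw = df.to_numpy(dtype=object)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path.name}: non-numeric cell {cell!r} at gene "
                    f"{df.index[i]!r}, sample {df.columns[j]!r}") from None
            if not math.isfinite(v):
                raise ValidationError(
                    f"{path.name}: non-finite cell {cell!r} at gene "
                    f"{df.index[i]!r}, sample {df.columns[j]!r}")
            if nonneg and v < 0:
                raise ValidationError(
                    f"{path.name}: negative value {v} at gene "
                    f"{df.index[i]!r}, sample {df.columns[j]!r}")
            out[i, j] = v
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a genes-by-samples expression TSV (e.g. RPKM values)."""
    df = _read_wide_tsv(path)
    return ExpressionMatrix(_to_numeric(df, Path(path), nonneg=True))


def read_cnv_table(path: str | Path) -> CNVTable:
    """Read a genes-by-samples absolute copy-number TSV."""
    df = _read_wide_tsv(path)
    return CNVTable(_to_numeric(df, Path(path), nonneg=True))


def read_flag_table(path: str | Path, data_type: DataType | str) -> FlagTable:
    """Read a binary event TSV; accepts 0/1 and case-insensitive true/false."""
    path = Path(path)
    df = _read_wide_tsv(path)
    out = np.full(df.shape, np.nan)
    raw = df.to_numpy(dtype=object)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                continue
            tok = str(cell).strip().lower()
            if tok == "":
                continue
            if tok in _TRUE_TOKENS:
                out[i, j] = 1.0
            elif tok in _FALSE_TOKENS:
                out[i, j] = 0.0
            else:
                raise ValidationError(
                    f"{path.name}: invalid flag token {cell!r} at gene "
                    f"{df.index[i]!r}, sample {df.columns[j]!r} "
                    "(expected 0/1 or true/false)")
    return FlagTable(DataType(data_type), pd.DataFrame(out, index=df.index, columns=df.columns))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a genes-by-samples table in the wide TSV dialect."""
    df.to_csv(path, sep="\t", index_label="gene", na_rep="")


def read_pathway(path: str | Path) -> Pathway:
    """Read and validate a pathway JSON file.

    Expected shape::

        {"name": str, "category": [str], "nodes": [{"id", "label"}],
         "edges": [{"source", "target", "directed"}],
         "families": {familyId: [memberId, ...]}}
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return pathway_from_dict(doc, origin=path.name)


def pathway_from_dict(doc: dict, origin: str = "<dict>") -> Pathway:
    if not isinstance(doc, dict):
        raise ValidationError(f"{origin}: pathway document must be a JSON object")
    for key, typ in (("name", str), ("nodes", list)):
        if key not in doc or not isinstance(doc[key], typ):
            raise ValidationError(f"{origin}: missing or malformed {key!r}")
    nodes = []
    for nd in doc["nodes"]:
        if not isinstance(nd, dict) or "id" not in nd:
            raise ValidationError(f"{origin}: node entries need an 'id'")
        nodes.append(PathwayNode(str(nd["id"]), str(nd.get("label", nd["id"]))))
    edges = []
    for ed in doc.get("edges", []):
        if not isinstance(ed, dict) or "source" not in ed or "target" not in ed:
            raise ValidationError(f"{origin}: edge entries need 'source' and 'target'")
        edges.append(PathwayEdge(str(ed["source"]), str(ed["target"]),
                                 bool(ed.get("directed", True))))
    families = {str(f): [str(m) for m in ms]
                for f, ms in dict(doc.get("families", {})).items()}
    category = [str(c) for c in doc.get("category", [])]
    return Pathway(name=str(doc["name"]), category=category, nodes=nodes,
                   edges=edges, families=families)


def pathway_to_dict(pathway: Pathway) -> dict:
    return {
        "name": pathway.name,
        "category": list(pathway.category),
        "nodes": [{"id": n.id, "label": n.label} for n in pathway.nodes],
        "edges": [{"source": e.source, "target": e.target, "directed": e.directed}
                  for e in pathway.edges],
        "families": {f: list(ms) for f, ms in pathway.families.items()},
    }


def write_pathway(pathway: Pathway, path: str | Path) -> None:
    """Write a pathway so that ``read_pathway`` reproduces it exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(pathway_to_dict(pathway), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_gene_list(path: str | Path) -> GeneList:
    """Read a plain-text gene list (one symbol per line, '#' comments)."""
    path = Path(path)
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line)
    if not genes:
        raise ValidationError(f"{path.name}: gene list is empty after removing comments")
    return GeneList(name=path.stem, genes=genes)
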