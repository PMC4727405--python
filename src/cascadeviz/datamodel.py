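"""Core in-memory containers for cohort genomics tables and pathway graphs.

A cohort is a set of per-sample tables (expression, binary event flags,
copy number) joined only by sample identifier; a pathway is a small directed
gene graph, optionally with collapsed gene-family nodes.  Tables are stored
as pandas DataFrames (genes as rows, samples as columns) with ``NaN`` for
"not assessed", which downstream frequency denominators exclude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd


class DataType(str, Enum):
    """Binary event classes a cohort may carry per gene and sample."""

    MUTATION = "mutation"
    DAMAGING_SNV = "damaging_snv"
    SPLICING = "splicing"
    INDEL = "indel"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


FLAG_DATA_TYPES = tuple(DataType)


class ValidationError(ValueError):
    """Raised when an on-disk table or pathway violates a structural invariant."""


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``level`` is ``"error"`` or ``"warning"``."""

    level: str
    message: str

    def __str__(self) -> str:
        return f"[{self.level}] {self.message}"


def _check_unique(labels: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {kind} {lab!r}")
        seen.add(lab)


def _check_matrix(values: pd.DataFrame, *, nonneg: bool, kind: str) -> None:
    _check_unique(values.index, f"gene in {kind}")
    _check_unique(values.columns, f"sample in {kind}")
    arr = values.to_numpy(dtype=float)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            v = arr[i, j]
            if math.isnan(v):
                continue
            if math.isinf(v):
                raise ValidationError(
                    f"non-finite value in {kind} at gene {values.index[i]!r}, "
                    f"sample {values.columns[j]!r}"
                )
            if nonneg and v < 0:
                raise ValidationError(
                    f"negative value {v} in {kind} at gene {values.index[i]!r}, "
                    f"sample {values.columns[j]!r}"
                )


@dataclass
class ExpressionMatrix:
    """Gene-by-sample numeric expression (typically RPKM); NaN = missing."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_matrix(self.values, nonneg=True, kind="expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class FlagTable:
    """Gene-by-sample binary event table; entries 0.0, 1.0 or NaN (missing)."""

    data_type: DataType
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        self.data_type = DataType(self.data_type)
        self.flags = self.flags.astype(float)
        _check_matrix(self.flags, nonneg=True, kind=f"{self.data_type} flag table")
        arr = self.flags.to_numpy(dtype=float)
        bad = [(i, j) for i in range(arr.shape[0]) for j in range(arr.shape[1])
               if not math.isnan(arr[i, j]) and arr[i, j] not in (0.0, 1.0)]
        if bad:
            i, j = bad[0]
            raise ValidationError(
                f"non-binary value {arr[i, j]} in {self.data_type} flag table at "
                f"gene {self.flags.index[i]!r}, sample {self.flags.columns[j]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.flags.index)

    @property
    def samples(self) -> list[str]:
        return list(self.flags.columns)


@dataclass
class CNVTable:
    """Gene-by-sample absolute copy number (diploid neutral = 2); NaN = missing."""

    copy_number: pd.DataFrame

    def __post_init__(self) -> None:
        self.copy_number = self.copy_number.astype(float)
        _check_matrix(self.copy_number, nonneg=True, kind="CNV table")

    @property
    def genes(self) -> list[str]:
        return list(self.copy_number.index)

    @property
    def samples(self) -> list[str]:
        return list(self.copy_number.columns)


@dataclass
class CohortDataset:
    """All per-sample tables of one cohort under a master sample registry.

    Tables are linked only by sample identifier; no data type is mandatory.
    If ``samples`` is omitted the registry is the union of table samples.
    """

    name: str
    samples: list[str] = field(default_factory=list)
    expression: ExpressionMatrix | None = None
    flag_tables: dict[DataType, FlagTable] = field(default_factory=dict)
    cnv: CNVTable | None = None

    def __post_init__(self) -> None:
        self.flag_tables = {DataType(k): v for k, v in self.flag_tables.items()}
        if not self.samples:
            seen: list[str] = []
            for tab in self._tables():
                for s in tab.columns:
                    if s not in seen:
                        seen.append(s)
            self.samples = seen

    def _tables(self) -> list[pd.DataFrame]:
        out = []
        if self.expression is not None:
            out.append(self.expression.values)
        for ft in self.flag_tables.values():
            out.append(ft.flags)
        if self.cnv is not None:
            out.append(self.cnv.copy_number)
        return out

    @property
    def n_tables(self) -> int:
        return len(self._tables())

    def genes(self) -> list[str]:
        """Union of gene symbols across all tables, first-seen order."""
        seen: list[str] = []
        for tab in self._tables():
            for g in tab.index:
                if g not in seen:
                    seen.append(g)
        return seen


@dataclass(frozen=True)
class PathwayNode:
    id: str
    label: str
    is_family: bool = False

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError(f"node {self.id!r} has an empty label")


@dataclass(frozen=True)
class PathwayEdge:
    source: str
    target: str
    directed: bool = True


@dataclass
class Pathway:
    """Directed gene-interaction graph with optional collapsed family nodes.

    ``families`` maps a family node id (e.g. ``"JAK"``) to its member node
    ids (``JAK1``, ``JAK2`` ...).  Family nodes stand in for their members in
    the collapsed main view; members carry their own statistics when the
    family is expanded.  Cycles are legal (signalling loops exist).
    """

    name: str
    category: list[str] = field(default_factory=list)
    nodes: list[PathwayNode] = field(default_factory=list)
    edges: list[PathwayEdge] = field(default_factory=list)
    families: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValidationError(f"pathway {self.name!r} has no nodes")
        _check_unique((n.id for n in self.nodes), "node id")
        ids = {n.id for n in self.nodes}
        for e in self.edges:
            for end in (e.source, e.target):
                if end not in ids:
                    raise ValidationError(
                        f"edge {e.source!r}->{e.target!r} references unknown node {end!r}"
                    )
        membership: dict[str, str] = {}
        for fam, members in self.families.items():
            if fam not in ids:
                raise ValidationError(f"family node {fam!r} is not a declared node")
            for m in members:
                if m not in ids:
                    raise ValidationError(f"family {fam!r} member {m!r} is not a declared node")
                if m in membership:
                    raise ValidationError(
                        f"node {m!r} is a member of two families "
                        f"({membership[m]!r} and {fam!r})"
                    )
                membership[m] = fam
        # materialize the is_family flag on declared family nodes
        fam_ids = set(self.families)
        self.nodes = [
            PathwayNode(n.id, n.label, is_family=(n.id in fam_ids or n.is_family))
            for n in self.nodes
        ]

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def node(self, node_id: str) -> PathwayNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def family_of(self, node_id: str) -> str | None:
        for fam, members in self.families.items():
            if node_id in members:
                return fam
        return None

    def member_ids(self) -> set[str]:
        """Ids of all family-member nodes (hidden while collapsed)."""
        return {m for members in self.families.values() for m in members}

    def gene_nodes(self) -> list[PathwayNode]:
        """Non-family nodes, i.e. the nodes that carry per-gene statistics."""
        return [n for n in self.nodes if not n.is_family]

    def collapsed_node_ids(self) -> list[str]:
        """Node ids shown in the default (all families collapsed) view."""
        hidden = self.member_ids()
        return [n.id for n in self.nodes if n.id not in hidden]

    def to_networkx(self, *, collapsed: bool = True) -> nx.DiGraph:
        """Directed graph over the collapsed (default) or full node set.

        Undirected edges appear as arc pairs flagged ``directed=False`` so
        layout code can ignore them for depth.  With ``collapsed=True``,
        edges touching a hidden family member are re-attached to the family
        node.
        """
        g = nx.DiGraph()
        keep = set(self.collapsed_node_ids()) if collapsed else set(self.node_ids)
        member_to_fam = {m: f for f, ms in self.families.items() for m in ms}
        for n in self.nodes:
            if n.id in keep:
                g.add_node(n.id, label=n.label, is_family=n.is_family)
        for e in self.edges:
            s, t = e.source, e.target
            if collapsed:
                s = member_to_fam.get(s, s)
                t = member_to_fam.get(t, t)
            if s == t or s not in keep or t not in keep:
                continue
            g.add_edge(s, t, directed=e.directed)
            if not e.directed:
                g.add_edge(t, s, directed=False)
        return g


@dataclass
class GeneList:
    """Named set of gene symbols used to restrict frequency coloring."""

    name: str
    genes: set[str]

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        if not self.genes:
            raise ValidationError(f"gene list {self.name!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def validate_dataset(dataset: CohortDataset) -> list[Finding]:
    """Check cross-table consistency; returns findings, never raises.

    Missing data types are tolerated by design: the tool must render
    whatever subset of tables exists.  Errors are reserved for structural
    problems (no tables at all, sample ids outside the master registry).
    """
    findings: list[Finding] = []
    if dataset.n_tables == 0:
        findings.append(Finding("error", f"dataset {dataset.name!r} contains no tables"))
        return findings
    registry = set(dataset.samples)
    named: list[tuple[str, pd.DataFrame]] = []
    if dataset.expression is not None:
        named.append(("expression", dataset.expression.values))
    for dt, ft in dataset.flag_tables.items():
        named.append((str(dt), ft.flags))
    if dataset.cnv is not None:
        named.append(("cnv", dataset.cnv.copy_number))
    for kind, tab in named:
        for s in tab.columns:
            if s not in registry:
                findings.append(Finding(
                    "error", f"{kind} table sample {s!r} is not in the sample registry"))
    present = {dt for dt in FLAG_DATA_TYPES if dt in dataset.flag_tables}
    absent = [str(dt) for dt in FLAG_DATA_TYPES if dt not in present]
    if absent:
        findings.append(Finding(
            "warning", "data types not provided (tolerated): " + ", ".join(absent)))
    return findings


def validate_against_pathway(dataset: CohortDataset, pathway: Pathway) -> list[Finding]:
    """Warn about pathway genes absent from every cohort table."""
    known = set(dataset.genes())
    out = []
    for node in pathway.gene_nodes():
        if node.label not in known:
            out.append(Finding(
                "warning", f"pathway gene {node.label!r} absent from all cohort tables"))
    return out
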