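"""Seeded synthetic cohort and pathway generators.

Every fixture the pipeline consumes can be produced here: binary event
tables as independent per-gene Bernoulli draws, expression as a (optionally
bimodal) truncated-at-zero normal mixture, CNV as a neutral baseline with a
fraction of samples shifted by a gain/loss magnitude, and random single-root
connected pathway graphs.  Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CNVTable,
    CohortDataset,
    DataType,
    ExpressionMatrix,
    FlagTable,
    Pathway,
    PathwayEdge,
    PathwayNode,
    ValidationError,
)
from .io import write_table


@dataclass
class ExpressionModel:
    """Per-gene expression: N(baseline, noise_sd), truncated at 0, with an
    optional second mode mixed in at ``mix_fraction`` (bimodal cohorts)."""

    baseline: float = 10.0
    noise_sd: float = 2.0
    second_mode: float | None = None
    mix_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.noise_sd < 0:
            raise ValidationError("expression baseline and noise_sd must be >= 0")
        if not (0.0 <= self.mix_fraction <= 1.0):
            raise ValidationError("mix_fraction must be in [0, 1]")
        if self.mix_fraction > 0 and self.second_mode is None:
            raise ValidationError("mix_fraction > 0 requires a second_mode")


@dataclass
class CNVModel:
    """Per-gene copy number: neutral everywhere except a fraction of samples
    shifted by ``shift`` (positive = gain, negative = loss)."""

    neutral: float = 2.0
    shift: float = 0.0
    affected_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.neutral < 0:
            raise ValidationError("neutral copy number must be >= 0")
        if not (0.0 <= self.affected_fraction <= 1.0):
            raise ValidationError("affected_fraction must be in [0, 1]")
        if self.neutral + self.shift < 0:
            raise ValidationError("shift would produce negative copy numbers")


@dataclass
class GeneSpec:
    """Simulation parameters for one gene."""

    event_probs: dict[DataType, float] = field(default_factory=dict)
    expression: ExpressionModel = field(default_factory=ExpressionModel)
    cnv: CNVModel = field(default_factory=CNVModel)

    def __post_init__(self) -> None:
        self.event_probs = {DataType(k): float(v) for k, v in self.event_probs.items()}
        for dt, p in self.event_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{dt} probability must be in [0, 1], got {p}")


@dataclass
class SimulationSpec:
    n_samples: int
    genes: dict[str, GeneSpec]
    seed: int = 0
    name: str = "simulated-cohort"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not self.genes:
            raise ValidationError("at least one gene is required")


def simulate_cohort(spec: SimulationSpec, out_dir: str | Path | None = None) -> CohortDataset:
    """Draw a full synthetic cohort; optionally write its TSVs to ``out_dir``.

    Flags are independent Bernoulli(p) per gene and sample; expression is
    the gene's normal mixture truncated at zero; CNV equals the neutral
    value except for the first ``round(affected_fraction * n)`` samples in a
    seeded random order, which are shifted by the gene's magnitude.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    gene_names = list(spec.genes)

    flag_frames: dict[DataType, pd.DataFrame] = {}
    used_types = sorted({dt for g in spec.genes.values() for dt in g.event_probs},
                        key=lambda d: d.value)
    for dt in used_types:
        rows = []
        for g in gene_names:
            p = spec.genes[g].event_probs.get(dt)
            if p is None:
                rows.append(np.full(spec.n_samples, np.nan))
            else:
                rows.append(rng.binomial(1, p, size=spec.n_samples).astype(float))
        flag_frames[dt] = pd.DataFrame(rows, index=gene_names, columns=samples)

    expr_rows = []
    for g in gene_names:
        em = spec.genes[g].expression
        base = rng.normal(em.baseline, em.noise_sd, size=spec.n_samples)
        if em.mix_fraction > 0:
            in_second = rng.random(spec.n_samples) < em.mix_fraction
            second = rng.normal(em.second_mode, em.noise_sd, size=spec.n_samples)
            base = np.where(in_second, second, base)
        expr_rows.append(np.clip(base, 0.0, None))
    expr = pd.DataFrame(expr_rows, index=gene_names, columns=samples)

    cnv_rows = []
    for g in gene_names:
        cm = spec.genes[g].cnv
        vals = np.full(spec.n_samples, cm.neutral, dtype=float)
        n_aff = int(round(cm.affected_fraction * spec.n_samples))
        if n_aff > 0 and cm.shift != 0.0:
            affected = rng.permutation(spec.n_samples)[:n_aff]
            vals[affected] += cm.shift
        cnv_rows.append(vals)
    cnv = pd.DataFrame(cnv_rows, index=gene_names, columns=samples)

    dataset = CohortDataset(
        name=spec.name, samples=samples,
        expression=ExpressionMatrix(expr),
        flag_tables={dt: FlagTable(dt, df) for dt, df in flag_frames.items()},
        cnv=CNVTable(cnv),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(expr, out_dir / "expression.tsv")
        write_table(cnv, out_dir / "cnv.tsv")
        for dt, df in flag_frames.items():
            write_table(df.astype("Int64"), out_dir / f"{dt}.tsv")
    return dataset


def simulate_pathway(n_nodes: int, n_families: int = 0, edge_density: float = 0.15,
                     seed: int = 0, cyclic: bool = False,
                     gene_prefix: str = "G") -> Pathway:
    """Random single-root connected pathway graph, deterministic per seed.

    DAG mode (default) gives every non-root node at least one parent among
    earlier nodes, so depths are finite from the single root; ``cyclic``
    adds one back edge when possible.  ``n_families`` collapses groups of
    leaf genes under synthetic family nodes.
    """
    if n_nodes < 1:
        raise ValidationError("n_nodes must be >= 1")
    if not (0.0 <= edge_density <= 1.0):
        raise ValidationError("edge_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [f"{gene_prefix}{i + 1:03d}" for i in range(n_nodes)]
    nodes = [PathwayNode(n, n) for n in names]
    edges: list[PathwayEdge] = []
    seen: set[tuple[str, str]] = set()
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, i))
        edges.append(PathwayEdge(names[parent], names[i]))
        seen.add((names[parent], names[i]))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            pair = (names[i], names[j])
            if pair not in seen and rng.random() < edge_density:
                edges.append(PathwayEdge(*pair))
                seen.add(pair)
    if cyclic and n_nodes >= 2:
        edges.append(PathwayEdge(names[-1], names[0]))

    families: dict[str, list[str]] = {}
    if n_families > 0:
        # prefer sink genes as family members; pad with other non-root genes
        sources = {e.source for e in edges}
        targets = {e.target for e in edges}
        leaves = [n for n in names if n not in sources and n in targets]
        pool = leaves + [n for n in reversed(names[1:]) if n not in leaves]
        if len(pool) < 2 * n_families:
            raise ValidationError(
                f"cannot form {n_families} families from {len(pool)} candidate genes")
        leaves = pool[:max(2 * n_families, len(leaves))]
        per = len(leaves) // n_families
        fam_nodes = []
        for k in range(n_families):
            members = leaves[k * per:(k + 1) * per] if k < n_families - 1 \
                else leaves[(n_families - 1) * per:]
            fam_id = f"FAM{k + 1}"
            fam_nodes.append(PathwayNode(fam_id, fam_id, is_family=True))
            families[fam_id] = members
            for m in members:
                for e in edges:
                    if e.target == m and (e.source, fam_id) not in seen:
                        edges.append(PathwayEdge(e.source, fam_id))
                        seen.add((e.source, fam_id))
                        break
        nodes.extend(fam_nodes)
    return Pathway(name=f"simulated-{n_nodes}n-seed{seed}",
                   category=["simulated", "synthetic"],
                   nodes=nodes, edges=edges, families=families)
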