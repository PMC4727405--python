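"""Per-gene cohort summary statistics.

For each gene the cohort is reduced to: event frequencies per binary data
type with a three-bin classification (low / intermediate / high), an
expression summary (mean or median) with an outlier-sample rule, and the
mean copy-number deviation from the diploid baseline with its direction.
These summaries drive all node coloring and elevation in the scene.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import CNVConfig, OutlierConfig, ThresholdConfig
from .datamodel import (
    CNVTable,
    CohortDataset,
    DataType,
    ExpressionMatrix,
    FlagTable,
    GeneList,
    Pathway,
    ValidationError,
)

BINS = ("low", "intermediate", "high")


@dataclass(frozen=True)
class FrequencySummary:
    """Cohort frequency of one binary event type for one gene.

    ``n_assessed`` counts non-missing entries only: a blank cell means the
    sample was never assessed and must not inflate the denominator.
    """

    frequency: float | None
    n_events: int
    n_assessed: int
    bin: str | None

    def __post_init__(self) -> None:
        if self.n_assessed > 0:
            assert self.frequency is not None
            assert abs(self.frequency - self.n_events / self.n_assessed) < 1e-12


@dataclass(frozen=True)
class ExpressionGeneSummary:
    summary: float | None
    outlier_samples: frozenset[str]
    is_outlier_gene: bool
    n_assessed: int


@dataclass(frozen=True)
class CNVSummary:
    """Raw mean deviation from neutral, its sign, and the boolean-mode flag
    (any single sample deviating from neutral by more than epsilon)."""

    mean_deviation: float
    direction: str  # gain | loss | neutral
    per_sample: dict[str, float]
    boolean_flag: bool


@dataclass
class CohortGeneSummary:
    """Everything the scene needs to know about one gene."""

    gene: str
    frequencies: dict[DataType, FrequencySummary] = field(default_factory=dict)
    expression: ExpressionGeneSummary | None = None
    cnv: CNVSummary | None = None
    restricted_out: bool = False


def event_frequency(flags: FlagTable, gene: str) -> tuple[float | None, int, int]:
    """Cohort frequency of a binary event for ``gene``.

    Returns ``(frequency, n_events, n_assessed)``; frequency is None when no
    sample was assessed.
    """
    if gene not in flags.flags.index:
        raise ValidationError(f"gene {gene!r} not present in {flags.data_type} flag table")
    row = flags.flags.loc[gene]
    n_assessed = int(row.notna().sum())
    n_events = int(row.fillna(0).sum())
    if n_assessed == 0:
        return None, 0, 0
    return n_events / n_assessed, n_events, n_assessed


def bin_frequency(frequency: float, thresholds: ThresholdConfig,
                  data_type: DataType | None = None) -> str:
    """Classify a frequency into low / intermediate / high.

    Boundary rule: the low bin is closed at ``low_max`` and the high bin is
    closed at ``high_min`` (a frequency exactly at a cut point takes the
    outer bin).
    """
    if not (0.0 <= frequency <= 1.0) or math.isnan(frequency):
        raise ValidationError(f"frequency must be in [0, 1], got {frequency}")
    low_max, high_min = thresholds.bounds(data_type)
    if frequency <= low_max:
        return "low"
    if frequency >= high_min:
        return "high"
    return "intermediate"


def expression_summary(expr: ExpressionMatrix, gene: str,
                       config: OutlierConfig) -> ExpressionGeneSummary:
    """Summarize one gene's expression and flag outlier-heavy genes.

    A sample s is an outlier iff ``|x_s - mean| > k_sd * sd`` where sd is
    the sample (n-1) standard deviation over assessed samples; the gene is
    flagged iff the outlier fraction reaches ``min_outlier_fraction``.
    With fewer than two assessed values the outlier assessment is absent.
    """
    if gene not in expr.values.index:
        raise ValidationError(f"gene {gene!r} not present in expression matrix")
    row = expr.values.loc[gene].dropna()
    n = len(row)
    if n == 0:
        return ExpressionGeneSummary(None, frozenset(), False, 0)
    summary = float(row.median() if config.summary_stat == "median" else row.mean())
    if n < 2:
        return ExpressionGeneSummary(summary, frozenset(), False, n)
    mean = float(row.mean())
    sd = float(row.std(ddof=1))
    outliers = frozenset(row.index[(row - mean).abs() > config.k_sd * sd])
    flagged = len(outliers) / n >= config.min_outlier_fraction and len(outliers) > 0
    return ExpressionGeneSummary(summary, outliers, flagged, n)


def cnv_summary(cnv: CNVTable, gene: str, config: CNVConfig) -> CNVSummary | None:
    """Mean copy-number deviation from the neutral baseline for one gene.

    Direction is the exact sign of the mean deviation in both display
    modes; boolean mode additionally records whether any single sample
    deviates from neutral by more than ``epsilon`` (the constant-height
    flag applied at layout time).  Returns None when no sample has data.
    """
    if gene not in cnv.copy_number.index:
        raise ValidationError(f"gene {gene!r} not present in CNV table")
    row = cnv.copy_number.loc[gene].dropna()
    if len(row) == 0:
        return None
    dev = row - config.neutral_copy_number
    mean_dev = float(dev.mean())
    direction = "gain" if mean_dev > 0 else ("loss" if mean_dev < 0 else "neutral")
    flag = bool((dev.abs() > config.epsilon).any())
    return CNVSummary(mean_dev, direction, {s: float(v) for s, v in dev.items()}, flag)


def apply_gene_list_restriction(
        summaries: dict[str, CohortGeneSummary],
        gene_list: GeneList | None) -> dict[str, CohortGeneSummary]:
    """Mark genes outside ``gene_list`` as restricted (uncolored in the scene).

    Numeric fields are preserved so per-sample detail views keep working;
    with no list the map is returned unchanged.
    """
    if gene_list is None:
        return summaries
    return {g: replace(s, restricted_out=(g not in gene_list))
            for g, s in summaries.items()}


def summarize_cohort(dataset: CohortDataset, pathway: Pathway,
                     thresholds: ThresholdConfig | None = None,
                     outlier_cfg: OutlierConfig | None = None,
                     cnv_cfg: CNVConfig | None = None,
                     gene_list: GeneList | None = None) -> dict[str, CohortGeneSummary]:
    """One CohortGeneSummary per non-family pathway node.

    Family nodes carry no statistics of their own (they do not show data
    values until expanded); absent data types simply leave the matching
    fields absent.
    """
    thresholds = thresholds or ThresholdConfig()
    outlier_cfg = outlier_cfg or OutlierConfig()
    cnv_cfg = cnv_cfg or CNVConfig()
    out: dict[str, CohortGeneSummary] = {}
    for node in pathway.gene_nodes():
        gene = node.label
        summary = CohortGeneSummary(gene=gene)
        for dt, ft in dataset.flag_tables.items():
            if gene not in ft.flags.index:
                continue
            freq, n_ev, n_as = event_frequency(ft, gene)
            b = bin_frequency(freq, thresholds, dt) if freq is not None else None
            summary.frequencies[dt] = FrequencySummary(freq, n_ev, n_as, b)
        if dataset.expression is not None and gene in dataset.expression.values.index:
            summary.expression = expression_summary(dataset.expression, gene, outlier_cfg)
        if dataset.cnv is not None and gene in dataset.cnv.copy_number.index:
            summary.cnv = cnv_summary(dataset.cnv, gene, cnv_cfg)
        out[gene] = summary
    return apply_gene_list_restriction(out, gene_list)


def gene_detail(dataset: CohortDataset, gene: str,
                sort_by: str | None = None, ascending: bool = True) -> pd.DataFrame:
    """Per-sample listing of every available value for one gene.

    Columns are the available data types (expression, flag types, cnv and
    cnv_deviation relative to diploid); rows are the master sample registry.
    ``sort_by`` orders samples by any column, e.g. relative copy number.
    An unknown gene yields an empty frame with a warning, not an error.
    """
    cols: dict[str, pd.Series] = {}
    if dataset.expression is not None and gene in dataset.expression.values.index:
        cols["expression"] = dataset.expression.values.loc[gene]
    for dt, ft in dataset.flag_tables.items():
        if gene in ft.flags.index:
            cols[str(dt)] = ft.flags.loc[gene]
    if dataset.cnv is not None and gene in dataset.cnv.copy_number.index:
        cn = dataset.cnv.copy_number.loc[gene]
        cols["cnv"] = cn
        cols["cnv_deviation"] = cn - 2.0
    if not cols:
        warnings.warn(f"gene {gene!r} is absent from every cohort table", stacklevel=2)
        return pd.DataFrame(index=pd.Index(dataset.samples, name="sample"))
    detail = pd.DataFrame(cols).reindex(dataset.samples)
    detail.index.name = "sample"
    if sort_by is not None:
        if sort_by not in detail.columns:
            raise ValidationError(f"cannot sort detail view by unknown column {sort_by!r}")
        detail = detail.sort_values(sort_by, ascending=ascending, kind="stable")
    return detail


def summaries_to_frame(summaries: dict[str, CohortGeneSummary]) -> pd.DataFrame:
    """Flatten summaries into one row per gene for TSV reports."""
    rows = []
    for gene, s in summaries.items():
        row: dict[str, object] = {"gene": gene, "restricted_out": s.restricted_out}
        for dt in DataType:
            fs = s.frequencies.get(dt)
            row[f"{dt}_frequency"] = None if fs is None else fs.frequency
            row[f"{dt}_n_events"] = None if fs is None else fs.n_events
            row[f"{dt}_n_assessed"] = None if fs is None else fs.n_assessed
            row[f"{dt}_bin"] = None if fs is None else fs.bin
        row["expression_summary"] = None if s.expression is None else s.expression.summary
        row["expression_outlier_gene"] = (
            False if s.expression is None else s.expression.is_outlier_gene)
        row["cnv_mean_deviation"] = None if s.cnv is None else s.cnv.mean_deviation
        row["cnv_direction"] = None if s.cnv is None else s.cnv.direction
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
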