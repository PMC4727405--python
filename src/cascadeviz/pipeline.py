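"""End-to-end convenience: dataset + pathway + config -> layout + scene."""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

from . import __version__
from .config import AnalysisConfig
from .datamodel import CohortDataset, DataType, GeneList, Pathway
from .io import read_cnv_table, read_expression_table, read_flag_table
from .layout import LayoutModel, apply_cnv_elevation, compute_depths, radial_layout
from .scene import SceneGraph, build_scene
from .stats import CohortGeneSummary, summarize_cohort

TABLE_FILES = {
    "expression": "expression.tsv",
    "cnv": "cnv.tsv",
    **{str(dt): f"{dt}.tsv" for dt in DataType},
}


def load_dataset_dir(path: str | Path, name: str | None = None) -> CohortDataset:
    """Load a cohort from a directory of conventionally named TSVs.

    Recognized files: ``expression.tsv``, ``cnv.tsv`` and one
    ``<data_type>.tsv`` per binary event type; any subset is acceptable.
    """
    path = Path(path)
    expr = None
    cnv = None
    flags = {}
    if (path / "expression.tsv").exists():
        expr = read_expression_table(path / "expression.tsv")
    if (path / "cnv.tsv").exists():
        cnv = read_cnv_table(path / "cnv.tsv")
    for dt in DataType:
        f = path / f"{dt}.tsv"
        if f.exists():
            flags[dt] = read_flag_table(f, dt)
    return CohortDataset(name=name or path.name, expression=expr,
                         flag_tables=flags, cnv=cnv)


def run_pipeline(dataset: CohortDataset, pathway: Pathway, config: AnalysisConfig,
                 gene_list: GeneList | None = None, seed: int | None = None,
                 ) -> tuple[dict[str, CohortGeneSummary], LayoutModel, SceneGraph]:
    """Summarize, lay out and build the scene for one pathway view."""
    summaries = summarize_cohort(dataset, pathway, config.thresholds,
                                 config.outlier, config.cnv, gene_list)
    depths = compute_depths(pathway)
    layout = radial_layout(pathway, depths, config.layout)
    if config.view.cnv:
        layout = apply_cnv_elevation(layout, summaries, pathway, config.cnv)
    provenance = {
        "tool": "cascadeviz",
        "version": __version__,
        "dataset": dataset.name,
        "pathway": pathway.name,
        "config_hash": config.config_hash(),
    }
    if seed is not None:
        provenance["seed"] = seed
    view = replace(config.view, show_guide_rings=(
        config.layout.show_guide_rings and config.view.show_guide_rings))
    scene = build_scene(pathway, layout, summaries, view, config.colors, provenance)
    return summaries, layout, scene
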