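"""User-tunable parameters: thresholds, outlier rule, CNV encoding, layout,
colors and the active-view selection, plus YAML/JSON config-file loading."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .datamodel import DataType, ValidationError

RGB = tuple[int, int, int]


def _check_rgb(color: RGB, name: str) -> RGB:
    color = tuple(int(c) for c in color)  # type: ignore[assignment]
    if len(color) != 3 or any(c < 0 or c > 255 for c in color):
        raise ValidationError(f"{name}: RGB channels must be in [0, 255], got {color}")
    return color


@dataclass
class ThresholdConfig:
    """Two cut points splitting cohort frequency into low / intermediate / high.

    ``frequency <= low_max`` is low; ``frequency >= high_min`` is high; the
    bins are closed on the low and high side.  Per-data-type overrides allow
    e.g. a tighter splicing threshold than the mutation one.
    """

    low_max: float = 0.10
    high_min: float = 0.30
    per_type: dict[DataType, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.per_type = {DataType(k): (float(v[0]), float(v[1]))
                         for k, v in self.per_type.items()}
        for lo, hi in [(self.low_max, self.high_min), *self.per_type.values()]:
            if not (0.0 <= lo < hi <= 1.0):
                raise ValidationError(
                    f"thresholds need 0 <= low_max < high_min <= 1, got ({lo}, {hi})")

    def bounds(self, data_type: DataType | None = None) -> tuple[float, float]:
        if data_type is not None and DataType(data_type) in self.per_type:
            return self.per_type[DataType(data_type)]
        return (self.low_max, self.high_min)


@dataclass
class OutlierConfig:
    """Expression outlier rule: a sample is an outlier when it deviates from
    the gene's cohort mean by more than ``k_sd`` sample standard deviations;
    the gene is flagged when at least ``min_outlier_fraction`` of assessed
    samples are outliers."""

    k_sd: float = 2.0
    min_outlier_fraction: float = 0.05
    summary_stat: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValidationError(f"k_sd must be > 0, got {self.k_sd}")
        if not (0.0 < self.min_outlier_fraction <= 1.0):
            raise ValidationError(
                f"min_outlier_fraction must be in (0, 1], got {self.min_outlier_fraction}")
        if self.summary_stat not in ("mean", "median"):
            raise ValidationError(f"summary_stat must be 'mean' or 'median'")


@dataclass
class CNVConfig:
    """Copy-number encoding.  ``relative`` mode elevates nodes by the mean
    deviation from the neutral copy number times ``height_scale``; ``boolean``
    mode uses a constant flag height whenever any sample deviates from
    neutral by more than ``epsilon``."""

    neutral_copy_number: float = 2.0
    mode: str = "relative"  # or "boolean"
    height_scale: float = 5.0
    epsilon: float = 0.5

    def __post_init__(self) -> None:
        if self.neutral_copy_number < 0:
            raise ValidationError("neutral_copy_number must be >= 0")
        if self.mode not in ("relative", "boolean"):
            raise ValidationError("CNV mode must be 'relative' or 'boolean'")
        if self.height_scale <= 0:
            raise ValidationError("height_scale must be > 0")
        if self.epsilon < 0:
            raise ValidationError("epsilon must be >= 0")


@dataclass
class LayoutConfig:
    """Radial layout geometry in scene units."""

    ring_spacing: float = 10.0
    family_plane_height: float = 6.0
    child_spread: float = 8.0
    angular_tiebreak: str = "alphabetical"  # or "input_order"
    show_guide_rings: bool = True

    def __post_init__(self) -> None:
        for name in ("ring_spacing", "family_plane_height", "child_spread"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.angular_tiebreak not in ("alphabetical", "input_order"):
            raise ValidationError("angular_tiebreak must be 'alphabetical' or 'input_order'")


@dataclass
class ColorScheme:
    """Node and primitive colors (RGB 0-255)."""

    bin_colors: dict[str, RGB] = field(default_factory=lambda: {
        "low": (255, 255, 255),        # white
        "intermediate": (255, 105, 180),  # pink
        "high": (255, 0, 0),           # red
    })
    family_color: RGB = (139, 69, 19)      # brown
    expression_bar_color: RGB = (0, 160, 0)  # green
    outlier_marker_color: RGB = (255, 0, 0)
    gain_cone_color: RGB = (255, 0, 0)
    loss_cone_color: RGB = (0, 160, 0)
    no_data_color: RGB = (180, 180, 180)
    edge_color: RGB = (120, 120, 120)
    guide_ring_color: RGB = (200, 200, 200)

    def __post_init__(self) -> None:
        self.bin_colors = {k: _check_rgb(v, f"bin_colors[{k}]")
                           for k, v in self.bin_colors.items()}
        for k in set(("low", "intermediate", "high")) - set(self.bin_colors):
            raise ValidationError(f"bin_colors is missing the {k!r} bin")
        for name in ("family_color", "expression_bar_color", "outlier_marker_color",
                     "gain_cone_color", "loss_cone_color", "no_data_color",
                     "edge_color", "guide_ring_color"):
            setattr(self, name, _check_rgb(getattr(self, name), name))


@dataclass
class ViewConfig:
    """Which data layers are active and which flag type colors the spheres."""

    expression: bool = False
    splicing: bool = False
    cnv: bool = False
    node_color_type: DataType | None = DataType.MUTATION
    show_guide_rings: bool = True
    expression_bar_scale: float = 0.1  # scene units per expression unit
    expression_bar_max: float = 20.0

    def __post_init__(self) -> None:
        if self.node_color_type is not None:
            self.node_color_type = DataType(self.node_color_type)
        if self.expression_bar_scale <= 0 or self.expression_bar_max <= 0:
            raise ValidationError("expression bar scale/max must be > 0")


@dataclass
class AnalysisConfig:
    """Bundle of every tunable block, loadable from one YAML/JSON file."""

    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    outlier: OutlierConfig = field(default_factory=OutlierConfig)
    cnv: CNVConfig = field(default_factory=CNVConfig)
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    colors: ColorScheme = field(default_factory=ColorScheme)
    view: ViewConfig = field(default_factory=ViewConfig)
    gene_list_path: str | None = None

    def config_hash(self) -> str:
        """Stable short hash recorded in output provenance blocks."""
        def jsonable(obj):
            if isinstance(obj, dict):
                return {str(k): jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
            if isinstance(obj, (list, tuple)):
                return [jsonable(v) for v in obj]
            if isinstance(obj, DataType):
                return obj.value
            return obj
        blob = json.dumps(jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML or JSON; absent blocks use defaults."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValidationError(f"{path.name}: config root must be a mapping")

    def block(cls, key):
        sub = doc.get(key, {})
        if not isinstance(sub, dict):
            raise ValidationError(f"{path.name}: {key!r} must be a mapping")
        if key == "colors":
            sub = {k: (tuple(v) if isinstance(v, list) else v) for k, v in sub.items()}
            if "bin_colors" in sub:
                sub["bin_colors"] = {k: tuple(v) for k, v in sub["bin_colors"].items()}
        return cls(**sub)

    return AnalysisConfig(
        thresholds=block(ThresholdConfig, "thresholds"),
        outlier=block(OutlierConfig, "outlier"),
        cnv=block(CNVConfig, "cnv"),
        layout=block(LayoutConfig, "layout"),
        colors=block(ColorScheme, "colors"),
        view=block(ViewConfig, "view"),
        gene_list_path=doc.get("gene_list_path"),
    )
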