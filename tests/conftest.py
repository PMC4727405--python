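import numpy as np
import pandas as pd
import pytest

from cascadeviz import (
    CNVTable,
    CohortDataset,
    DataType,
    ExpressionMatrix,
    FlagTable,
    Pathway,
    PathwayEdge,
    PathwayNode,
)

CANONICAL_SEED = 0


def frame(rows: dict[str, list[float]], samples: list[str]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples).astype(float)


@pytest.fixture
def chain_pathway() -> Pathway:
    """A -> B -> C."""
    return Pathway("chain", nodes=[PathwayNode(n, n) for n in "ABC"],
                   edges=[PathwayEdge("A", "B"), PathwayEdge("B", "C")])


@pytest.fixture
def jak_pathway() -> Pathway:
    """Receptor feeding a collapsed 4-member kinase family."""
    members = ["JAK1", "JAK2", "JAK3", "TYK2"]
    nodes = [PathwayNode("RTK", "RTK"), PathwayNode("JAK", "JAK"),
             *[PathwayNode(m, m) for m in members]]
    return Pathway("jak", nodes=nodes, edges=[PathwayEdge("RTK", "JAK")],
                   families={"JAK": members})


@pytest.fixture
def small_dataset() -> CohortDataset:
    """Three genes x four samples with every table type and some missing cells."""
    samples = ["S1", "S2", "S3", "S4"]
    expr = frame({"A": [1.0, 2.0, 3.0, 4.0],
                  "B": [5.0, 5.0, 5.0, 5.0],
                  "C": [0.0, np.nan, 10.0, 20.0]}, samples)
    mut = frame({"A": [1, 0, 0, 0],
                 "B": [1, 1, 1, 1],
                 "C": [0, np.nan, np.nan, 1]}, samples)
    spl = frame({"A": [0, 0, 0, 0],
                 "B": [1, 0, 1, 0],
                 "C": [np.nan] * 4}, samples)
    cnv = frame({"A": [2, 2, 4, 4],
                 "B": [1, 1, 2, 2],
                 "C": [2, 2, 2, 2]}, samples)
    return CohortDataset(
        name="small", samples=samples,
        expression=ExpressionMatrix(expr),
        flag_tables={DataType.MUTATION: FlagTable(DataType.MUTATION, mut),
                     DataType.SPLICING: FlagTable(DataType.SPLICING, spl)},
        cnv=CNVTable(cnv))
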