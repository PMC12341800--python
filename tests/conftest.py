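import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from consig import (
    CellAnnotation,
    CellClass,
    ExpressionMatrix,
    FCScale,
    LayerTag,
    MarkerTable,
)


def make_marker_table(rows):
    """rows: (study, population, cell_class, gene, fc, scale, p_adj)."""
    df = pd.DataFrame(
        rows, columns=["study_id", "population_label", "cell_class", "gene",
                       "fc_value", "fc_scale", "p_adj"])
    return MarkerTable(df)


@pytest.fixture
def small_markers():
    rows = [
        ("s1", "RGL", CellClass.NSC, "Fabp7", 2.0, FCScale.LINEAR, 0.01),
        ("s1", "RGL", CellClass.NSC, "Hopx", 1.8, FCScale.LINEAR, 0.02),
        ("s1", "nIPC", CellClass.NP, "Ascl1", 2.5, FCScale.LINEAR, 0.001),
        ("s2", "NSC", CellClass.NSC, "FABP7", 0.9, FCScale.LOG2, 0.01),
        ("s2", "NSC", CellClass.NSC, "Aldoc", 0.7, FCScale.LOG2, 0.01),
        ("s3", "qNSC", CellClass.NSC, "Fabp7", 0.5, FCScale.LN, 0.03),
        ("s3", "qNSC", CellClass.NSC, "Id4", 0.4, FCScale.LN, 0.01),
    ]
    return make_marker_table(rows)


@pytest.fixture
def tiny_expr():
    """5 genes x 4 cells, log-normalized, all values distinct per cell."""
    dense = np.array([
        [5.0, 1.0, 0.0, 2.0],
        [4.0, 2.0, 0.0, 6.0],
        [3.0, 3.0, 0.0, 0.0],
        [2.0, 4.0, 1.0, 0.0],
        [1.0, 5.0, 2.0, 0.0],
    ])
    return ExpressionMatrix(
        ("g1", "g2", "g3", "g4", "g5"),
        ("c1", "c2", "c3", "c4"),
        sparse.csr_matrix(dense), LayerTag.LOGNORM)


@pytest.fixture
def tiny_ann(tiny_expr):
    return CellAnnotation(pd.DataFrame({
        "cluster": ["A", "A", "B", "B"],
        "study_id": "s1",
        "pseudotime": [0.1, 0.4, 0.6, 0.9],
    }, index=pd.Index(tiny_expr.cell_ids, name="cell_id")))
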