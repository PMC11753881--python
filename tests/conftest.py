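import numpy as np
import pandas as pd
import pytest

from evquant import AbundanceMatrix, AnnotationMap


@pytest.fixture
def small_matrix() -> AbundanceMatrix:
    """3 proteins x 4 samples, two groups of two, one missing cell."""
    data = pd.DataFrame(
        {
            "cell_r1": [30.0, 70.0, 10.0],
            "cell_r2": [25.0, 75.0, 12.0],
            "ev_r1": [np.nan, 40.0, 60.0],
            "ev_r2": [5.0, 35.0, 55.0],
        },
        index=pd.Index(["P1", "P2", "P3"], name="protein_id"),
    )
    groups = pd.Series(
        ["cell", "cell", "ev", "ev"], index=data.columns, name="group"
    )
    return AbundanceMatrix(data, groups)


@pytest.fixture
def annotation_map() -> AnnotationMap:
    return AnnotationMap(
        cog={"P1": ["C"], "P2": ["M", "P"], "P3": ["J"]},
        go={"P1": ["ion binding"], "P2": ["hydrolase activity", "ion binding"]},
        localization={"P1": "cytoplasm", "P2": "membrane"},
    )


def two_group_matrix(values: np.ndarray, n1: int, n2: int,
                     groups=("g1", "g2")) -> AbundanceMatrix:
    """Helper: wrap an array as an AbundanceMatrix with two groups."""
    cols = [f"{groups[0]}_r{i+1}" for i in range(n1)] + [
        f"{groups[1]}_r{i+1}" for i in range(n2)
    ]
    data = pd.DataFrame(
        values,
        index=pd.Index([f"P{i+1:04d}" for i in range(values.shape[0])], name="protein_id"),
        columns=cols,
    )
    gser = pd.Series([groups[0]] * n1 + [groups[1]] * n2, index=cols, name="group")
    return AbundanceMatrix(data, gser)
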