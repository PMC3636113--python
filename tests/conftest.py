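import numpy as np
import pandas as pd
import pytest

from coexfish.expression import ReadCountMatrix
from coexfish.network import ExpressionCompendium


def make_matrix(data: dict[str, list[int]], n_ref: int = 3, n_treat: int = 3,
                ref: str = "+Pi", treat: str = "-Pi") -> ReadCountMatrix:
    """Count matrix from gene -> [ref replicates..., treat replicates...] rows."""
    ref_cols = [f"{ref}_r{i+1}" for i in range(n_ref)]
    treat_cols = [f"{treat}_r{i+1}" for i in range(n_treat)]
    counts = pd.DataFrame(data, index=ref_cols + treat_cols).T
    conditions = pd.Series({**{c: ref for c in ref_cols}, **{c: treat for c in treat_cols}})
    return ReadCountMatrix(counts=counts, conditions=conditions)


def make_compendium(columns: dict[str, np.ndarray]) -> ExpressionCompendium:
    frame = pd.DataFrame(columns)
    frame.index = [f"S{i+1:03d}" for i in range(len(frame))]
    return ExpressionCompendium(values=frame)


@pytest.fixture
def toy_matrix() -> ReadCountMatrix:
    """Six genes covering all tiers plus de novo and silent cases."""
    return make_matrix(
        {
            "silent": [0, 0, 0, 0, 0, 0],
            "denovo": [0, 0, 0, 4, 7, 2],
            "low": [0, 3, 7, 1, 2, 5],
            "medium": [11, 40, 200, 90, 120, 80],
            "high": [2500, 1800, 900, 2600, 2700, 2400],
            "flat": [100, 100, 100, 100, 100, 100],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
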