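import numpy as np
import pandas as pd
import pytest

from refstab.data_io import CtMatrix
from refstab.qpcr_core import QuantityMatrix


def q_from_log2(rows: dict[str, list[float]]) -> QuantityMatrix:
    """Build a QuantityMatrix directly from log2-quantity rows."""
    df = pd.DataFrame({g: np.power(2.0, np.asarray(v, dtype=float)) for g, v in rows.items()}).T
    df.columns = [f"s{i + 1}" for i in range(df.shape[1])]
    genes = list(df.index)
    return QuantityMatrix(
        values=df,
        reference_ct=pd.Series(20.0, index=genes),
        efficiencies=pd.Series(2.0, index=genes),
    )


@pytest.fixture
def three_gene_quantities() -> QuantityMatrix:
    """The hand-computable instance: two identical genes and one flat gene."""
    return q_from_log2({"A": [0, 1, 2], "B": [0, 1, 2], "C": [0, 0, 0]})


@pytest.fixture
def small_ct() -> CtMatrix:
    values = pd.DataFrame(
        {
            "s1": [20.0, 25.0, 19.0],
            "s2": [21.0, 25.0, 21.0],
            "s3": [22.0, 25.0, 20.0],
        },
        index=["A", "C", "D"],
    )
    return CtMatrix(values, efficiencies=pd.Series(2.0, index=values.index))


def random_ct(rng: np.random.Generator, n_genes: int = 6, n_samples: int = 8) -> CtMatrix:
    values = pd.DataFrame(
        rng.uniform(15.0, 30.0, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return CtMatrix(values, efficiencies=pd.Series(2.0, index=values.index))
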