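import numpy as np
import pandas as pd
import pytest

from refstab import (
    CtMatrix,
    ExpressionMatrix,
    StudyDesign,
    default_ct_spec,
    simulate_ct,
)


@pytest.fixture
def toy_ct():
    """3 genes x 3 samples with hand-checkable pairwise SDs."""
    return CtMatrix(
        pd.DataFrame(
            {
                "s1": [20.0, 25.0, 30.0],
                "s2": [21.0, 25.0, 31.0],
                "s3": [22.0, 25.0, 30.0],
            },
            index=pd.Index(["g1", "g2", "g3"], name="gene"),
        )
    )


@pytest.fixture
def toy_quantities():
    """Quantities g1=(1,2,4), g2=(2,4,8), g3=(1,1,1): M = (0.5, 0.5, 1.0)."""
    import refstab.stability as st

    q = pd.DataFrame(
        {"s1": [1.0, 2.0, 1.0], "s2": [2.0, 4.0, 1.0], "s3": [4.0, 8.0, 1.0]},
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    return st.RelativeQuantityMatrix(q, pd.Series(2.0, index=q.index))


@pytest.fixture
def small_expression():
    return ExpressionMatrix(
        pd.DataFrame(
            {
                "s1": [10.0, 10.0, 1.0],
                "s2": [20.0, 10.0, 0.0],
                "s3": [30.0, 10.0, 0.0],
                "s4": [40.0, 10.0, 0.0],
            },
            index=pd.Index(["rising", "flat", "onehot"], name="gene"),
        )
    )


@pytest.fixture(scope="session")
def default_sim():
    """One collapsed draw of the package's reference 12x39 Ct design."""
    return simulate_ct(default_ct_spec(seed=20))


@pytest.fixture
def two_group_design():
    rows = [(f"s{i}", "grp", "A" if i <= 3 else "B") for i in range(1, 7)]
    return StudyDesign(pd.DataFrame(rows, columns=["sample", "factor", "level"]))


def random_ct(rng: np.random.Generator, genes: int, samples: int) -> CtMatrix:
    vals = rng.uniform(18.0, 32.0, size=(genes, samples))
    return CtMatrix(
        pd.DataFrame(
            vals,
            index=pd.Index([f"g{i}" for i in range(genes)], name="gene"),
            columns=[f"s{j}" for j in range(samples)],
        )
    )
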