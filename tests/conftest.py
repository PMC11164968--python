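import numpy as np
import pandas as pd
import pytest

from refstab import CtTable


@pytest.fixture
def worked_example() -> pd.DataFrame:
    """Three-gene toy: A and B move together, C is flat.

    Hand-computed: V_AB = 0, V_AC = V_BC = 1 (log2 ratios {0,1,2}),
    M = (0.5, 0.5, 1.0), NF_3 = (1, 2^(2/3), 2^(4/3)), V_2/3 = 1/3.
    """
    return pd.DataFrame(
        [[1.0, 2.0, 4.0], [1.0, 2.0, 4.0], [1.0, 1.0, 1.0]],
        index=["A", "B", "C"],
        columns=["s1", "s2", "s3"],
    )


def make_ct_table(ct, genes=None, samples=None, groups=None) -> CtTable:
    ct = np.asarray(ct, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(ct.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(ct.shape[1])]
    groups = groups or {s: "all" for s in samples}
    return CtTable(tuple(genes), tuple(samples), ct, groups)


@pytest.fixture
def ct_factory():
    return make_ct_table


@pytest.fixture
def random_ct_tables():
    """Factory for batches of random all-one-group Ct tables."""

    def make(n_tables: int, n_genes: int = 5, n_samples: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_tables):
            out.append(make_ct_table(rng.uniform(18.0, 30.0, (n_genes, n_samples))))
        return out

    return make
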