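import numpy as np
import pandas as pd
import pytest

from dcenet.datatypes import ExpressionMatrix, IndividualCorrelationStack


def make_samplesheet(groups: dict[str, int], n_timepoints: int = 3,
                     sexes: dict[str, str] | None = None) -> pd.DataFrame:
    """Sample sheet for `groups` = {label: n_individuals}, complete series."""
    rows = []
    for grp, n in groups.items():
        for i in range(n):
            ind = f"{grp}{i + 1:02d}"
            sex = (sexes or {}).get(ind, "female" if i % 2 == 0 else "male")
            for t in range(1, n_timepoints + 1):
                rows.append({"sample_id": f"{ind}_T{t}", "individual_id": ind,
                             "group": grp, "timepoint": t, "sex": sex})
    return pd.DataFrame(rows).set_index("sample_id")


def make_expr(values: np.ndarray, genes, samples: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(values, index=list(genes), columns=samples.index),
                            samples)


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    """3 genes x 6 samples (2 individuals x 3 time points, one group)."""
    samples = make_samplesheet({"LCD": 2})
    values = np.array([
        [1.0, 2.0, 3.0, 2.0, 4.0, 6.0],
        [6.0, 4.0, 2.0, 6.0, 5.0, 4.0],
        [5.0, 5.0, 5.0, 1.0, 2.0, 10.0],
    ])
    return make_expr(values, ["g1", "g2", "g3"], samples)


def random_stack(rng: np.random.Generator, n_genes: int, n_individuals: int,
                 nan_frac: float = 0.0) -> IndividualCorrelationStack:
    """Random symmetric correlation matrices (uniform in [-1, 1], diagonal 1)."""
    genes = [f"g{i:02d}" for i in range(n_genes)]
    mats = {}
    for k in range(n_individuals):
        m = rng.uniform(-1, 1, (n_genes, n_genes))
        m = (m + m.T) / 2.0
        if nan_frac > 0:
            mask = rng.random((n_genes, n_genes)) < nan_frac
            mask |= mask.T
            m[mask] = np.nan
        np.fill_diagonal(m, 1.0)
        mats[f"ind{k:02d}"] = m
    return IndividualCorrelationStack(gene_ids=genes, matrices=mats)
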