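import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pyropattern.data_io import ClinicalTable, ExpressionMatrix


def make_expr(values, genes=None, samples=None, scale="log2", cohort=None):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return ExpressionMatrix(
        gene_ids=genes or [f"G{i}" for i in range(g)],
        sample_ids=samples or [f"S{j}" for j in range(n)],
        values=values,
        scale=scale,
        cohort=cohort,
    )


def make_clinical(times, events, sample_ids=None, **covariates):
    n = len(times)
    ids = sample_ids or [f"S{j}" for j in range(n)]
    df = pd.DataFrame(
        {"time": np.asarray(times, dtype=float), "event": np.asarray(events), **covariates},
        index=pd.Index(ids, name="sample_id"),
    )
    return ClinicalTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_expr(rng):
    return make_expr(rng.normal(5, 1, size=(20, 12)))
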