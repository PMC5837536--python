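import numpy as np
import pandas as pd
import pytest

from ivbalance import CohortTable, ColumnRoleMap, cohort_from_frame

TOY_ROLES = ColumnRoleMap(exposure_col="x", instrument_col="z", outcome_cols=("y",),
                          covariate_cols=("c",), cluster_col="doc")


def make_cohort(x, z, y, c, doc=None) -> CohortTable:
    """Assemble a small cohort from raw column arrays."""
    n = len(x)
    df = pd.DataFrame({"x": np.asarray(x, dtype=float),
                       "z": np.asarray(z, dtype=float),
                       "y": np.asarray(y, dtype=float),
                       "c": np.asarray(c, dtype=float),
                       "doc": np.arange(n) if doc is None else np.asarray(doc)})
    return cohort_from_frame(df, TOY_ROLES)


def random_cohort(rng, n=50, n_clusters=8) -> CohortTable:
    """Random binary-instrument table with both arms guaranteed present."""
    while True:
        x = (rng.random(n) < 0.4).astype(float)
        z = (rng.random(n) < 0.4).astype(float)
        if 0 < z.sum() < n and 0 < x.sum() < n:
            xz1 = x[z == 1].mean()
            xz0 = x[z == 0].mean()
            if xz1 != xz0:
                break
    c = rng.standard_normal(n) + 0.5 * x
    y = x + rng.standard_normal(n)
    doc = rng.integers(0, n_clusters, size=n)
    return make_cohort(x, z, y, c, doc)


@pytest.fixture
def rng():
    return np.random.default_rng(20170407)


@pytest.fixture
def toy_cohort():
    # 8 rows, two physicians, exposure/instrument imperfectly aligned
    return make_cohort(x=[1, 1, 0, 0, 1, 0, 0, 1],
                      z=[1, 0, 0, 0, 1, 1, 0, 1],
                      y=[2.0, 1.5, 0.3, 0.1, 1.9, 0.7, 0.2, 2.2],
                      c=[0.9, 0.8, 0.2, 0.1, 0.7, 0.4, 0.3, 1.0],
                      doc=[0, 0, 0, 0, 1, 1, 1, 1])
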