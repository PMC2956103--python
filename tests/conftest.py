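import numpy as np
import pandas as pd
import pytest

from tgx.io import DesignTable, ExpressionBundle, GeneSetCollection
from tgx.scoring import GeneChangeTable


def make_changes(effects, weights=None, condition_id="cond_1"):
    """GeneChangeTable from plain sequences, probes named p1..pn."""
    effects = np.asarray(effects, dtype=float)
    if weights is None:
        weights = np.ones_like(effects)
    idx = pd.Index([f"p{i + 1}" for i in range(effects.size)])
    return GeneChangeTable(condition_id=condition_id,
                           effects=pd.Series(effects, index=idx),
                           weights=pd.Series(np.asarray(weights, float), index=idx))


def exact_correlation_data(corr, n, seed=0):
    """n x p data whose *sample* correlation equals ``corr`` exactly.

    Random draws are whitened against their own empirical covariance and then
    recolored with the Cholesky factor of the target, so the construction is
    exact (up to floating point), not asymptotic.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, p))
    z -= z.mean(axis=0)
    emp = (z.T @ z) / (n - 1)
    z = z @ np.linalg.inv(np.linalg.cholesky(emp)).T
    x = z @ np.linalg.cholesky(corr).T
    return x


@pytest.fixture
def tiny_bundle():
    """2 probes x 4 samples with a clean +1 log2 effect on p1 in cond_1."""
    values = pd.DataFrame(
        [[8.0, 8.0, 9.0, 9.0],
         [5.0, 5.0, 5.0, 5.0]],
        index=["p1", "p2"], columns=["c1", "c2", "t1", "t2"])
    calls = pd.DataFrame(
        [["P", "P", "P", "P"],
         ["P", "P", "A", "A"]],
        index=["p1", "p2"], columns=["c1", "c2", "t1", "t2"])
    return ExpressionBundle(values=values, calls=calls)


@pytest.fixture
def tiny_design():
    rows = [
        {"sample_id": s, "condition_id": "cond_1",
         "role": "control" if s.startswith("c") else "treated",
         "compound": "cmpd", "dose": "high", "timepoint_h": 24.0}
        for s in ["c1", "c2", "t1", "t2"]
    ]
    return DesignTable(table=pd.DataFrame(rows))


@pytest.fixture
def tiny_sets():
    return GeneSetCollection(sets={"both": ["p1", "p2"], "only_p1": ["p1"]},
                             descriptions={"both": "", "only_p1": ""})
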