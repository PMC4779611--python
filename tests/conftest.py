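import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from dosagecomp.annotation import CountMatrix
from dosagecomp.normalization import ExpressionMatrix, rescale_quantile, rpkm_total
from dosagecomp.simulate import SimulationConfig, simulate


def make_annotation(chroms, starts=None, lengths=None):
    """Annotation frame from a list of chromosome labels."""
    n = len(chroms)
    starts = starts if starts is not None else [1000 * (i + 1) for i in range(n)]
    lengths = lengths if lengths is not None else [1000] * n
    return pd.DataFrame({
        "chromosome": chroms,
        "start": starts,
        "end": [s + 499 for s in starts],
        "strand": ["+"] * n,
        "exonic_length": lengths,
    }, index=[f"g{i}" for i in range(n)])


def make_expr(values, chroms=None, columns=None, samples=None):
    """ExpressionMatrix (+ optional annotation) from a plain array."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    columns = columns or [f"s{j}" for j in range(arr.shape[1])]
    genes = [f"g{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=genes, columns=columns)
    expr = ExpressionMatrix(values=df, method="total", samples=samples)
    if chroms is None:
        return expr
    return expr, make_annotation(chroms)


def sample_sheet(ids, sexes):
    return pd.DataFrame({
        "sex": sexes,
        "stage": ["pupa"] * len(ids),
        "time_point": [4.0] * len(ids),
        "replicate": list(range(1, len(ids) + 1)),
    }, index=pd.Index(ids, name="sample_id"))


def simulated_expression(config: SimulationConfig, seed=None, norm="uq"):
    """Simulate and normalize; returns (result, expr, males, females)."""
    res = simulate(config, seed=seed)
    expr = rpkm_total(res.counts, res.annotation["exonic_length"])
    if norm == "uq":
        expr = rescale_quantile(expr, 0.75)
    males = res.counts.samples_where(sex="male")
    females = res.counts.samples_where(sex="female")
    return res, expr, males, females


@pytest.fixture(scope="session")
def pupae_run():
    """One seeded complete-compensation dataset shared across tests."""
    from dosagecomp.simulate import preset

    return simulated_expression(preset("pupae_complete", seed=1))


@pytest.fixture
def toy_counts():
    counts = pd.DataFrame(
        {"m1": [100, 50, 10, 0], "f1": [200, 100, 20, 0]},
        index=["g0", "g1", "g2", "g3"],
    )
    return CountMatrix(counts=counts, samples=sample_sheet(["m1", "f1"], ["male", "female"]))
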