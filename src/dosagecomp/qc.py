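"""Divergent-replicate detection.

For each replicate r in a group, the statistic is the sum over genes of
squared expression (RPKM) differences to every other replicate:

    ssd(r) = sum_g sum_{r' != r} (x_{g,r} - x_{g,r'})^2

Its null distribution is obtained by permutation: each permutation
independently shuffles every gene's values across the replicates, which
preserves the per-gene value multiset while breaking any replicate-wide
shift.  P-values use the add-one convention p = (1 + #{perm >= obs}) /
(1 + n_perm), so they are never exactly zero.  Replicates with p below
``alpha`` (default 0.001) are flagged; downstream analyses are then run
both with and without the flagged replicates.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .normalization import ExpressionMatrix


class QCError(ValueError):
    pass


def _values(expr: ExpressionMatrix | pd.DataFrame, replicate_group: Sequence[str]) -> pd.DataFrame:
    frame = expr.values if isinstance(expr, ExpressionMatrix) else expr
    missing = [s for s in replicate_group if s not in frame.columns]
    if missing:
        raise QCError(f"replicates not in matrix: {missing}")
    return frame[list(replicate_group)]


def _ssd(v: np.ndarray) -> np.ndarray:
    """Per-replicate SSD for v of shape (..., genes, replicates)."""
    r = v.shape[-1]
    s = v.sum(axis=-1, keepdims=True)
    q = (v ** 2).sum(axis=-1, keepdims=True)
    # sum_{r'} (x_r - x_r')^2 = R x_r^2 - 2 x_r S + Q, summed over genes
    return (r * v ** 2 - 2 * v * s + q).sum(axis=-2)


def ssd_statistic(
    expr: ExpressionMatrix | pd.DataFrame,
    replicate_group: Sequence[str],
) -> pd.Series:
    """Sum of squared expression differences of each replicate to the rest."""
    vals = _values(expr, replicate_group)
    if vals.shape[1] < 2:
        raise QCError("need >= 2 replicates")
    if vals.shape[1] == 2:
        warnings.warn(
            "with 2 replicates both SSD values are equal; the test is uninformative"
        )
    return pd.Series(_ssd(vals.to_numpy(dtype=float)), index=vals.columns, name="ssd")


def permutation_test(
    expr: ExpressionMatrix | pd.DataFrame,
    replicate_group: Sequence[str],
    n_perm: int = 10_000,
    alpha: float = 0.001,
    seed: int | None = None,
    chunk: int = 500,
) -> pd.DataFrame:
    """Permutation test of the per-replicate SSD statistic.

    Returns one row per replicate: ssd, p_value, flagged, n_perm, seed.
    Deterministic for a fixed seed.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
    vals = _values(expr, replicate_group)
    observed = ssd_statistic(expr, replicate_group)
    v = vals.to_numpy(dtype=float)
    n_genes, n_rep = v.shape
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_rep, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n_genes, n_rep))
        idx = np.argsort(keys, axis=-1)
        perm = np.take_along_axis(np.broadcast_to(v, (b, n_genes, n_rep)), idx, axis=-1)
        perm_ssd = _ssd(perm)  # (b, n_rep)
        exceed += (perm_ssd >= observed.to_numpy()).sum(axis=0)
        done += b
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({
        "sample_id": list(vals.columns),
        "ssd": observed.to_numpy(),
        "p_value": p,
        "flagged": p < alpha,
        "n_perm": n_perm,
        "seed": seed,
    }).set_index("sample_id")
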