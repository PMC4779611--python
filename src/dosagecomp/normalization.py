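"""Count normalization: RPKM under three library-size definitions.

RPKM(g, s) = count(g, s) / (exonic length of g in kb * library size of s
in millions).  With the library size taken as the per-sample total count
this is total-count normalization; because total counts are dominated by
a handful of very highly expressed genes, the 75th-percentile
(upper-quartile) and median rescalings are provided as alternatives:
each sample is rescaled by the chosen quantile of its *positive* RPKM
values, anchored at the geometric mean of the per-sample quantiles so
that the overall output scale remains comparable to the input.

Also provides count-level depth resampling (binomial thinning, the
count-space analogue of re-sampling reads to a lower sequencing depth)
and MA values for between-sample diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import CountMatrix

METHOD_TOTAL = "total"
METHOD_UQ = "upper_quartile"
METHOD_MEDIAN = "median_scaled"


class NormalizationError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Normalized expression (RPKM), genes x samples, with provenance.

    ``method`` records which library-size definition produced the values;
    analyses must not mix methods.
    """

    values: pd.DataFrame
    method: str
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise NormalizationError("expression values must be finite")
        if (arr < 0).any():
            raise NormalizationError("expression values must be >= 0")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def sex_mean(self, sample_ids: list[str]) -> pd.Series:
        """Replicate-averaged expression profile over the given samples."""
        return self.values[list(sample_ids)].mean(axis=1)


def rpkm_total(
    counts: CountMatrix,
    lengths: Mapping[str, float] | pd.Series,
    library_sizes: Mapping[str, float] | pd.Series | None = None,
) -> ExpressionMatrix:
    """Convert counts to RPKM with total-count library sizes.

    Parameters
    ----------
    counts
        Raw count matrix.
    lengths
        Per-gene exon-union length in base pairs.
    library_sizes
        Per-sample mapped-read totals; default is the per-sample column
        sum of the count matrix.
    """
    lengths = pd.Series(lengths, dtype=float)
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise NormalizationError(f"genes without exonic length: {missing[:10]}")
    len_kb = lengths.loc[counts.gene_ids] / 1_000.0
    if (len_kb <= 0).any():
        bad = len_kb.index[len_kb <= 0].tolist()
        raise NormalizationError(f"non-positive gene lengths: {bad[:10]}")
    if library_sizes is None:
        lib = counts.counts.sum(axis=0).astype(float)
    else:
        lib = pd.Series(library_sizes, dtype=float).loc[counts.sample_ids]
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise NormalizationError(f"non-positive library sizes: {bad}")
    vals = counts.counts.div(len_kb, axis=0).div(lib / 1e6, axis=1)
    return ExpressionMatrix(values=vals, method=METHOD_TOTAL, samples=counts.samples)


def rescale_quantile(expr: ExpressionMatrix, q: float = 0.75) -> ExpressionMatrix:
    """Rescale each sample by a quantile of its positive values.

    ``q=0.75`` gives upper-quartile normalization, ``q=0.5`` median
    normalization.  The quantile is computed over positive values only
    (with deep zero-inflated data the raw percentile can be 0) by linear
    interpolation between order statistics, h = (n-1)q + 1.  Column s is
    multiplied by G / Q_s where G is the geometric mean of the per-sample
    quantiles, so within-analysis ratios are unchanged by the choice of
    anchor.
    """
    if expr.method != METHOD_TOTAL:
        raise NormalizationError("rescale_quantile expects total-count RPKM input")
    if not 0 < q < 1:
        raise NormalizationError("quantile must be in (0, 1)")
    qs = {}
    for s in expr.sample_ids:
        col = expr.values[s].to_numpy()
        pos = col[col > 0]
        if pos.size == 0:
            raise NormalizationError(f"sample {s} has no positive expression values")
        qs[s] = float(np.quantile(pos, q))  # linear interpolation rule
    qser = pd.Series(qs)
    anchor = float(np.exp(np.mean(np.log(qser.to_numpy()))))
    vals = expr.values.mul(anchor / qser, axis=1)
    method = METHOD_UQ if abs(q - 0.75) < 1e-12 else (
        METHOD_MEDIAN if abs(q - 0.5) < 1e-12 else f"quantile_{q:g}"
    )
    return ExpressionMatrix(values=vals, method=method, samples=expr.samples)


def downsample_counts(
    counts: CountMatrix,
    target_depth: int,
    seed: int | np.random.Generator | None = None,
) -> CountMatrix:
    """Binomially thin each sample's counts to a common target depth.

    Each count is replaced by Binomial(count, target_depth / column sum),
    which preserves expected RPKM while emulating sequencing at lower
    depth.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    depths = counts.counts.sum(axis=0)
    if (depths < target_depth).any():
        bad = depths.index[depths < target_depth].tolist()
        raise NormalizationError(
            f"target depth {target_depth} exceeds column sums of samples {bad}"
        )
    out = {}
    for s in counts.sample_ids:
        p = target_depth / depths[s] if depths[s] > 0 else 0.0
        col = counts.counts[s].to_numpy()
        if p >= 1.0:
            out[s] = col.copy()
        else:
            out[s] = rng.binomial(col, p)
    thinned = pd.DataFrame(out, index=counts.gene_ids)
    return CountMatrix(counts=thinned, samples=counts.samples)


def ma_values(
    expr: ExpressionMatrix,
    sample_a: str,
    sample_b: str,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-gene (A, M) pairs for an MA diagnostic plot.

    M = log2((a+pc)/(b+pc)); A = 0.5 * log2((a+pc)(b+pc)).  The default
    pseudocount 0.01 suits RPKM-scale values; use 1.0 on raw counts.
    """
    if pseudocount <= 0:
        raise NormalizationError("pseudocount must be > 0")
    for s in (sample_a, sample_b):
        if s not in expr.values.columns:
            raise NormalizationError(f"sample {s} not in expression matrix")
    a = expr.values[sample_a].to_numpy() + pseudocount
    b = expr.values[sample_b].to_numpy() + pseudocount
    m = np.log2(a / b)
    avg = 0.5 * np.log2(a * b)
    return pd.DataFrame({"A": avg, "M": m}, index=expr.gene_ids)
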