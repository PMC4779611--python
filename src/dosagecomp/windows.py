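"""Positional expression profiles along a chromosome.

Gene density and local X:A expression ratios are profiled in overlapping
windows (default 1 Mb, stepping 100 kb).  A gene belongs to a window if
its midpoint (rounded down) lies within it, so away from the chromosome
ends every gene is counted in exactly window/step windows.  The window
X:A ratio divides the median expression of the window's X-linked genes
by the median expression of *all* autosomal genes; windows with too few
expressed genes are flagged undefined rather than reported.

Coordinates are 1-based inclusive; windows start at 1, 1+step, ...
Trailing windows that extend past the chromosome end are emitted and
flagged partial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AUTOSOMES
from .normalization import ExpressionMatrix

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 100_000


class WindowError(ValueError):
    pass


@dataclass
class WindowProfile:
    """One sliding window: coordinates, gene counts, local X:A ratio."""

    window_start: int
    window_end: int
    partial: bool = False
    n_genes_at_threshold: dict[float, int] = field(default_factory=dict)
    window_xa_ratio: float = float("nan")
    n_window_genes_used: int = 0
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None


def _window_starts(chrom_length: int, window: int, step: int) -> list[int]:
    if step <= 0 or window < step:
        raise WindowError("require window >= step > 0")
    return list(range(1, int(chrom_length) + 1, step))


def _midpoints(annotation: pd.DataFrame) -> pd.Series:
    return (annotation["start"] + annotation["end"]) // 2


def window_density(
    annotation: pd.DataFrame,
    expr_values: pd.Series | None = None,
    chromosome: str = "X",
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    thresholds: Sequence[float] = (0.0,),
    chrom_length: int | None = None,
    assign: str = "midpoint",
) -> list[WindowProfile]:
    """Count genes expressed above each threshold in sliding windows.

    ``expr_values`` is a per-gene expression vector (replicate-averaged
    upstream); with ``None`` all genes count at every threshold <= 0.
    ``assign`` picks the gene->window rule: 'midpoint' (default),
    'start', or 'overlap' (gene counted in every window its span
    touches).
    """
    ann = annotation[annotation["chromosome"] == chromosome]
    if ann.empty:
        warnings.warn(f"no genes on chromosome {chromosome}; empty profile")
        return []
    if chrom_length is None:
        chrom_length = int(ann["end"].max())
    if assign == "midpoint":
        lo = hi = _midpoints(ann)
    elif assign == "start":
        lo = hi = ann["start"]
    elif assign == "overlap":
        lo, hi = ann["start"], ann["end"]
    else:
        raise WindowError(f"unknown assignment rule {assign!r}")
    expr = None
    if expr_values is not None:
        expr = expr_values.reindex(ann.index)
        if expr.isna().any():
            raise WindowError("expression vector missing genes on the chromosome")
    profiles = []
    for start in _window_starts(chrom_length, window, step):
        end = start + window - 1
        in_win = (hi.to_numpy() >= start) & (lo.to_numpy() <= end)
        counts = {}
        for t in thresholds:
            if expr is None:
                counts[float(t)] = int(in_win.sum()) if t <= 0 else 0
            else:
                counts[float(t)] = int((in_win & (expr.to_numpy() >= t)).sum())
        profiles.append(
            WindowProfile(
                window_start=start,
                window_end=end,
                partial=end > chrom_length,
                n_genes_at_threshold=counts,
            )
        )
    return profiles


def window_xa(
    annotation: pd.DataFrame,
    expr: ExpressionMatrix | pd.Series,
    samples: Sequence[str] | None = None,
    chromosome: str = "X",
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    threshold: float = 1.0,
    min_genes: int = 5,
    chrom_length: int | None = None,
    combine: str = "mean",
    assign: str = "midpoint",
) -> list[WindowProfile]:
    """Local X:A ratios: window X-gene median over global autosomal median.

    With an ExpressionMatrix and several samples, per-sample window
    ratios are combined across samples ('mean' or 'median' of the
    per-sample ratios).  Windows in which fewer than ``min_genes``
    expressed X genes fall (in any sample) are flagged undefined.
    """
    if isinstance(expr, pd.Series):
        cols = expr.to_frame("value")
    else:
        ids = list(samples) if samples is not None else expr.sample_ids
        cols = expr.values[ids]
    if combine not in ("mean", "median"):
        raise WindowError(f"unknown combine rule {combine!r}")

    ann_x = annotation[annotation["chromosome"] == chromosome]
    ann_a = annotation[annotation["chromosome"].isin(AUTOSOMES)]
    if ann_x.empty:
        warnings.warn(f"no genes on chromosome {chromosome}; empty profile")
        return []
    if ann_a.empty:
        raise WindowError("no autosomal genes available for the denominator")
    if chrom_length is None:
        chrom_length = int(ann_x["end"].max())

    if assign == "midpoint":
        lo = hi = _midpoints(ann_x).to_numpy()
    elif assign == "start":
        lo = hi = ann_x["start"].to_numpy()
    elif assign == "overlap":
        lo, hi = ann_x["start"].to_numpy(), ann_x["end"].to_numpy()
    else:
        raise WindowError(f"unknown assignment rule {assign!r}")

    auto_medians = {}
    for s in cols.columns:
        a = cols[s].reindex(ann_a.index).to_numpy(dtype=float)
        a = a[a >= threshold]
        if a.size == 0 or np.median(a) == 0:
            raise WindowError(f"autosomal median undefined or zero for sample {s}")
        auto_medians[s] = float(np.median(a))

    x_vals = {s: cols[s].reindex(ann_x.index).to_numpy(dtype=float) for s in cols.columns}

    profiles = []
    for start in _window_starts(chrom_length, window, step):
        end = start + window - 1
        in_win = (hi >= start) & (lo <= end)
        prof = WindowProfile(
            window_start=start, window_end=end, partial=end > chrom_length
        )
        per_sample = []
        n_used = []
        for s in cols.columns:
            v = x_vals[s][in_win]
            v = v[v >= threshold]
            n_used.append(v.size)
            if v.size < min_genes:
                per_sample.append(np.nan)
            else:
                per_sample.append(float(np.median(v)) / auto_medians[s])
        prof.n_window_genes_used = int(min(n_used)) if n_used else 0
        arr = np.asarray(per_sample, dtype=float)
        if np.isnan(arr).any():
            prof.undefined_reason = f"fewer_than_{min_genes}_expressed_genes"
        else:
            prof.window_xa_ratio = float(np.mean(arr) if combine == "mean" else np.median(arr))
        profiles.append(prof)
    return profiles


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n_windows: int
    undefined_reason: str | None = None


def density_departure_correlation(
    profiles: Sequence[WindowProfile],
    threshold: float | None = None,
) -> CorrelationResult:
    """Pearson correlation of window gene count with |log2(X:A ratio)|.

    Asks whether windows departing from ratio parity are the gene-poor
    ones.  Uses defined windows only; the gene count is the count at
    ``threshold`` if profiles carry one, else ``n_window_genes_used``.
    """
    xs, ys = [], []
    for p in profiles:
        if not p.defined or not np.isfinite(p.window_xa_ratio) or p.window_xa_ratio <= 0:
            continue
        if threshold is not None and threshold in p.n_genes_at_threshold:
            xs.append(p.n_genes_at_threshold[threshold])
        else:
            xs.append(p.n_window_genes_used)
        ys.append(abs(np.log2(p.window_xa_ratio)))
    n = len(xs)
    if n < 3:
        return CorrelationResult(float("nan"), float("nan"), n, "fewer_than_3_defined_windows")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, "zero_variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n)


def profiles_frame(profiles: Sequence[WindowProfile], chromosome: str = "X") -> pd.DataFrame:
    """Tabulate window profiles for TSV output."""
    rows = []
    for p in profiles:
        row = {
            "chromosome": chromosome,
            "window_start": p.window_start,
            "window_end": p.window_end,
            "partial": p.partial,
            "xa_ratio": p.window_xa_ratio,
            "n_window_genes_used": p.n_window_genes_used,
            "undefined_reason": p.undefined_reason or "",
        }
        for t, c in p.n_genes_at_threshold.items():
            row[f"n_genes_ge_{t:g}"] = c
        rows.append(row)
    return pd.DataFrame(rows)
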