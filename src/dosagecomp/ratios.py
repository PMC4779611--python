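"""Chromosome-wide expression-ratio analysis.

The central statistic is a ratio of median expression between gene sets
defined by chromosome: X:A (X over the pooled autosomes chr2+chr3) and,
as a null range for natural between-chromosome variation, chr3:2.  The
ratios are swept over minimum-expression thresholds because the set of
genes deemed "expressed" strongly influences dosage-compensation
inference.

Male:female contrasts come in two flavours:

* Method 1 — the ratio of the per-sex chromosomal ratios:
  (X:A in males) / (X:A in females);
* Method 2 — per-gene male:female ratios are computed first, and the
  estimate is the ratio of chromosomal *medians of per-gene ratios*.

Uncertainty is quantified by a stratified bootstrap: genes are resampled
with replacement independently within each chromosome stratum (stratum
sizes preserved), and the same resampled gene multiset is applied to
every sample entering the contrast so that the paired male/female
structure is preserved.  Confidence intervals are percentile intervals
over the bootstrap replicates.

Undefined ratios (empty gene set after filtering, zero denominator
median) are carried as flagged estimates, never silent NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import AUTOSOMES
from .normalization import ExpressionMatrix

#: numerator / denominator chromosome sets per ratio kind
RATIO_KINDS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "x_a": (("X",), ("chr2", "chr3")),
    "chr3_2": (("chr3",), ("chr2",)),
}

#: Default minimum-RPKM sweep grid; CIs are only meaningful for 0.2-15.
DEFAULT_THRESHOLDS = (0.0, 0.2, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0, 40.0)
DEFAULT_CI_RANGE = (0.2, 15.0)


class RatioError(ValueError):
    pass


@dataclass
class RatioEstimate:
    """One (ratio kind, threshold, contrast) cell of the analysis."""

    ratio_type: str
    sex_or_contrast: str
    threshold: float
    estimate: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_numerator_genes: int = 0
    n_denominator_genes: int = 0
    n_excluded_undefined: int = 0
    n_boot: int = 0
    level: float = 0.95
    seed: int | None = None
    undefined_reason: str | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["notes"] = ";".join(self.notes)
        return d


def select_genes(
    values: pd.DataFrame | pd.Series,
    threshold: float,
    scope: str = "per_sample",
) -> pd.DataFrame | pd.Series:
    """Boolean inclusion mask for a minimum-expression threshold.

    ``per_sample`` includes gene g for sample s iff value(g, s) >=
    threshold (a threshold of 0 keeps every gene, active or not);
    ``mean_over_samples`` uses one shared mask based on the row mean.
    """
    if threshold < 0:
        raise RatioError("threshold must be >= 0")
    if scope == "per_sample" or isinstance(values, pd.Series):
        return values >= threshold
    if scope == "mean_over_samples":
        return values.mean(axis=1) >= threshold
    raise RatioError(f"unknown scope {scope!r}")


def _check_kind(kind: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    if kind not in RATIO_KINDS:
        raise RatioError(f"unknown ratio kind {kind!r}; choose from {list(RATIO_KINDS)}")
    return RATIO_KINDS[kind]


def _profile(expr: ExpressionMatrix, samples: str | Sequence[str]) -> pd.Series:
    if isinstance(samples, str):
        samples = [samples]
    return expr.values[list(samples)].mean(axis=1)


def _median_ratio(num: np.ndarray, den: np.ndarray) -> float:
    return float(np.median(num) / np.median(den))


# ---------------------------------------------------------------------------
# Point estimators
# ---------------------------------------------------------------------------

def _strata_within(
    profile: pd.Series, chrom: pd.Series, kind: str, threshold: float
) -> dict[str, np.ndarray]:
    num, den = _check_kind(kind)
    keep = select_genes(profile, threshold)
    return {
        c: profile[keep & (chrom == c)].to_numpy(dtype=float)
        for c in (*num, *den)
    }


def chrom_ratio(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    samples: str | Sequence[str],
    kind: str = "x_a",
    threshold: float = 0.0,
    sex_or_contrast: str | None = None,
) -> RatioEstimate:
    """Within-sample ratio of median expression between chromosome sets.

    ``samples`` may be a single sample id or a list of replicates, which
    are arithmetically averaged before filtering and ratio computation.
    """
    num, den = _check_kind(kind)
    prof = _profile(expr, samples)
    chrom = annotation.loc[prof.index, "chromosome"]
    strata = _strata_within(prof, chrom, kind, threshold)
    label = sex_or_contrast or (samples if isinstance(samples, str) else "+".join(samples))
    est = RatioEstimate(ratio_type=kind, sex_or_contrast=label, threshold=threshold)
    return _finish_point(est, strata, num, den)


def _finish_point(
    est: RatioEstimate,
    strata: dict[str, np.ndarray],
    num: tuple[str, ...],
    den: tuple[str, ...],
) -> RatioEstimate:
    num_vals = np.concatenate([strata[c] for c in num]) if num else np.array([])
    den_vals = np.concatenate([strata[c] for c in den]) if den else np.array([])
    est.n_numerator_genes = int(sum(strata[c].size for c in num))
    est.n_denominator_genes = int(sum(strata[c].size for c in den))
    if num_vals.size == 0:
        est.undefined_reason = "empty_numerator_set"
        return est
    if den_vals.size == 0:
        est.undefined_reason = "empty_denominator_set"
        return est
    den_med = float(np.median(den_vals))
    if den_med == 0:
        est.undefined_reason = "zero_denominator_median"
        return est
    est.estimate = float(np.median(num_vals)) / den_med
    return est


def mf_ratio_method1(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    male_samples: Sequence[str],
    female_samples: Sequence[str],
    kind: str = "x_a",
    threshold: float = 0.0,
    filter_scope: str = "mean_of_sexes",
) -> RatioEstimate:
    """Male:female contrast as a ratio of per-sex chromosomal ratios.

    The per-sex ratios are computed on replicate-averaged expression; by
    default both sexes use the gene set whose male/female mean passes the
    threshold (``filter_scope='mean_of_sexes'``), so the two component
    ratios are computed on the same genes.  ``filter_scope='per_sex'``
    filters each sex on its own averaged profile instead.
    """
    num, den = _check_kind(kind)
    m = _profile(expr, male_samples)
    f = _profile(expr, female_samples)
    chrom = annotation.loc[m.index, "chromosome"]
    est = RatioEstimate(ratio_type=kind, sex_or_contrast="male_vs_female_m1", threshold=threshold)
    if filter_scope == "mean_of_sexes":
        keep = (m + f) / 2 >= threshold
        strata_m = {c: m[keep & (chrom == c)].to_numpy(float) for c in (*num, *den)}
        strata_f = {c: f[keep & (chrom == c)].to_numpy(float) for c in (*num, *den)}
    elif filter_scope == "per_sex":
        strata_m = _strata_within(m, chrom, kind, threshold)
        strata_f = _strata_within(f, chrom, kind, threshold)
    else:
        raise RatioError(f"unknown filter_scope {filter_scope!r}")
    male = _finish_point(
        RatioEstimate(ratio_type=kind, sex_or_contrast="male", threshold=threshold),
        strata_m, num, den,
    )
    female = _finish_point(
        RatioEstimate(ratio_type=kind, sex_or_contrast="female", threshold=threshold),
        strata_f, num, den,
    )
    est.n_numerator_genes = male.n_numerator_genes
    est.n_denominator_genes = male.n_denominator_genes
    for component in (male, female):
        if not component.defined:
            est.undefined_reason = f"{component.sex_or_contrast}:{component.undefined_reason}"
            return est
    if female.estimate == 0:
        est.undefined_reason = "zero_female_ratio"
        return est
    est.estimate = male.estimate / female.estimate
    return est


def _mf_gene_ratios(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    male_samples: Sequence[str],
    female_samples: Sequence[str],
    threshold: float,
) -> tuple[pd.Series, pd.Series, int]:
    """Per-gene M:F ratios on threshold-passing genes; returns (ratios,
    chromosomes, number of genes excluded for undefined ratio)."""
    m = _profile(expr, male_samples)
    f = _profile(expr, female_samples)
    keep = (m + f) / 2 >= threshold
    defined = f > 0
    n_undef = int((keep & ~defined).sum())
    sel = keep & defined
    ratios = (m[sel] / f[sel]).astype(float)
    chrom = annotation.loc[ratios.index, "chromosome"]
    return ratios, chrom, n_undef


def mf_ratio_method2(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    male_samples: Sequence[str],
    female_samples: Sequence[str],
    kind: str = "x_a",
    threshold: float = 0.0,
) -> RatioEstimate:
    """Male:female contrast via chromosomal medians of per-gene ratios.

    Genes with zero female expression have no defined ratio; they are
    excluded and counted in ``n_excluded_undefined``.
    """
    num, den = _check_kind(kind)
    ratios, chrom, n_undef = _mf_gene_ratios(
        expr, annotation, male_samples, female_samples, threshold
    )
    strata = {c: ratios[chrom == c].to_numpy(float) for c in (*num, *den)}
    est = RatioEstimate(ratio_type=kind, sex_or_contrast="male_vs_female_m2", threshold=threshold)
    est.n_excluded_undefined = n_undef
    return _finish_point(est, strata, num, den)


# ---------------------------------------------------------------------------
# Stratified bootstrap
# ---------------------------------------------------------------------------

def _boot_median_concat(
    arrays: Sequence[np.ndarray],
    idx: Sequence[np.ndarray],
) -> np.ndarray:
    """Median over the concatenation of per-stratum resampled arrays."""
    cols = [a[i] for a, i in zip(arrays, idx)]
    return np.median(np.concatenate(cols, axis=1), axis=1)


def bootstrap_ci(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    *,
    kind: str = "x_a",
    contrast: str = "within",
    samples: str | Sequence[str] | None = None,
    male_samples: Sequence[str] | None = None,
    female_samples: Sequence[str] | None = None,
    method: int = 1,
    threshold: float = 0.0,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    shared_resample: bool = True,
    gene_subset: pd.Index | None = None,
    chunk: int = 2_000,
    sex_or_contrast: str | None = None,
) -> RatioEstimate:
    """Point estimate plus stratified-bootstrap percentile CI.

    ``contrast='within'`` bootstraps the within-sex chromosomal ratio of
    ``samples``; ``contrast='male_vs_female'`` bootstraps the Method-1 or
    Method-2 male:female comparison.  Genes are resampled with
    replacement within chromosome strata; with ``shared_resample`` the
    same gene multiset is applied to both sexes (preserving pairing),
    otherwise the two sexes are resampled independently.
    """
    num, den = _check_kind(kind)
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI will be unstable")
    rng = np.random.default_rng(seed)

    if gene_subset is not None:
        expr = ExpressionMatrix(
            values=expr.values.loc[gene_subset], method=expr.method, samples=expr.samples
        )

    if contrast == "within":
        if samples is None:
            raise RatioError("contrast='within' requires samples")
        est = chrom_ratio(expr, annotation, samples, kind, threshold,
                          sex_or_contrast=sex_or_contrast)
        prof = _profile(expr, samples)
        chrom = annotation.loc[prof.index, "chromosome"]
        strata = _strata_within(prof, chrom, kind, threshold)
        paired = {c: (strata[c],) for c in strata}
        def stat(res: dict[str, tuple[np.ndarray, ...]], idx) -> np.ndarray:
            num_m = _boot_median_concat([res[c][0] for c in num], [idx[c] for c in num])
            den_m = _boot_median_concat([res[c][0] for c in den], [idx[c] for c in den])
            return num_m / den_m
    elif contrast == "male_vs_female":
        if male_samples is None or female_samples is None:
            raise RatioError("contrast='male_vs_female' requires male and female samples")
        if method == 1:
            est = mf_ratio_method1(expr, annotation, male_samples, female_samples, kind, threshold)
            m = _profile(expr, male_samples)
            f = _profile(expr, female_samples)
            chrom = annotation.loc[m.index, "chromosome"]
            keep = (m + f) / 2 >= threshold
            paired = {
                c: (
                    m[keep & (chrom == c)].to_numpy(float),
                    f[keep & (chrom == c)].to_numpy(float),
                )
                for c in (*num, *den)
            }
            def stat(res, idx):
                m_num = _boot_median_concat([res[c][0] for c in num], [idx[c][0] for c in num])
                m_den = _boot_median_concat([res[c][0] for c in den], [idx[c][0] for c in den])
                f_num = _boot_median_concat([res[c][1] for c in num], [idx[c][1] for c in num])
                f_den = _boot_median_concat([res[c][1] for c in den], [idx[c][1] for c in den])
                return (m_num / m_den) / (f_num / f_den)
        elif method == 2:
            est = mf_ratio_method2(expr, annotation, male_samples, female_samples, kind, threshold)
            ratios, chrom, _ = _mf_gene_ratios(expr, annotation, male_samples, female_samples, threshold)
            paired = {c: (ratios[chrom == c].to_numpy(float),) for c in (*num, *den)}
            def stat(res, idx):
                num_m = _boot_median_concat([res[c][0] for c in num], [idx[c] for c in num])
                den_m = _boot_median_concat([res[c][0] for c in den], [idx[c] for c in den])
                return num_m / den_m
        else:
            raise RatioError("method must be 1 or 2")
    else:
        raise RatioError(f"unknown contrast {contrast!r}")

    est.n_boot = n_boot
    est.level = level
    est.seed = seed
    if not est.defined:
        return est

    sizes = {c: paired[c][0].shape[0] for c in paired}
    if any(n == 1 for n in sizes.values()):
        est.notes.append("degenerate_stratum_size_1")

    # method-1 strata carry per-sex index tuples when resampling is unshared
    two_sided_m1 = contrast == "male_vs_female" and method == 1
    reps = np.empty(n_boot, dtype=float)
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = {}
        for c, n in sizes.items():
            if n == 0:
                empty = np.zeros((b, 0), dtype=np.intp)
                idx[c] = (empty, empty) if two_sided_m1 else empty
                continue
            shared = rng.integers(0, n, size=(b, n))
            if two_sided_m1:
                if shared_resample:
                    idx[c] = (shared, shared)
                else:
                    idx[c] = (shared, rng.integers(0, n, size=(b, n)))
            else:
                idx[c] = shared
        reps[done:done + b] = stat(paired, idx)
        done += b
    alpha = (1.0 - level) / 2.0
    est.ci_low = float(np.quantile(reps, alpha))
    est.ci_high = float(np.quantile(reps, 1.0 - alpha))
    return est


# ---------------------------------------------------------------------------
# Deciles, expressed fractions, threshold sweep
# ---------------------------------------------------------------------------

def decile_analysis(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    male_samples: Sequence[str],
    female_samples: Sequence[str],
    kind: str = "x_a",
    n_bins: int = 10,
    n_boot: int = 1_000,
    level: float = 0.95,
    seed: int | None = None,
) -> list[RatioEstimate]:
    """Method-2 M:F ratios with bootstrap CIs per expression decile.

    Genes are ranked by the mean of male and female replicate-averaged
    expression and split into ``n_bins`` equal-count bins (any remainder
    is spread over the lowest bins); bin 1 holds the lowest-expressed
    genes.
    """
    m = _profile(expr, male_samples)
    f = _profile(expr, female_samples)
    mean_expr = (m + f) / 2
    order = mean_expr.sort_values(kind="stable").index
    n = len(order)
    if n < n_bins:
        raise RatioError(f"need at least {n_bins} genes for {n_bins} bins")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if i < rem else base for i in range(n_bins)]
    out: list[RatioEstimate] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_bins)]
    pos = 0
    for i, size in enumerate(sizes):
        genes = order[pos:pos + size]
        pos += size
        est = bootstrap_ci(
            expr, annotation,
            kind=kind, contrast="male_vs_female", method=2,
            male_samples=male_samples, female_samples=female_samples,
            threshold=0.0, n_boot=n_boot, level=level,
            seed=child_seeds[i], gene_subset=genes,
        )
        est.threshold = float(i + 1)  # decile index, 1 = lowest expression
        est.sex_or_contrast = "male_vs_female_m2_decile"
        out.append(est)
    return out


def expressed_fraction(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    threshold: float,
    samples: str | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-chromosome fraction of genes at/above an expression threshold."""
    if threshold < 0:
        raise RatioError("threshold must be >= 0")
    prof = _profile(expr, samples if samples is not None else expr.sample_ids)
    chrom = annotation.loc[prof.index, "chromosome"]
    rows = []
    for c in sorted(chrom.unique()):
        vals = prof[chrom == c]
        n = len(vals)
        n_expr = int((vals >= threshold).sum())
        rows.append({
            "chromosome": c,
            "n_genes": n,
            "n_expressed": n_expr,
            "fraction": n_expr / n if n else float("nan"),
        })
    return pd.DataFrame(rows).set_index("chromosome")


def threshold_sweep(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    male_samples: Sequence[str],
    female_samples: Sequence[str],
    thresholds: Iterable[float] = DEFAULT_THRESHOLDS,
    kinds: Sequence[str] = ("x_a", "chr3_2"),
    methods: Sequence[int] = (1, 2),
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    ci_range: tuple[float, float] = DEFAULT_CI_RANGE,
) -> pd.DataFrame:
    """Full sweep of within-sex and M:F ratios over a threshold grid.

    Bootstrap CIs are computed only for thresholds inside ``ci_range``
    (outside it the intervals are not meaningful); elsewhere the point
    estimate is reported alone.  Returns one long-format row per
    (threshold, kind, contrast).
    """
    ss = np.random.SeedSequence(seed)
    rows = []

    def cell_seed() -> int:
        return int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))

    for threshold in thresholds:
        with_ci = ci_range[0] <= threshold <= ci_range[1] and n_boot > 0
        for kind in kinds:
            for sex, samp in (("male", male_samples), ("female", female_samples)):
                if with_ci:
                    est = bootstrap_ci(
                        expr, annotation, kind=kind, contrast="within",
                        samples=samp, threshold=threshold, n_boot=n_boot,
                        level=level, seed=cell_seed(), sex_or_contrast=sex,
                    )
                else:
                    est = chrom_ratio(expr, annotation, samp, kind, threshold,
                                      sex_or_contrast=sex)
                rows.append(est.to_dict())
            for method in methods:
                if with_ci:
                    est = bootstrap_ci(
                        expr, annotation, kind=kind, contrast="male_vs_female",
                        method=method, male_samples=male_samples,
                        female_samples=female_samples, threshold=threshold,
                        n_boot=n_boot, level=level, seed=cell_seed(),
                    )
                else:
                    fn = mf_ratio_method1 if method == 1 else mf_ratio_method2
                    est = fn(expr, annotation, male_samples, female_samples,
                             kind, threshold)
                rows.append(est.to_dict())
    return pd.DataFrame(rows)
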