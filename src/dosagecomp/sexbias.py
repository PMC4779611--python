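"""Per-gene sex-bias analysis and X-linkage enrichment.

A gene is male- or female-biased when it is differentially expressed
between the sexes (q-value below a cutoff, default 0.005) with a fold
change above 50% (ratio >= 1.5 or <= 2/3).  Externally supplied q-values
(e.g. from a dedicated differential-expression tool) take precedence;
otherwise a two-sided two-sample t test on log2(RPKM + pseudocount)
across replicates provides p-values, corrected by Benjamini-Hochberg.

Whether sex-biased genes avoid the X chromosome is tested with Fisher's
exact test on the 2x2 table (X / autosome) x (male- / female-biased),
under the null that bias direction is independent of linkage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import AUTOSOMES
from .normalization import ExpressionMatrix

DEFAULT_Q_CUT = 0.005
DEFAULT_FOLD_CUT = 1.5


class SexBiasError(ValueError):
    pass


def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise SexBiasError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mf_fold_table(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    male_samples: Sequence[str],
    female_samples: Sequence[str],
) -> pd.DataFrame:
    """Per-gene replicate-averaged expression and male:female fold.

    The fold is NaN where female expression is zero (undefined ratio).
    """
    m = expr.sex_mean(list(male_samples))
    f = expr.sex_mean(list(female_samples))
    fold = pd.Series(np.where(f > 0, m / f, np.nan), index=m.index)
    return pd.DataFrame({
        "chromosome": annotation.loc[m.index, "chromosome"],
        "male_expr": m,
        "female_expr": f,
        "mf_fold": fold,
    })


def ratio_histogram(
    folds: pd.Series | Sequence[float],
    bin_width: float = 0.02,
    expr_mask: pd.Series | None = None,
) -> pd.DataFrame:
    """Bin male:female ratios into half-open bins [k*w, (k+1)*w).

    Genes failing ``expr_mask`` (an expression-threshold mask) and genes
    with undefined ratios are excluded; the exclusion counts are recorded
    in DataFrame attrs.  Bin counts sum to the number of included genes.
    """
    if bin_width <= 0:
        raise SexBiasError("bin_width must be > 0")
    vals = pd.Series(folds, dtype=float)
    n_below = 0
    if expr_mask is not None:
        n_below = int((~expr_mask.reindex(vals.index, fill_value=False)).sum())
        vals = vals[expr_mask.reindex(vals.index, fill_value=False)]
    n_undefined = int(vals.isna().sum())
    vals = vals.dropna().to_numpy()
    if vals.size == 0:
        out = pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    else:
        k = np.floor(vals / bin_width).astype(int)
        uniq, counts = np.unique(k, return_counts=True)
        out = pd.DataFrame({
            "bin_left": uniq * bin_width,
            "bin_right": (uniq + 1) * bin_width,
            "count": counts,
        })
    out.attrs["n_included"] = int(vals.size)
    out.attrs["n_undefined"] = n_undefined
    out.attrs["n_below_threshold"] = n_below
    return out


def classify_bias(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    male_samples: Sequence[str],
    female_samples: Sequence[str],
    q_cut: float = DEFAULT_Q_CUT,
    fold_cut: float = DEFAULT_FOLD_CUT,
    external_q: pd.Series | None = None,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Classify every gene as male_biased / female_biased / unbiased.

    Classification requires q < ``q_cut`` and fold >= ``fold_cut`` (male)
    or <= 1/``fold_cut`` (female).  A gene silent in females but active
    in males has an undefined fold; it is classified by q-value and
    direction alone.  Genes silent in both sexes are 'undefined'.
    """
    male_samples, female_samples = list(male_samples), list(female_samples)
    table = mf_fold_table(expr, annotation, male_samples, female_samples)
    if external_q is not None:
        q = external_q.reindex(table.index)
        if q.isna().any():
            raise SexBiasError("external q-values missing for some genes")
        p = pd.Series(np.nan, index=table.index)
    else:
        if len(male_samples) < 2 or len(female_samples) < 2:
            raise SexBiasError(
                "need >= 2 replicates per sex to compute q-values in-house "
                "(or supply external_q)"
            )
        lm = np.log2(expr.values[male_samples].to_numpy() + pseudocount)
        lf = np.log2(expr.values[female_samples].to_numpy() + pseudocount)
        with warnings.catch_warnings():
            # silent genes have zero variance on both sides; their p is set to 1
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(lm, lf, axis=1)
        pvals = np.asarray(res.pvalue, dtype=float)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance ties
        p = pd.Series(pvals, index=table.index)
        q = pd.Series(bh_qvalues(p.to_numpy()), index=table.index)

    fold = table["mf_fold"]
    male_dir = table["male_expr"] > table["female_expr"]
    sig = q < q_cut
    fold_male = fold >= fold_cut
    fold_female = fold <= 1.0 / fold_cut
    undefined_fold = fold.isna()

    bias = np.full(len(table), "unbiased", dtype=object)
    bias[(sig & fold_male).to_numpy()] = "male_biased"
    bias[(sig & fold_female).to_numpy()] = "female_biased"
    # silent in females, active in males: fold undefined, direction male
    bias[(sig & undefined_fold & male_dir).to_numpy()] = "male_biased"
    silent_both = (table["male_expr"] == 0) & (table["female_expr"] == 0)
    bias[silent_both.to_numpy()] = "undefined"

    out = table.copy()
    out["p_value"] = p
    out["q_value"] = q
    out["bias_class"] = bias
    return out


@dataclass
class EnrichmentResult:
    """Fisher's exact test of bias direction vs X/autosomal linkage."""

    table: pd.DataFrame  # rows X/autosome, columns male_biased/female_biased
    odds_ratio: float
    p_value: float
    zero_cell: bool = False


def fisher_enrichment(records: pd.DataFrame) -> EnrichmentResult:
    """Test independence of male/female bias from X vs autosomal location.

    Unbiased and unplaced genes are excluded.  The two-sided p-value sums
    hypergeometric probabilities of tables as or less likely than the
    observed one; the odds ratio is the sample estimate ad/bc (flagged
    when a zero cell makes it 0 or infinite).
    """
    placed = records[records["chromosome"].isin(("X", *AUTOSOMES))]
    biased = placed[placed["bias_class"].isin(("male_biased", "female_biased"))]
    if biased.empty:
        raise SexBiasError("no sex-biased genes to test")
    is_x = biased["chromosome"] == "X"
    is_male = biased["bias_class"] == "male_biased"
    a = int((is_x & is_male).sum())
    b = int((is_x & ~is_male).sum())
    c = int((~is_x & is_male).sum())
    d = int((~is_x & ~is_male).sum())
    table = pd.DataFrame(
        [[a, b], [c, d]],
        index=["X", "autosome"],
        columns=["male_biased", "female_biased"],
    )
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        # ad/bc with a zero denominator: infinite unless numerator also 0
        odds = math.inf if a * d > 0 else float("nan")
        zero = True
    else:
        odds = (a * d) / (b * c)
        zero = a * d == 0
    return EnrichmentResult(table=table, odds_ratio=float(odds), p_value=float(res.pvalue), zero_cell=zero)


@dataclass
class RankSumResult:
    statistic: float
    p_value: float
    median_a: float
    median_b: float
    exact: bool


def compare_ratio_sets(
    ratios_a: Sequence[float],
    ratios_b: Sequence[float],
    exact_below: int = 20,
) -> RankSumResult:
    """Two-sided Mann-Whitney U comparison of two ratio sets.

    Used e.g. to ask whether candidate dosage-sensitive (CRP) genes shift
    toward female bias between early and late pupae.  Exact enumeration
    when the combined sample is small and tie-free, otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SexBiasError("each ratio set needs >= 2 values")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    use_exact = (a.size + b.size) < exact_below and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        exact=use_exact,
    )


def replicate_correlation(
    expr: ExpressionMatrix,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Spearman rank correlation between sample columns.

    Ties are mid-ranked.  Constant columns have no defined rank
    correlation; their pairs are NaN.
    """
    ids = list(samples) if samples is not None else expr.sample_ids
    if len(ids) < 2:
        raise SexBiasError("need >= 2 samples for pairwise correlation")
    vals = expr.values[ids].to_numpy(dtype=float)
    rho = stats.spearmanr(vals).statistic
    if np.isscalar(rho):  # spearmanr collapses 2-column input to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=ids, columns=ids)
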