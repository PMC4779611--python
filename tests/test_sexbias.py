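"""Sex-bias classification, enrichment, rank tests, correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dosagecomp.normalization import ExpressionMatrix
from dosagecomp.sexbias import (
    SexBiasError,
    bh_qvalues,
    classify_bias,
    compare_ratio_sets,
    fisher_enrichment,
    mf_fold_table,
    ratio_histogram,
    replicate_correlation,
)

from conftest import make_annotation, make_expr


# -- oracles ---------------------------------------------------------------

def oracle_bh(p):
    """Brute-force BH step-up: q_(i) = min_{j>=i} p_(j) m / j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    qs = [min(p[order[k]] * m / (k + 1), 1.0) for k in range(m)]
    for k in range(m - 2, -1, -1):
        qs[k] = min(qs[k], qs[k + 1])
    out = [0.0] * m
    for k, i in enumerate(order):
        out[i] = qs[k]
    return out


def oracle_fisher_two_sided(a, b, c, d):
    """Exhaustive hypergeometric enumeration (minimum-likelihood rule)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


def oracle_spearman(x, y):
    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        sv = np.array(v)[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = midranks(x), midranks(y)
    rxm, rym = rx - rx.mean(), ry - ry.mean()
    return (rxm * rym).sum() / np.sqrt((rxm**2).sum() * (rym**2).sum())


# -- BH --------------------------------------------------------------------

def test_bh_step_up_examples():
    np.testing.assert_allclose(bh_qvalues([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(bh_qvalues([0.37]), [0.37])
    with pytest.raises(SexBiasError):
        bh_qvalues([1.2])


def test_bh_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        p = rng.random(size=rng.integers(1, 25)).tolist()
        np.testing.assert_allclose(bh_qvalues(p), oracle_bh(p), atol=1e-12)


# -- histogram -------------------------------------------------------------

def test_ratio_histogram_binning_and_conservation():
    folds = pd.Series([1.013, 1.013, 0.5, 2.5, np.nan], index=[f"g{i}" for i in range(5)])
    hist = ratio_histogram(folds, bin_width=0.02)
    row = hist[np.isclose(hist["bin_left"], 1.00)]
    assert row["count"].iloc[0] == 2  # 1.013 lands in [1.00, 1.02)
    assert hist["count"].sum() == hist.attrs["n_included"] == 4
    assert hist.attrs["n_undefined"] == 1

    # invariant under permutation of the input
    hist2 = ratio_histogram(folds.sample(frac=1.0, random_state=1), bin_width=0.02)
    pd.testing.assert_frame_equal(
        hist.sort_values("bin_left").reset_index(drop=True),
        hist2.sort_values("bin_left").reset_index(drop=True),
    )


def test_ratio_histogram_single_bin_and_empty():
    hist = ratio_histogram(pd.Series([1.5, 1.5, 1.5]), bin_width=0.02)
    assert len(hist) == 1 and hist["count"].iloc[0] == 3
    empty = ratio_histogram(pd.Series([], dtype=float))
    assert len(empty) == 0


# -- classification --------------------------------------------------------

def _biased_dataset(rng, n=200, n_rep=4):
    chroms = ["X"] * 30 + ["chr2"] * 90 + ["chr3"] * 80
    base = np.exp(rng.normal(np.log(50), 0.2, size=n))
    male_fold = np.ones(n)
    male_fold[:10] = 6.0      # X male-biased block (genes g0..g9)
    male_fold[30:40] = 1.0 / 6.0  # chr2 female-biased block
    male = base * male_fold
    noise = lambda: np.exp(rng.normal(0, 0.05, size=(n, n_rep)))
    mvals = male[:, None] * noise()
    fvals = base[:, None] * noise()
    cols = [f"m{i}" for i in range(n_rep)] + [f"f{i}" for i in range(n_rep)]
    expr, ann = make_expr(np.column_stack([mvals, fvals]), chroms=chroms, columns=cols)
    return expr, ann, cols[:n_rep], cols[n_rep:]


def test_classify_bias_rule_application():
    expr, ann, males, females = _biased_dataset(np.random.default_rng(1))
    recs = classify_bias(expr, ann, males, females)
    assert set(recs["bias_class"]) <= {"male_biased", "female_biased", "unbiased", "undefined"}
    # each gene has exactly one class (partition)
    assert len(recs) == 200
    assert (recs.loc[[f"g{i}" for i in range(10)], "bias_class"] == "male_biased").all()
    assert (recs.loc[[f"g{i}" for i in range(30, 40)], "bias_class"] == "female_biased").all()
    assert (recs["q_value"].between(0, 1)).all()


def test_classify_bias_fold_rule_blocks_weak_folds():
    # q significant but fold below 1.5x -> unbiased
    rng = np.random.default_rng(2)
    n_rep = 6
    base = np.full((20, n_rep), 50.0)
    male = base * 1.4 * np.exp(rng.normal(0, 0.01, size=(20, n_rep)))
    female = base * np.exp(rng.normal(0, 0.01, size=(20, n_rep)))
    cols = [f"m{i}" for i in range(n_rep)] + [f"f{i}" for i in range(n_rep)]
    expr, ann = make_expr(np.column_stack([male, female]),
                          chroms=["chr2"] * 20, columns=cols)
    recs = classify_bias(expr, ann, cols[:n_rep], cols[n_rep:])
    sig = recs[recs["q_value"] < 0.005]
    assert len(sig) > 0
    assert (sig["bias_class"] == "unbiased").all()  # 1.4 < 1.5 fold cutoff


def test_classify_bias_external_q_and_zero_female():
    male = np.array([[10.0, 12.0], [8.0, 9.0]])
    female = np.array([[0.0, 0.0], [8.0, 9.0]])
    expr, ann = make_expr(np.column_stack([male, female]),
                          chroms=["X", "chr2"], columns=["m1", "m2", "f1", "f2"])
    q = pd.Series([1e-4, 0.9], index=["g0", "g1"])
    recs = classify_bias(expr, ann, ["m1", "m2"], ["f1", "f2"], external_q=q)
    assert np.isnan(recs.loc["g0", "mf_fold"])  # undefined fold
    assert recs.loc["g0", "bias_class"] == "male_biased"  # by q + direction
    assert recs.loc["g1", "bias_class"] == "unbiased"


def test_classify_bias_needs_replicates_without_external_q():
    expr, ann = make_expr([[1.0, 2.0]], chroms=["chr2"], columns=["m1", "f1"])
    with pytest.raises(SexBiasError, match="replicates"):
        classify_bias(expr, ann, ["m1"], ["f1"])


# -- Fisher ----------------------------------------------------------------

def records_from_table(a, b, c, d):
    rows = (
        [("X", "male_biased")] * a + [("X", "female_biased")] * b
        + [("chr2", "male_biased")] * c + [("chr2", "female_biased")] * d
    )
    return pd.DataFrame(rows, columns=["chromosome", "bias_class"])


def test_fisher_worked_example():
    res = fisher_enrichment(records_from_table(3, 1, 1, 3))
    assert res.p_value == pytest.approx(34 / 70, abs=1e-10)  # enumeration: 0.4857
    assert res.odds_ratio == pytest.approx(9.0)


def test_fisher_no_association_gives_p_one():
    res = fisher_enrichment(records_from_table(2, 2, 4, 4))
    assert res.p_value == pytest.approx(1.0)


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(3)
    for _ in range(60):
        a, b, c, d = rng.integers(0, 15, size=4)
        if (a + b == 0) or (c + d == 0) or (a + b + c + d == 0):
            continue
        res = fisher_enrichment(records_from_table(a, b, c, d))
        want = oracle_fisher_two_sided(int(a), int(b), int(c), int(d))
        assert res.p_value == pytest.approx(want, abs=1e-10)


def test_fisher_zero_cell_flag():
    res = fisher_enrichment(records_from_table(0, 5, 9, 6))
    assert res.zero_cell


# -- Mann-Whitney ----------------------------------------------------------

def test_ranksum_exact_small_sets():
    res = compare_ratio_sets([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert res.exact
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    same = compare_ratio_sets([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert same.p_value == pytest.approx(1.0)


def test_ranksum_detects_shift():
    rng = np.random.default_rng(4)
    hits = 0
    for s in range(20):
        a = rng.normal(0, 1, size=50)
        b = rng.normal(1, 1, size=50)
        if compare_ratio_sets(a, b).p_value < 0.01:
            hits += 1
    assert hits >= 18  # >= 90% power at delta = 1 sd


def test_ranksum_requires_two_values():
    with pytest.raises(SexBiasError):
        compare_ratio_sets([1.0], [2.0, 3.0])


# -- correlations ----------------------------------------------------------

def test_replicate_correlation_identity_and_reversal():
    vals = np.arange(10, dtype=float)
    expr = make_expr(np.column_stack([vals, vals, vals[::-1]]),
                     columns=["a", "b", "c"])
    rho = replicate_correlation(expr)
    assert rho.loc["a", "a"] == 1.0
    assert rho.loc["a", "b"] == pytest.approx(1.0)
    assert rho.loc["a", "c"] == pytest.approx(-1.0)


def test_spearman_matches_bruteforce_with_ties():
    rng = np.random.default_rng(5)
    for _ in range(30):
        x = rng.integers(0, 10, size=50).astype(float)  # ties guaranteed
        y = np.round(x * 0.5 + rng.gamma(2.0, 1.0, size=50), 1)
        expr = make_expr(np.column_stack([x, y]), columns=["a", "b"])
        rho = replicate_correlation(expr).loc["a", "b"]
        assert rho == pytest.approx(oracle_spearman(x, y), abs=1e-10)


def test_mf_fold_table_marks_undefined():
    expr, ann = make_expr([[4.0, 2.0], [3.0, 0.0]], chroms=["chr2", "X"],
                          columns=["m1", "f1"])
    table = mf_fold_table(expr, ann, ["m1"], ["f1"])
    assert table.loc["g0", "mf_fold"] == pytest.approx(2.0)
    assert np.isnan(table.loc["g1", "mf_fold"])
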