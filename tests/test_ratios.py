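"""Median-ratio estimators, stratified bootstrap, deciles, fractions."""

import statistics

import numpy as np
import pandas as pd
import pytest

from dosagecomp.ratios import (
    RatioError,
    bootstrap_ci,
    chrom_ratio,
    decile_analysis,
    expressed_fraction,
    mf_ratio_method1,
    mf_ratio_method2,
    select_genes,
    threshold_sweep,
)

from conftest import make_annotation, make_expr


def oracle_chrom_ratio(values, chroms, num, den, threshold):
    nv = [v for v, c in zip(values, chroms) if c in num and v >= threshold]
    dv = [v for v, c in zip(values, chroms) if c in den and v >= threshold]
    return statistics.median(nv) / statistics.median(dv)


def test_select_genes_rules():
    expr = make_expr([[0.5, 2.0], [1.0, 1.0], [3.0, 0.0]])
    mask = select_genes(expr.values, 1.0, "per_sample")
    assert mask.loc["g0", "s0"] == False and mask.loc["g0", "s1"] == True
    assert mask.loc["g1", "s0"] == True  # boundary: >= rule
    shared = select_genes(expr.values, 1.0, "mean_over_samples")
    assert shared.tolist() == [True, True, True]
    assert select_genes(expr.values, 0.0).all().all()  # threshold 0 keeps all
    with pytest.raises(RatioError):
        select_genes(expr.values, -1.0)


def test_chrom_ratio_hand_example():
    # X medians {2,4,6} -> 4; autosomes {2,4,6,8} -> 5
    expr, ann = make_expr(
        [2, 4, 6, 2, 4, 6, 8], chroms=["X"] * 3 + ["chr2", "chr2", "chr3", "chr3"]
    )
    est = chrom_ratio(expr, ann, "s0", "x_a")
    assert est.estimate == pytest.approx(0.8)
    assert est.n_numerator_genes == 3 and est.n_denominator_genes == 4


def test_chrom_ratio_identity_and_undefined():
    expr, ann = make_expr([1, 2, 3, 1, 2, 3], chroms=["chr3"] * 3 + ["chr2"] * 3)
    assert chrom_ratio(expr, ann, "s0", "chr3_2").estimate == pytest.approx(1.0)

    # all X genes below the threshold -> flagged, not silent NaN
    expr2, ann2 = make_expr([0.1, 5, 6], chroms=["X", "chr2", "chr3"])
    est = chrom_ratio(expr2, ann2, "s0", "x_a", threshold=1.0)
    assert not est.defined and est.undefined_reason == "empty_numerator_set"

    # zero denominator median is flagged
    expr3, ann3 = make_expr([1, 0, 0, 0], chroms=["X", "chr2", "chr2", "chr3"])
    est3 = chrom_ratio(expr3, ann3, "s0", "x_a")
    assert est3.undefined_reason == "zero_denominator_median"


def test_chrom_ratio_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = 12
        chroms = rng.choice(["X", "chr2", "chr3"], size=n).tolist()
        if len(set(chroms)) < 3:
            continue
        vals = rng.gamma(2.0, 5.0, size=n)
        expr, ann = make_expr(vals, chroms=chroms)
        got = chrom_ratio(expr, ann, "s0", "x_a").estimate
        want = oracle_chrom_ratio(vals, chroms, {"X"}, {"chr2", "chr3"}, 0.0)
        assert got == pytest.approx(want, abs=1e-12)


def test_chrom_ratio_scale_invariant():
    rng = np.random.default_rng(3)
    vals = rng.gamma(2.0, 5.0, size=20)
    chroms = (["X"] * 5 + ["chr2"] * 8 + ["chr3"] * 7)
    a = chrom_ratio(*make_expr(vals, chroms=chroms), "s0").estimate
    b = chrom_ratio(*make_expr(vals * 7.3, chroms=chroms), "s0").estimate
    assert a == pytest.approx(b, rel=1e-12)


def _mf_setup(rng, n=30):
    chroms = (["X"] * 8 + ["chr2"] * 11 + ["chr3"] * 11)[:n]
    male = rng.gamma(2.0, 5.0, size=n) + 0.5
    female = rng.gamma(2.0, 5.0, size=n) + 0.5
    expr, ann = make_expr(np.column_stack([male, female]), chroms=chroms,
                          columns=["m1", "f1"])
    return expr, ann, male, female, chroms


def test_mf_method1_identity_and_doubling():
    expr, ann, male, _, chroms = _mf_setup(np.random.default_rng(4))
    same, ann2 = make_expr(np.column_stack([male, male]), chroms=chroms, columns=["m1", "f1"])
    assert mf_ratio_method1(same, ann2, ["m1"], ["f1"]).estimate == pytest.approx(1.0)
    # doubling male X genes doubles the Method-1 contrast
    doubled = male.copy()
    doubled[:8] *= 2
    expr3, _ = make_expr(np.column_stack([doubled, male]), chroms=chroms, columns=["m1", "f1"])
    assert mf_ratio_method1(expr3, ann2, ["m1"], ["f1"]).estimate == pytest.approx(2.0)


def test_mf_method1_matches_composed_oracle():
    rng = np.random.default_rng(5)
    for _ in range(30):
        expr, ann, male, female, chroms = _mf_setup(rng)
        got = mf_ratio_method1(expr, ann, ["m1"], ["f1"]).estimate
        want = (
            oracle_chrom_ratio(male, chroms, {"X"}, {"chr2", "chr3"}, 0.0)
            / oracle_chrom_ratio(female, chroms, {"X"}, {"chr2", "chr3"}, 0.0)
        )
        assert got == pytest.approx(want, abs=1e-12)


def test_mf_method2_examples_and_oracle():
    # per-gene X ratios {1.0, 0.8, 1.2}; autosomal all 1.0 -> estimate 1.0
    male = np.array([1.0, 0.8, 1.2, 1, 1, 1, 1])
    female = np.ones(7)
    chroms = ["X"] * 3 + ["chr2", "chr2", "chr3", "chr3"]
    expr, ann = make_expr(np.column_stack([male, female]), chroms=chroms, columns=["m1", "f1"])
    assert mf_ratio_method2(expr, ann, ["m1"], ["f1"]).estimate == pytest.approx(1.0)

    rng = np.random.default_rng(6)
    for _ in range(30):
        expr, ann, male, female, chroms = _mf_setup(rng)
        got = mf_ratio_method2(expr, ann, ["m1"], ["f1"]).estimate
        ratios = male / female
        want = oracle_chrom_ratio(ratios, chroms, {"X"}, {"chr2", "chr3"}, -np.inf)
        assert got == pytest.approx(want, abs=1e-12)


def test_mf_method2_counts_undefined_ratios():
    male = np.array([2.0, 3.0, 1, 1, 1])
    female = np.array([0.0, 1.0, 1, 1, 1])  # g0 undefined M:F
    chroms = ["X", "X", "chr2", "chr3", "chr3"]
    expr, ann = make_expr(np.column_stack([male, female]), chroms=chroms, columns=["m1", "f1"])
    est = mf_ratio_method2(expr, ann, ["m1"], ["f1"])
    assert est.n_excluded_undefined == 1
    assert est.n_numerator_genes == 1


def test_bootstrap_degenerate_all_equal_collapses_ci():
    expr, ann = make_expr([5.0] * 12, chroms=["X"] * 4 + ["chr2"] * 4 + ["chr3"] * 4)
    est = bootstrap_ci(expr, ann, kind="x_a", contrast="within", samples="s0",
                       n_boot=200, seed=0)
    assert est.estimate == pytest.approx(1.0)
    assert est.ci_low == est.ci_high == pytest.approx(1.0)


def test_bootstrap_deterministic_for_fixed_seed():
    rng = np.random.default_rng(7)
    vals = rng.gamma(2.0, 5.0, size=40)
    chroms = ["X"] * 10 + ["chr2"] * 15 + ["chr3"] * 15
    expr, ann = make_expr(vals, chroms=chroms)
    a = bootstrap_ci(expr, ann, kind="x_a", contrast="within", samples="s0", n_boot=500, seed=9)
    b = bootstrap_ci(expr, ann, kind="x_a", contrast="within", samples="s0", n_boot=500, seed=9)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
    assert a.ci_low <= a.estimate <= a.ci_high


def test_bootstrap_small_n_boot_warns():
    expr, ann = make_expr([1.0] * 9, chroms=["X"] * 3 + ["chr2"] * 3 + ["chr3"] * 3)
    with pytest.warns(UserWarning, match="n_boot"):
        bootstrap_ci(expr, ann, kind="x_a", contrast="within", samples="s0",
                     n_boot=50, seed=0)


def test_decile_partition_arithmetic():
    rng = np.random.default_rng(8)
    n = 20
    chroms = (["X"] * 6 + ["chr2"] * 7 + ["chr3"] * 7)
    male = rng.gamma(2.0, 5.0, size=n) + 0.5
    expr, ann = make_expr(np.column_stack([male, male]), chroms=chroms, columns=["m1", "f1"])
    out = decile_analysis(expr, ann, ["m1"], ["f1"], n_boot=100, seed=0)
    assert len(out) == 10
    # 20 genes -> deciles of exactly 2; male == female -> estimate 1 where defined
    for est in out:
        n_genes = est.n_numerator_genes + est.n_denominator_genes
        assert n_genes == 2 or not est.defined
        if est.defined:
            assert est.estimate == pytest.approx(1.0)


def test_decile_recovers_planted_expression_dependence():
    # compensation only above the expression median: low deciles ~0.5, high ~1.0
    rng = np.random.default_rng(9)
    n_x, n_a = 120, 400
    base_x = np.sort(rng.gamma(3.0, 4.0, size=n_x)) + 0.5
    base_a = rng.gamma(3.0, 4.0, size=n_a) + 0.5
    c = np.where(np.arange(n_x) < n_x // 2, 0.5, 1.0)  # sorted: low half uncompensated
    male = np.concatenate([base_x * c, base_a])
    female = np.concatenate([base_x, base_a])
    chroms = ["X"] * n_x + ["chr2"] * (n_a // 2) + ["chr3"] * (n_a - n_a // 2)
    expr, ann = make_expr(np.column_stack([male, female]), chroms=chroms, columns=["m1", "f1"])
    out = decile_analysis(expr, ann, ["m1"], ["f1"], n_boot=200, seed=1)
    low = [e.estimate for e in out[:3] if e.defined]
    high = [e.estimate for e in out[-3:] if e.defined]
    assert np.mean(low) < 0.7
    assert np.mean(high) > 0.85


def test_expressed_fraction_counts():
    expr, ann = make_expr(
        [5, 0.5, 2, 0.1, 9, 0], chroms=["X", "X", "X", "chr2", "chr2", "chr3"]
    )
    out = expressed_fraction(expr, ann, threshold=1.0)
    assert out.loc["X", "fraction"] == pytest.approx(2 / 3)
    assert out.loc["chr2", "fraction"] == pytest.approx(0.5)
    assert out.loc["chr3", "fraction"] == 0.0
    all_in = expressed_fraction(expr, ann, threshold=0.0)
    assert (all_in["fraction"] == 1.0).all()


def test_expressed_fraction_matches_bruteforce():
    rng = np.random.default_rng(10)
    vals = rng.gamma(1.0, 3.0, size=30)
    chroms = rng.choice(["X", "chr2", "chr3"], size=30).tolist()
    expr, ann = make_expr(vals, chroms=chroms)
    out = expressed_fraction(expr, ann, threshold=2.0)
    for c in set(chroms):
        members = [v for v, ch in zip(vals, chroms) if ch == c]
        want = sum(v >= 2.0 for v in members) / len(members)
        assert out.loc[c, "fraction"] == pytest.approx(want, abs=1e-15)


def test_threshold_monotone_gene_counts(pupae_run):
    _, expr, males, _ = pupae_run
    res, ann = None, None
    prev = None
    annotation = pupae_run[0].annotation
    for t in (0.0, 0.5, 1.0, 5.0, 20.0):
        est = chrom_ratio(expr, annotation, males, "x_a", t)
        n = est.n_numerator_genes + est.n_denominator_genes
        if prev is not None:
            assert n <= prev
        prev = n


def test_threshold_sweep_shape_and_ci_range(pupae_run):
    res, expr, males, females = pupae_run
    sweep = threshold_sweep(
        expr, res.annotation, males, females,
        thresholds=(0.0, 1.0, 40.0), n_boot=200, seed=0,
    )
    # 3 thresholds x 2 kinds x (male, female, m1, m2)
    assert len(sweep) == 24
    inside = sweep[sweep["threshold"] == 1.0]
    assert inside["ci_low"].notna().all()
    outside = sweep[sweep["threshold"] == 0.0]
    assert outside["ci_low"].isna().all()  # CI suppressed outside 0.2-15
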