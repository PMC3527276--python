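"""Exact-test machinery against enumeration, scipy and statsmodels oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as hst
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from shdrop.model import SAMPLE_COLUMNS, CountMatrix, Genotype, PipelineConfig
from shdrop.stats import (
    Contingency2x2,
    bh_adjust,
    build_table,
    cmle_odds_ratio,
    exact_ci,
    fisher_two_sided,
    fold_depletion,
    run_stats,
)

# ---------------------------------------------------------------- oracles


def enum_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact-fraction enumeration of the full support."""
    n1, n2, m1 = a + b, c + d, a + c
    total = math.comb(n1 + n2, m1)
    probs = {
        x: Fraction(math.comb(n1, x) * math.comb(n2, m1 - x), total)
        for x in range(max(0, m1 - n2), min(n1, m1) + 1)
    }
    threshold = probs[a] * Fraction(10**7 + 1, 10**7)
    return float(min(sum(p for p in probs.values() if p <= threshold), Fraction(1)))


def noncentral_tail(table: Contingency2x2, psi: float, upper: bool) -> float:
    """P_psi(A >= a) or P_psi(A <= a), summed in log space from exact binomials."""
    a, n1, n2 = table.a, table.n_t0, table.n_t10
    m1 = table.a + table.c
    log_psi = math.log(psi)
    xs = range(max(0, m1 - n2), min(n1, m1) + 1)
    logs = [
        math.log(math.comb(n1, x)) + math.log(math.comb(n2, m1 - x)) + x * log_psi
        for x in xs
    ]
    peak = max(logs)
    z = sum(math.exp(v - peak) for v in logs)
    sel = sum(
        math.exp(v - peak)
        for x, v in zip(xs, logs)
        if (x >= a if upper else x <= a)
    )
    return sel / z


def conditional_loglik(table: Contingency2x2, log_psi: float) -> float:
    a, n1, n2 = table.a, table.n_t0, table.n_t10
    m1 = table.a + table.c
    xs = range(max(0, m1 - n2), min(n1, m1) + 1)
    logs = [
        math.log(math.comb(n1, x)) + math.log(math.comb(n2, m1 - x)) + x * log_psi
        for x in xs
    ]
    peak = max(logs)
    logz = peak + math.log(sum(math.exp(v - peak) for v in logs))
    return (
        math.log(math.comb(n1, a)) + math.log(math.comb(n2, m1 - a)) + a * log_psi - logz
    )


def tables(max_cell=20):
    cell = hst.integers(min_value=0, max_value=max_cell)
    return (
        hst.tuples(cell, cell, cell, cell)
        .filter(lambda t: t[0] + t[1] > 0 and t[2] + t[3] > 0)
        .map(lambda t: Contingency2x2(*t))
    )


# ---------------------------------------------------------------- build_table


def _matrix_from_counts(t0_plus, t10_plus, t0_minus, t10_minus, ids):
    import pandas as pd

    idx = pd.Index(ids, name="shrna_id")
    counts = pd.DataFrame(
        np.column_stack([t0_plus, t10_plus, t0_minus, t10_minus]),
        index=idx,
        columns=list(SAMPLE_COLUMNS),
    )
    return CountMatrix(counts, pd.Series(["g"] * len(ids), index=idx, name="gene_id"))


def test_build_table_arithmetic():
    m = _matrix_from_counts([10, 90], [2, 48], [1, 9], [1, 9], ["x", "y"])
    t = build_table(m, "x", Genotype.P53_PLUS)
    assert t.cells() == (10, 90, 2, 48)
    t0 = build_table(m, "y", Genotype.P53_MINUS)
    assert t0.cells() == (9, 1, 9, 1)


def test_build_table_zero_count_shrna():
    m = _matrix_from_counts([0, 100], [3, 47], [1, 9], [1, 9], ["x", "y"])
    assert build_table(m, "x", Genotype.P53_PLUS).cells() == (0, 100, 3, 47)


def test_build_table_errors():
    m = _matrix_from_counts([1], [1], [0], [0], ["x"])
    with pytest.raises(KeyError):
        build_table(m, "nope", Genotype.P53_PLUS)
    with pytest.raises(ValueError, match="zero sample total"):
        build_table(m, "x", Genotype.P53_MINUS)
    with pytest.raises(ValueError, match="negative"):
        Contingency2x2(1, -1, 0, 0)


# ---------------------------------------------------------------- fisher


def test_fisher_balanced_table_is_one():
    assert fisher_two_sided(Contingency2x2(5, 95, 5, 95)) == 1.0


def test_fisher_tea_tasting_table():
    p = fisher_two_sided(Contingency2x2(3, 1, 1, 3))
    assert p == pytest.approx(34 / 70, abs=1e-12)


@given(tables())
def test_fisher_matches_exact_enumeration(table):
    p = fisher_two_sided(table)
    assert p == pytest.approx(enum_fisher_p(*table.cells()), abs=1e-12)


@given(tables(max_cell=30))
def test_fisher_matches_scipy(table):
    a, b, c, d = table.cells()
    assert fisher_two_sided(table) == pytest.approx(
        fisher_exact([[a, b], [c, d]])[1], abs=1e-10
    )


@given(tables())
def test_fisher_transposition_symmetry(table):
    a, b, c, d = table.cells()
    if a + c > 0 and b + d > 0:
        assert fisher_two_sided(table) == pytest.approx(
            fisher_two_sided(Contingency2x2(a, c, b, d)), abs=1e-12
        )


# ---------------------------------------------------------------- CMLE OR


def test_cmle_balanced_table_is_one():
    assert cmle_odds_ratio(Contingency2x2(5, 95, 5, 95)) == pytest.approx(1.0, abs=1e-9)


def test_cmle_boundaries():
    assert cmle_odds_ratio(Contingency2x2(4, 0, 0, 4)) == math.inf
    assert cmle_odds_ratio(Contingency2x2(0, 4, 4, 0)) == 0.0
    # degenerate support: shRNA absent from both samples
    assert cmle_odds_ratio(Contingency2x2(0, 10, 0, 10)) == 1.0


def test_cmle_tea_tasting_table():
    or_hat = cmle_odds_ratio(Contingency2x2(3, 1, 1, 3))
    assert or_hat == pytest.approx(6.408309, rel=1e-5)
    # grid maximisation of the conditional likelihood confirms the root
    t = Contingency2x2(3, 1, 1, 3)
    log_hat = math.log(or_hat)
    grid = np.linspace(log_hat - 2, log_hat + 2, 2001)
    ll = [conditional_loglik(t, g) for g in grid]
    assert abs(grid[int(np.argmax(ll))] - log_hat) <= grid[1] - grid[0]


@given(tables())
def test_cmle_matches_scipy_conditional(table):
    a, b, c, d = table.cells()
    ours = cmle_odds_ratio(table)
    ref = scipy_odds_ratio([[a, b], [c, d]], kind="conditional").statistic
    if math.isinf(ours):
        assert math.isinf(ref) or ref > 1e8
    elif ours == 0.0:
        assert ref < 1e-8 or ref == 0.0
    elif a + c == 0 or b + d == 0:
        pass  # degenerate support: estimate conventionally 1, scipy returns nan
    else:
        assert ours == pytest.approx(ref, rel=1e-6, abs=1e-9)


@given(tables())
def test_cmle_inversion_symmetry(table):
    a, b, c, d = table.cells()
    if a + c == 0 or b + d == 0:
        return
    left = cmle_odds_ratio(table)
    right = cmle_odds_ratio(Contingency2x2(b, a, d, c))
    if left == 0.0:
        assert math.isinf(right)
    elif math.isinf(left):
        assert right == 0.0
    else:
        assert left == pytest.approx(1.0 / right, rel=1e-7)


# ---------------------------------------------------------------- exact CI


def test_ci_null_table_contains_one():
    lo, hi = exact_ci(Contingency2x2(5, 95, 5, 95), 0.95)
    assert lo < 1.0 < hi


def test_ci_boundary_cases():
    lo, hi = exact_ci(Contingency2x2(0, 10, 5, 5), 0.95)
    assert lo == 0.0 and hi < math.inf
    lo, hi = exact_ci(Contingency2x2(5, 0, 0, 10), 0.95)
    assert math.isinf(hi)


def test_ci_tea_tasting_tail_equations():
    t = Contingency2x2(3, 1, 1, 3)
    lo, hi = exact_ci(t, 0.95)
    assert noncentral_tail(t, hi, upper=False) == pytest.approx(0.025, abs=1e-8)
    assert noncentral_tail(t, lo, upper=True) == pytest.approx(0.025, abs=1e-8)


@given(tables())
def test_ci_matches_scipy_and_brackets_estimate(table):
    a, b, c, d = table.cells()
    lo, hi = exact_ci(table, 0.95)
    or_hat = cmle_odds_ratio(table)
    assert lo <= or_hat <= hi
    if a + c == 0 or b + d == 0:
        return
    ref = scipy_odds_ratio([[a, b], [c, d]], kind="conditional").confidence_interval(0.95)
    assert lo == pytest.approx(ref.low, rel=1e-5, abs=1e-8)
    if math.isinf(hi):
        assert math.isinf(ref.high)
    else:
        assert hi == pytest.approx(ref.high, rel=1e-5)


# ---------------------------------------------------------------- fold & BH


@pytest.mark.parametrize(
    "cells, pc, expected",
    [
        ((100, 900, 25, 975), 0.0, 4.0),
        ((50, 950, 50, 950), 0.0, 1.0),
        ((100, 900, 0, 1000), 0.5, 201.0),
        ((100, 900, 0, 1000), 0.0, math.inf),
    ],
)
def test_fold_depletion_formula(cells, pc, expected):
    got = fold_depletion(Contingency2x2(*cells), pc)
    if math.isinf(expected):
        assert math.isinf(got)
    else:
        assert got == pytest.approx(expected, rel=1e-12)


def test_bh_single_and_worked_example():
    assert bh_adjust([0.2]).tolist() == [0.2]
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def naive_bh(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        out[i] = running
    return out


@given(hst.lists(hst.floats(min_value=0, max_value=1), min_size=1, max_size=60))
def test_bh_matches_naive_stepup(p):
    np.testing.assert_allclose(bh_adjust(p), naive_bh(p), atol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    p = rng.random(500)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)


@given(hst.lists(hst.floats(min_value=0, max_value=1), min_size=1, max_size=60))
def test_bh_dominates_raw_p(p):
    adj = bh_adjust(p)
    assert (adj >= np.asarray(p) - 1e-15).all()
    assert (adj <= 1.0).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------- run_stats


def test_run_stats_complete_and_per_genotype_families():
    rng = np.random.default_rng(4)
    n = 30
    base = rng.integers(100, 400, size=n)
    m = _matrix_from_counts(base, base, base, rng.integers(100, 400, size=n),
                            [f"s{i}" for i in range(n)])
    res = run_stats(m, PipelineConfig())
    assert set(res) == set(Genotype)
    assert all(len(df) == n for df in res.values())
    # BH is applied within each genotype: identical T0/T10 columns give p=1
    np.testing.assert_allclose(res[Genotype.P53_PLUS]["p"], 1.0, atol=1e-9)
    np.testing.assert_allclose(res[Genotype.P53_PLUS]["p_adj"], 1.0, atol=1e-9)


def test_run_stats_halved_frequency_fold_two():
    n = 20
    t0 = np.full(n, 500)
    t10 = np.full(n, 500)
    t10_mod = t10.copy()
    t10_mod[0] = 250  # halved frequency (totals barely change)
    ids = [f"s{i}" for i in range(n)]
    m = _matrix_from_counts(t0, t10_mod, t0, t10_mod, ids)
    res = run_stats(m, PipelineConfig())
    for g in Genotype:
        assert res[g].loc["s0", "fold_depletion"] == pytest.approx(2.0, rel=0.05)
        assert res[g].loc["s0", "odds_ratio"] == pytest.approx(2.0, rel=0.1)
    assert (res[Genotype.P53_PLUS]["p_adj"] >= res[Genotype.P53_PLUS]["p"] - 1e-15).all()


def test_stats_table_roundtrip_with_inf(tmp_path):
    from shdrop.stats import read_stats_table, write_stats_table

    m = _matrix_from_counts([100, 400], [0, 500], [100, 400], [0, 500], ["x", "y"])
    df = run_stats(m, PipelineConfig())[Genotype.P53_MINUS]
    path = tmp_path / "stats.tsv"
    write_stats_table(df, path)
    assert "Inf" in path.read_text()
    again = read_stats_table(path)
    assert math.isinf(again.loc["x", "ci_high"]) or again.loc["x", "ci_high"] > 1
    np.testing.assert_allclose(again["p"], df["p"])
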