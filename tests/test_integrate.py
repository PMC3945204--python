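"""Overlap statistics, enrichment tests, and downstream comparisons."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from funcbind import binding as bnd
from funcbind import integrate as itg


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def exact_fisher_p(a, b, c, d):
    """Independent oracle: exact-rational hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    denom = comb(N, c1)
    pobs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if px <= pobs:
            total += px
    return float(total)


def test_fisher_enumerated_examples():
    _, p = itg.fisher_exact([[5, 0], [0, 5]])
    assert p == pytest.approx(2 / 252, abs=1e-12)
    _, p = itg.fisher_exact([[1, 1], [1, 1]])
    assert p == pytest.approx(1.0)
    _, p = itg.fisher_exact([[2, 3], [4, 1]])
    assert p == pytest.approx(132 / 252, abs=1e-12)


def test_fisher_zero_margin_sentinel():
    odds, p = itg.fisher_exact([[0, 0], [3, 4]])
    assert p == 1.0 and np.isnan(odds)


def test_fisher_continuity_odds_with_zero_cell():
    odds, _ = itg.fisher_exact([[5, 0], [2, 3]])
    assert odds == pytest.approx((5.5 * 3.5) / (0.5 * 2.5))


def test_fisher_rejects_negative_cells():
    with pytest.raises(ValueError):
        itg.fisher_exact([[-1, 2], [3, 4]])


def test_fisher_random_tables_vs_oracle(rng):
    for _ in range(300):
        a, b, c, d = rng.integers(0, 10, size=4)
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        _, p = itg.fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(exact_fisher_p(a, b, c, d), abs=1e-12)


# ---------------------------------------------------------------------------
# relative enrichment
# ---------------------------------------------------------------------------

def test_relative_enrichment_independence_is_one():
    # a = row*col/N exactly: row=10, col=8, N=40 -> a=2
    assert itg.relative_enrichment([[2, 8], [6, 24]]) == pytest.approx(1.0)


def test_relative_enrichment_example_and_transpose():
    tab = [[4, 6], [4, 26]]  # bound margin 10, de margin 8, N=40 -> expected 2
    assert itg.relative_enrichment(tab) == pytest.approx(2.0)
    t = [[4, 4], [6, 26]]
    assert itg.relative_enrichment(t) == pytest.approx(2.0)


def test_relative_enrichment_zero_margin_sentinel():
    assert np.isnan(itg.relative_enrichment([[0, 0], [5, 5]]))


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def test_rank_sum_identical_groups_p_one():
    _, p = itg.rank_sum_test([1.0, 2.0], [1.0, 2.0])
    assert p == 1.0
    _, p = itg.rank_sum_test([3.0, 3.0], [3.0, 3.0])
    assert p == 1.0


def test_rank_sum_exact_enumerated_example():
    _, p = itg.rank_sum_test([1.0, 2.0], [3.0, 4.0], method="exact")
    assert p == pytest.approx(2 / 6, abs=1e-12)


def test_rank_sum_empty_group_sentinel():
    _, p = itg.rank_sum_test([], [1.0])
    assert np.isnan(p)


def test_rank_sum_asymptotic_close_to_exact(rng):
    """Moderate version of the exact-oracle agreement check."""
    worst = 0.0
    for _ in range(100):
        n, m = rng.integers(3, 9, size=2)
        x = rng.normal(size=n)
        y = rng.normal(rng.uniform(-1, 1), 1, size=m)
        _, p_ex = itg.rank_sum_test(x, y, method="exact")
        _, p_as = itg.rank_sum_test(x, y, method="asymptotic")
        worst = max(worst, abs(p_ex - p_as))
    assert worst < 0.05


# ---------------------------------------------------------------------------
# overlap classification
# ---------------------------------------------------------------------------

def test_overlap_table_hand_count():
    uni = [f"g{i}" for i in range(10)]
    bound = uni[:4]
    de = uni[2:5]
    tab = itg.overlap_table(uni, bound, de)
    assert (tab.a, tab.b, tab.c, tab.d) == (2, 2, 1, 5)
    assert tab.frac_bound_de == pytest.approx(0.5)
    assert tab.frac_de_bound == pytest.approx(2 / 3)
    # exact identity between counts and fractions
    assert tab.frac_bound_de * (tab.a + tab.b) == pytest.approx(tab.a)
    assert tab.frac_de_bound * (tab.a + tab.c) == pytest.approx(tab.a)


def test_overlap_table_empty_de_missing_fraction():
    uni = [f"g{i}" for i in range(6)]
    tab = itg.overlap_table(uni, uni[:3], [])
    assert tab.frac_bound_de == 0.0
    assert np.isnan(tab.frac_de_bound)


def _assignment(pairs_rows):
    pairs = pd.DataFrame(pairs_rows, columns=["gene", "factor", "chrom",
                                              "midpoint", "distance"])
    counts = pairs.groupby(["gene", "factor"]).size().rename("count").reset_index()
    return bnd.TargetAssignment(pairs=pairs, counts=counts, window_max=10_000)


def test_classify_functional_definition():
    asg = _assignment([("g0", "F", "c", 1, 0), ("g1", "F", "c", 2, 0),
                       ("g2", "X", "c", 3, 0)])
    res = pd.DataFrame({"q": [0.01, 0.5, 0.01], "log2fc": [1.0, -1.0, 2.0]},
                       index=["g0", "g1", "g2"])
    calls, tab = itg.classify_functional(asg, res, 0.05, ["F"])
    by_gene = calls.set_index("gene")
    assert bool(by_gene.loc["g0", "functional"])          # bound & DE
    assert not by_gene.loc["g1", "functional"]            # bound, not DE
    assert not by_gene.loc["g2", "functional"]            # DE, bound by other
    assert tab.a == 1 and tab.n == 3


def test_classify_functional_bad_fdr():
    asg = _assignment([("g0", "F", "c", 1, 0)])
    res = pd.DataFrame({"q": [0.01], "log2fc": [1.0]}, index=["g0"])
    with pytest.raises(ValueError):
        itg.classify_functional(asg, res, 0.0, ["F"])


# ---------------------------------------------------------------------------
# state enrichment
# ---------------------------------------------------------------------------

def test_state_enrichment_no_contrast():
    states = pd.Series(["A"] * 8)
    de = pd.Series([True, False] * 4)
    out = itg.state_enrichment(states, de).set_index("state")
    assert out.loc["A", "p"] == 1.0


def test_state_enrichment_hand_computed_with_bh():
    """12 events over 3 states with hand-set labels; tables, Fisher p and
    the BH step-up all verified manually."""
    states = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4)
    de = pd.Series([True] * 4 + [False] * 4 + [True, False, False, False])
    out = itg.state_enrichment(states, de).set_index("state")
    assert (out.loc["A", ["a", "b", "c", "d"]] == [4, 0, 1, 7]).all()
    assert (out.loc["B", ["a", "b", "c", "d"]] == [0, 4, 5, 3]).all()
    assert (out.loc["C", ["a", "b", "c", "d"]] == [1, 3, 4, 4]).all()
    for s in "ABC":
        a, b, c, d = out.loc[s, ["a", "b", "c", "d"]]
        assert out.loc[s, "p"] == pytest.approx(exact_fisher_p(a, b, c, d),
                                                abs=1e-12)
    # BH by hand: sorted p * m / rank, cumulative min from the right
    ps = out["p"].sort_values()
    m = len(ps)
    stepped = [p * m / (i + 1) for i, p in enumerate(ps)]
    expect = np.minimum.accumulate(stepped[::-1])[::-1]
    got = out.loc[ps.index, "p_adj"].to_numpy()
    np.testing.assert_allclose(got, np.minimum(expect, 1.0), atol=1e-12)


def test_event_de_status_any_gene_rule():
    pairs = pd.DataFrame({
        "gene": ["g0", "g1"], "factor": ["F", "F"], "chrom": ["c", "c"],
        "midpoint": [100, 100], "distance": [0, 0]})
    ev = itg.event_de_status(pairs, {"g1"})
    assert len(ev) == 1 and bool(ev["de"].iloc[0])


# ---------------------------------------------------------------------------
# site features
# ---------------------------------------------------------------------------

def test_compare_site_features_sentinels_and_shift():
    shift, _, p = itg.compare_site_features([], [1.0, 2.0])
    assert np.isnan(p)
    shift, _, p = itg.compare_site_features([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
    assert shift == pytest.approx(4.0)
    assert p < 0.2


# ---------------------------------------------------------------------------
# co-occupancy
# ---------------------------------------------------------------------------

def test_cooccupancy_shared_fraction_and_exclusion():
    uni = {f"g{i}" for i in range(50)}
    asg = _assignment([(f"g{i}", "T1", "c", i, 0) for i in range(10)])
    de_tf = {"e1": {"T1", "T2"}, "e2": {"T1", "T2"}, "e3": {"T9"}}
    de_gene = {"e1": set(list(uni)[:8]), "e2": set(list(uni)[4:12]),
               "e3": set(list(uni)[:5])}
    expr = {e: uni for e in de_tf}
    pairs, _ = itg.cooccupancy_enrichment(de_tf, de_gene, expr, asg)
    by = pairs.set_index(["exp1", "exp2"])
    assert by.loc[("e1", "e2"), "shared_fraction"] == pytest.approx(1.0)
    # pairs with empty DE-TF intersection are excluded but counted
    assert ("e1", "e3") not in by.index
    assert pairs.attrs["n_excluded"] == 2


def test_cooccupancy_requires_two_experiments():
    with pytest.raises(ValueError):
        itg.cooccupancy_enrichment({"e": set()}, {}, {}, _assignment([]))


# ---------------------------------------------------------------------------
# direction of effect
# ---------------------------------------------------------------------------

def test_direction_of_effect_counts():
    calls = pd.DataFrame({"gene": ["a", "b", "c", "d"],
                          "bound": [True, True, True, False],
                          "de": [True, True, True, True]})
    calls["functional"] = calls["bound"] & calls["de"]
    res = pd.DataFrame({"log2fc": [1.0, -1.0, 2.0, -0.5]},
                       index=["a", "b", "c", "d"])
    d = itg.direction_of_effect(calls, res)
    assert d["frac_up_functional"] == pytest.approx(2 / 3)
    assert d["frac_up_de"] == pytest.approx(0.5)


def test_direction_of_effect_sentinels():
    calls = pd.DataFrame({"gene": ["a"], "bound": [False], "de": [False],
                          "functional": [False]})
    res = pd.DataFrame({"log2fc": [1.0]}, index=["a"])
    d = itg.direction_of_effect(calls, res)
    assert np.isnan(d["frac_up_functional"]) and np.isnan(d["frac_up_de"])


def test_direction_all_down_is_zero():
    calls = pd.DataFrame({"gene": ["a", "b"], "bound": [True, True],
                          "de": [True, True], "functional": [True, True]})
    res = pd.DataFrame({"log2fc": [-1.0, -0.2]}, index=["a", "b"])
    assert itg.direction_of_effect(calls, res)["frac_up_functional"] == 0.0


# ---------------------------------------------------------------------------
# window sensitivity
# ---------------------------------------------------------------------------

def test_window_sensitivity_saturation_and_monotone_denominator():
    """All binding within 2 kb: fractions identical for every window >= 2 kb,
    and the bound-gene denominator never shrinks as the window widens."""
    tss = pd.DataFrame({"gene": ["g0", "g1"], "chrom": "c", "strand": "+",
                        "position": [10_000, 50_000], "cage_score": 1.0})
    ev = pd.DataFrame({"factor": "F", "chrom": "c",
                       "midpoint": [10_500, 11_500, 49_200]})
    per_exp = {"e": {"expressed": {"g0", "g1"}, "de": {"g0"}, "factors": {"F"}}}
    out = itg.window_sensitivity(ev, tss, per_exp,
                                 windows=(2_000, 5_000, 10_000, 20_000))
    plain = out[out["inner"] == 0]
    assert plain["n_bound"].is_monotonic_increasing or \
        plain["n_bound"].nunique() == 1
    fracs = plain["frac_bound_de"].unique()
    assert len(fracs) == 1 and fracs[0] == pytest.approx(0.5)


def test_window_sensitivity_matches_recomputation(rng):
    tss = pd.DataFrame({
        "gene": [f"g{i}" for i in range(20)], "chrom": "c", "strand": "+",
        "position": rng.choice(400_000, 20, replace=False), "cage_score": 1.0})
    ev = pd.DataFrame({"factor": rng.choice(["F", "G"], 200), "chrom": "c",
                       "midpoint": rng.integers(0, 400_000, 200)})
    expressed = {f"g{i}" for i in range(20)}
    de = set(rng.choice(sorted(expressed), 6, replace=False))
    per_exp = {"e": {"expressed": expressed, "de": de, "factors": {"F"}}}
    out = itg.window_sensitivity(ev, tss, per_exp, windows=(1_000, 10_000),
                                 annulus=(1_000, 10_000))
    for _, row in out.iterrows():
        asg = bnd.assign_targets_window(ev, tss, window=row["outer"],
                                        inner=row["inner"])
        bound = asg.bound_genes({"F"}) & expressed
        expect = len(bound & de) / len(bound) if bound else np.nan
        if np.isnan(expect):
            assert np.isnan(row["frac_bound_de"])
        else:
            assert row["frac_bound_de"] == pytest.approx(expect)
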