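"""Functional-binding classification and downstream comparisons.

Binding of a factor to a gene is called *functional* when the gene is both
bound (within the TSS window, by the relevant factor set) and
differentially expressed in the corresponding knockdown. On top of that
per-(gene, experiment) classification this module computes the study's
comparisons: bound x DE overlap tables with Fisher tests and relative
enrichment, chromatin-state enrichment of functional binding, rank-sum
comparisons of site features, co-occupancy enrichment binned by shared DE
factors, direction of effect, and window-sensitivity summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .binding import TargetAssignment, assign_targets_window

#: sentinel odds ratio when a margin is zero
OR_UNDEFINED = float("nan")


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def fisher_exact(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, p). The p-value is the sum of hypergeometric
    probabilities no larger than that of the observed table, conditional on
    the margins. The odds ratio is a*d / (b*c), computed with a 0.5
    continuity correction when any cell is zero (reporting only — the
    p-value is untouched). A zero margin gives p = 1 and an undefined
    odds-ratio sentinel (NaN).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0 or any(x != int(x) for x in (a, b, c, d)):
        raise ValueError("cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return OR_UNDEFINED, 1.0
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def relative_enrichment(table: Sequence[Sequence[int]]) -> float:
    """Observed overlap divided by the overlap expected under independence:
    a * N / ((a + b) * (a + c)). Symmetric in the two margins; NaN when a
    margin is zero."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row, col = a + b, a + c
    if row == 0 or col == 0 or n == 0:
        return float("nan")
    return a * n / (row * col)


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  method: str = "auto") -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    ``method='exact'`` enumerates all assignments of the pooled values to
    the two groups (feasible for small groups; ties handled through average
    ranks); ``'asymptotic'`` uses the normal approximation with tie
    correction and continuity correction; ``'auto'`` picks exact when both
    groups have <= 8 observations. Returns (rank-sum statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return float("nan"), float("nan")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    obs = float(ranks[:n].sum())
    mu = n * (n + m + 1) / 2.0
    if np.all(pooled == pooled[0]):
        return obs, 1.0
    if method == "auto":
        method = "exact" if (n <= 8 and m <= 8) else "asymptotic"
    if method == "exact":
        dev = abs(obs - mu)
        count = total = 0
        for comb in combinations(range(n + m), n):
            s = ranks[list(comb)].sum()
            total += 1
            if abs(s - mu) >= dev - 1e-9:
                count += 1
        return obs, count / total
    if method == "asymptotic":
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        return obs, float(res.pvalue)
    raise ValueError(f"unknown method: {method}")


# ---------------------------------------------------------------------------
# overlap classification
# ---------------------------------------------------------------------------

@dataclass
class OverlapTable:
    """2x2 (bound x DE) counts over the expressed-gene universe."""

    n: int
    a: int  # bound & DE
    b: int  # bound & not DE
    c: int  # not bound & DE
    d: int  # neither
    frac_bound_de: float   # a / (a + b): fraction of bound genes that are DE
    frac_de_bound: float   # a / (a + c): fraction of DE genes that are bound
    odds_ratio: float
    fisher_p: float
    rel_enrichment: float

    def as_table(self) -> List[List[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def overlap_table(universe: Iterable[str], bound: Iterable[str],
                  de: Iterable[str]) -> OverlapTable:
    uni = set(universe)
    bound = set(bound) & uni
    de = set(de) & uni
    a = len(bound & de)
    b = len(bound - de)
    c = len(de - bound)
    d = len(uni) - a - b - c
    tab = [[a, b], [c, d]]
    odds, p = fisher_exact(tab)
    return OverlapTable(
        n=len(uni), a=a, b=b, c=c, d=d,
        frac_bound_de=a / (a + b) if (a + b) else float("nan"),
        frac_de_bound=a / (a + c) if (a + c) else float("nan"),
        odds_ratio=odds, fisher_p=p, rel_enrichment=relative_enrichment(tab),
    )


def classify_functional(
    assignment: TargetAssignment,
    de_results: pd.DataFrame,
    fdr: float,
    relevant_factors: Sequence[str],
) -> Tuple[pd.DataFrame, OverlapTable]:
    """Per-gene functional calls for one experiment.

    The universe is the expressed-gene index of ``de_results``; a gene is
    bound if any relevant factor has an assigned event, DE if q <= fdr, and
    functional if both.
    """
    if not (0 < fdr < 1):
        raise ValueError("fdr must lie in (0, 1)")
    universe = list(de_results.index)
    bound = assignment.bound_genes(relevant_factors) & set(universe)
    de = set(de_results.index[de_results["q"] <= fdr])
    calls = pd.DataFrame(
        {
            "gene": universe,
            "bound": [g in bound for g in universe],
            "de": [g in de for g in universe],
        }
    )
    calls["functional"] = calls["bound"] & calls["de"]
    return calls, overlap_table(universe, bound, de)


# ---------------------------------------------------------------------------
# chromatin-state enrichment
# ---------------------------------------------------------------------------

def event_de_status(pairs: pd.DataFrame, de_genes: Set[str]) -> pd.DataFrame:
    """Unique events from assignment pairs, flagged DE if ANY assigned gene
    is differentially expressed."""
    df = pairs.copy()
    df["de"] = df["gene"].isin(de_genes)
    ev = (
        df.groupby(["factor", "chrom", "midpoint"], sort=True)["de"]
        .any()
        .reset_index()
    )
    return ev


def state_enrichment(event_states: pd.Series, event_de: pd.Series,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-state 2x2 (event in state) x (assigned gene DE) Fisher tests with
    BH adjustment across states."""
    states = pd.Series(event_states).astype(str)
    de = pd.Series(event_de).astype(bool)
    if len(states) != len(de):
        raise ValueError("state and DE vectors must align")
    rows = []
    for s in sorted(states.unique()):
        ins = states == s
        a = int((ins & de).sum())
        b = int((ins & ~de).sum())
        c = int((~ins & de).sum())
        d = int((~ins & ~de).sum())
        odds, p = fisher_exact([[a, b], [c, d]])
        rows.append({"state": s, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["direction"] = np.where(out["odds_ratio"] > 1, "enriched", "depleted")
        out["significant"] = out["p_adj"] < alpha
    return out


# ---------------------------------------------------------------------------
# site features
# ---------------------------------------------------------------------------

def compare_site_features(values_functional: Sequence[float],
                          values_nonfunctional: Sequence[float],
                          method: str = "auto") -> Tuple[float, float, float]:
    """Rank-sum comparison of a site/gene feature between the functional and
    non-functional groups. Returns (median shift, statistic, p)."""
    x = np.asarray(values_functional, dtype=float)
    y = np.asarray(values_nonfunctional, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        return float("nan"), float("nan"), float("nan")
    stat, p = rank_sum_test(x, y, method=method)
    return float(np.median(x) - np.median(y)), stat, p


# ---------------------------------------------------------------------------
# co-occupancy
# ---------------------------------------------------------------------------

def cooccupancy_enrichment(
    de_tf_sets: Dict[str, Set[str]],
    de_gene_sets: Dict[str, Set[str]],
    expressed_sets: Dict[str, Set[str]],
    assignment: TargetAssignment,
    n_bins: int = 5,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise co-occupancy enrichment, binned by shared DE-factor fraction.

    For each unordered experiment pair: the shared fraction is the Jaccard
    index of the two DE-factor sets; the enrichment is the relative
    enrichment of (gene DE in both) x (gene bound by a factor in the
    intersection) over genes expressed in both experiments. Pairs with an
    empty DE-factor intersection are excluded (counted). The included pairs
    are binned into quantiles of the shared fraction.
    """
    exps = sorted(de_tf_sets)
    if len(exps) < 2:
        raise ValueError("need at least two experiments")
    rows, excluded = [], 0
    for e1, e2 in combinations(exps, 2):
        t1, t2 = de_tf_sets[e1], de_tf_sets[e2]
        union = t1 | t2
        inter = t1 & t2
        shared = len(inter) / len(union) if union else 0.0
        if not inter:
            excluded += 1
            continue
        uni = expressed_sets[e1] & expressed_sets[e2]
        de_both = de_gene_sets[e1] & de_gene_sets[e2] & uni
        bound = assignment.bound_genes(inter) & uni
        a = len(bound & de_both)
        b = len(bound - de_both)
        c = len(de_both - bound)
        d = len(uni) - a - b - c
        rows.append({"exp1": e1, "exp2": e2, "shared_fraction": shared,
                     "n_universe": len(uni), "n_de_both": len(de_both),
                     "n_bound": len(bound),
                     "enrichment": relative_enrichment([[a, b], [c, d]])})
    pairs = pd.DataFrame(rows)
    pairs.attrs["n_excluded"] = excluded
    if len(pairs) == 0:
        return pairs, pd.DataFrame()
    valid = pairs.dropna(subset=["enrichment"]).copy()
    try:
        valid["bin"] = pd.qcut(valid["shared_fraction"], q=n_bins,
                               labels=False, duplicates="drop")
    except ValueError:
        valid["bin"] = 0
    summary = (
        valid.groupby("bin")
        .agg(n_pairs=("enrichment", "size"),
             shared_lo=("shared_fraction", "min"),
             shared_hi=("shared_fraction", "max"),
             median_enrichment=("enrichment", "median"))
        .reset_index()
    )
    return pairs, summary


# ---------------------------------------------------------------------------
# direction of effect
# ---------------------------------------------------------------------------

def direction_of_effect(calls: pd.DataFrame,
                        de_results: pd.DataFrame) -> Dict[str, float]:
    """Fraction of up-regulated genes among functional targets and among all
    DE genes of one experiment (NaN sentinels when a group is empty)."""
    lfc = de_results["log2fc"]
    func_genes = calls.loc[calls["functional"], "gene"]
    de_genes = calls.loc[calls["de"], "gene"]
    out = {"n_functional": int(len(func_genes)), "n_de": int(len(de_genes))}
    out["frac_up_functional"] = (
        float((lfc.loc[func_genes] > 0).mean()) if len(func_genes) else float("nan")
    )
    out["frac_up_de"] = (
        float((lfc.loc[de_genes] > 0).mean()) if len(de_genes) else float("nan")
    )
    return out


# ---------------------------------------------------------------------------
# window sensitivity
# ---------------------------------------------------------------------------

def window_sensitivity(
    events: pd.DataFrame,
    tss: pd.DataFrame,
    per_experiment: Dict[str, dict],
    windows: Sequence[int] = (1_000, 5_000, 10_000, 20_000),
    annulus: Tuple[int, int] = (1_000, 10_000),
) -> pd.DataFrame:
    """Fraction of bound genes that are DE, per window size and experiment.

    ``per_experiment`` maps experiment -> {"expressed": set, "de": set,
    "factors": set}. The promoter-excluded annulus (inner, outer) is
    appended as its own row group.
    """
    specs = [(0, w, f"{w // 1000}kb") for w in windows]
    specs.append((annulus[0], annulus[1],
                  f"{annulus[0] // 1000}-{annulus[1] // 1000}kb"))
    rows = []
    for inner, outer, label in specs:
        asg = assign_targets_window(events, tss, window=outer, inner=inner)
        for exp, info in sorted(per_experiment.items()):
            bound = asg.bound_genes(info["factors"]) & info["expressed"]
            de = info["de"] & info["expressed"]
            frac = len(bound & de) / len(bound) if bound else float("nan")
            rows.append({"window": label, "inner": inner, "outer": outer,
                         "experiment": exp, "n_bound": len(bound),
                         "frac_bound_de": frac})
    out = pd.DataFrame(rows)
    med = (
        out.groupby(["window", "inner", "outer"], sort=False)["frac_bound_de"]
        .median()
        .rename("median_frac_bound_de")
        .reset_index()
    )
    return out.merge(med, on=["window", "inner", "outer"])
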