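"""Per-gene differential expression for knockdown vs control.

Each gene is tested with a likelihood-ratio test in a fixed-effect linear
model: Y_ij = mu_i + beta_j X_i + eps_ij, where beta_j indicates whether
array j is a knockdown or a control and X_i is the gene's knockdown effect
(log2). Under Gaussian errors with the variance profiled out, the LRT
statistic is n * ln(RSS0 / RSS1) and is referred to a chi-square with one
degree of freedom (an exact-F variant is available for calibration
studies). Multiple testing is handled with Storey q-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: smallest representable p, used for degenerate zero-residual fits
TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class LRTResult:
    log2fc: float
    lrt_stat: float
    p: float
    degenerate: bool = False


def _rss(Y: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RSS under grand-mean and two-group-mean models; Y is genes x arrays
    with the first n1 columns in group 1."""
    grand = Y.mean(axis=1, keepdims=True)
    rss0 = ((Y - grand) ** 2).sum(axis=1)
    m1 = Y[:, :n1].mean(axis=1, keepdims=True)
    m2 = Y[:, n1:].mean(axis=1, keepdims=True)
    rss1 = ((Y[:, :n1] - m1) ** 2).sum(axis=1) + ((Y[:, n1:] - m2) ** 2).sum(axis=1)
    return rss0, rss1, (m1 - m2).ravel()


def lrt_matrix(y_kd: np.ndarray, y_ctl: np.ndarray,
               dist: str = "chi2") -> pd.DataFrame:
    """Vectorized LRT over genes; rows of the inputs are genes.

    ``dist='chi2'`` refers n*ln(RSS0/RSS1) to chi-square(1); ``dist='f'``
    uses the exact F statistic with (1, n-2) degrees of freedom.
    """
    y_kd = np.atleast_2d(np.asarray(y_kd, dtype=float))
    y_ctl = np.atleast_2d(np.asarray(y_ctl, dtype=float))
    n1, n2 = y_kd.shape[1], y_ctl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    n = n1 + n2
    Y = np.concatenate([y_kd, y_ctl], axis=1)
    rss0, rss1, diff = _rss(Y, n1)
    # rss1 == 0 with a group difference means perfect separation (infinite
    # evidence); rss1 == rss0 == 0 is a constant row and carries none.
    constant = (rss1 <= 0.0) & (rss0 <= 0.0)
    degenerate = (rss1 <= 0.0) & ~constant
    bad = degenerate | constant
    with np.errstate(divide="ignore", invalid="ignore"):
        if dist == "chi2":
            stat = n * np.log(np.where(bad, np.nan, rss0 / rss1))
            p = stats.chi2.sf(stat, df=1)
        elif dist == "f":
            stat = np.where(bad, np.nan, (rss0 - rss1) / (rss1 / (n - 2)))
            p = stats.f.sf(stat, 1, n - 2)
        else:
            raise ValueError(f"unknown dist: {dist}")
    stat = np.where(degenerate, np.inf, stat)
    p = np.where(degenerate, TINY_P, p)
    stat = np.where(constant, 0.0, stat)
    p = np.where(constant, 1.0, p)
    # identical groups: RSS0 == RSS1 exactly -> stat 0, p 1
    zero = (~bad) & (stat <= 0)
    p = np.where(zero, 1.0, p)
    stat = np.where(zero, 0.0, stat)
    return pd.DataFrame(
        {"log2fc": diff, "lrt_stat": stat, "p": p, "degenerate": degenerate}
    )


def lrt_gene(y_kd: Sequence[float], y_ctl: Sequence[float],
             dist: str = "chi2") -> LRTResult:
    """Single-gene convenience wrapper around :func:`lrt_matrix`."""
    row = lrt_matrix(np.asarray(y_kd)[None, :], np.asarray(y_ctl)[None, :],
                     dist=dist).iloc[0]
    return LRTResult(log2fc=float(row["log2fc"]), lrt_stat=float(row["lrt_stat"]),
                     p=float(row["p"]), degenerate=bool(row["degenerate"]))


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def estimate_pi0(pvals: np.ndarray,
                 lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 on a lambda grid with a cubic
    smoother evaluated at the largest lambda, clamped to [1/m, 1]."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m < 2:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.0, 0.9001, 0.05)
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return float(min(1.0, max(pi0, 1.0 / m)))


def storey_qvalues(pvals: Sequence[float], pi0: float | None = None) -> np.ndarray:
    """Storey-Tibshirani q-values: q_i = pi0 * min_{p_(j) >= p_(i)} p_(j) m / j."""
    p = np.asarray(pvals, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    if pi0 is None:
        pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_de(results: pd.DataFrame, fdr: float) -> List[str]:
    """Genes with q <= fdr; monotone non-decreasing in fdr."""
    if not (0 <= fdr < 1):
        raise ValueError("fdr must lie in [0, 1)")
    return list(results.index[results["q"] <= fdr])


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def effect_pct(log2fc: float | np.ndarray, symmetric: bool = True):
    """Percent difference in expression implied by a log2 fold change.

    Default (symmetric on the log scale): (2^|lfc| - 1) * 100, so a halving
    and a doubling both read 100%. The asymmetric alternative
    (1 - 2^-|lfc|) * 100 is available with ``symmetric=False``.
    """
    a = np.abs(log2fc)
    if symmetric:
        return (np.power(2.0, a) - 1.0) * 100.0
    return (1.0 - np.power(2.0, -a)) * 100.0


def knockdown_efficiency_array(results: pd.DataFrame, target_gene: str) -> float:
    """Array-based knockdown efficiency: (1 - 2^log2fc) * 100, clamped to
    [0, 100]. Returns NaN when the target gene was filtered out."""
    if target_gene not in results.index:
        return float("nan")
    lfc = float(results.loc[target_gene, "log2fc"])
    eff = (1.0 - 2.0**lfc) * 100.0
    return float(min(100.0, max(0.0, eff)))


# ---------------------------------------------------------------------------
# experiment-level table
# ---------------------------------------------------------------------------

def de_table(values: pd.DataFrame, kd_arrays: Sequence[str],
             ctl_arrays: Sequence[str], genes: Sequence[str] | None = None,
             dist: str = "f", symmetric_effect: bool = True) -> pd.DataFrame:
    """Full DE table for one knockdown: log2fc, LRT statistic, p, q, effect_pct.

    The default reference is the exact F (equivalent ranking to the
    chi-square LRT — both are monotone in RSS0/RSS1 — but calibrated at the
    small array counts of a triplicate design); pass ``dist='chi2'`` for
    the asymptotic version.
    """
    if genes is not None:
        values = values.loc[list(genes)]
    res = lrt_matrix(values[list(kd_arrays)].to_numpy(),
                     values[list(ctl_arrays)].to_numpy(), dist=dist)
    res.index = values.index
    res["q"] = storey_qvalues(res["p"].to_numpy())
    res["effect_pct"] = effect_pct(res["log2fc"].to_numpy(),
                                   symmetric=symmetric_effect)
    return res
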