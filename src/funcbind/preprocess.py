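"""Normalization and removal of unwanted variation.

The preprocessing chain is: probe filtering -> quantile normalization of
all arrays together -> selection of negative-control probes (least-variable
probes per transfection batch, intersected) -> estimation of hidden
nuisance factors from the control probes (SVD of the row-centered control
submatrix) -> residualization of every gene on those factors. The number
of factors k is chosen by a replicate-concordance diagnostic: the smallest
k that yields zero differentially expressed genes between control groups
across batches while maximizing the number of DE genes shared between
knockdown experiments repeated in different batches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, rankdata

from .matrix import CONTROL, ExpressionMatrix

log = logging.getLogger(__name__)

ORTHO_TOL = 1e-8


# ---------------------------------------------------------------------------
# probe filtering
# ---------------------------------------------------------------------------

def filter_probes(annotation: pd.DataFrame) -> pd.DataFrame:
    """Apply the probe quality rules and keep one probe per gene.

    A probe survives iff it maps uniquely, has no 1-mismatch secondary hit,
    is not on chrY and overlaps no heterozygous SNP; among survivors the
    3'-most probe (lowest ``three_prime_rank``) represents the gene. Genes
    with no surviving probe are dropped (logged).
    """
    ok = (
        annotation["maps_uniquely"].astype(bool)
        & ~annotation["secondary_hit_1mm"].astype(bool)
        & ~annotation["on_chrY"].astype(bool)
        & ~annotation["het_snp_overlap"].astype(bool)
    )
    surviving = annotation[ok]
    dropped = sorted(set(annotation["gene_id"]) - set(surviving["gene_id"]))
    if dropped:
        log.info("filter_probes: %d genes lost all probes", len(dropped))
    kept = (
        surviving.sort_values(["gene_id", "three_prime_rank"], kind="mergesort")
        .groupby("gene_id", sort=True)
        .head(1)
        .reset_index(drop=True)
    )
    return kept


def probes_to_genes(mat: ExpressionMatrix, retained: pd.DataFrame) -> ExpressionMatrix:
    """Subset the probe-level matrix to retained probes and reindex by gene."""
    ids = [p for p in retained["probe_id"] if p in mat.values.index]
    sub = mat.subset_rows(ids)
    mapping = dict(zip(retained["probe_id"], retained["gene_id"]))
    sub.values.index = [mapping[p] for p in ids]
    sub.detection_p.index = sub.values.index
    return sub


# ---------------------------------------------------------------------------
# detection filter
# ---------------------------------------------------------------------------

def detection_filter(
    mat: ExpressionMatrix,
    kd_arrays: Sequence[str],
    control_arrays: Sequence[str],
    threshold: float = 0.01,
) -> List[str]:
    """Genes detected (p < threshold) on ALL knockdown replicates OR on ALL
    control arrays of the experiment."""
    kd_arrays, control_arrays = list(kd_arrays), list(control_arrays)
    missing = (set(kd_arrays) | set(control_arrays)) - set(mat.array_ids)
    if missing:
        raise KeyError(f"unknown arrays: {sorted(missing)}")
    det = mat.detection_p
    on_kd = (det[kd_arrays] < threshold).all(axis=1)
    on_ctl = (det[control_arrays] < threshold).all(axis=1)
    return list(det.index[on_kd | on_ctl])


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the vector of row-rank means.

    Ties within a column receive the mean of the reference values their
    ranks span (the usual tie convention for rank-based normalization).
    """
    X = values.to_numpy(dtype=float)
    n, m = X.shape
    if m <= 1:
        return values.copy()
    ref = np.sort(X, axis=0).mean(axis=1)
    cum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        rmin = rankdata(col, method="min").astype(int)
        rmax = rankdata(col, method="max").astype(int)
        out[:, j] = (cum[rmax] - cum[rmin - 1]) / (rmax - rmin + 1)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# control probes
# ---------------------------------------------------------------------------

@dataclass
class ControlProbeSet:
    per_batch: Dict[int, List[str]]
    intersection: List[str]
    n_per_batch: int


def select_control_probes(
    values: pd.DataFrame,
    batches: pd.Series,
    n_per_batch: int = 2000,
    candidates: Optional[Iterable[str]] = None,
) -> ControlProbeSet:
    """Least-variable probes per batch, intersected across batches.

    ``batches`` maps array id -> batch label. Variance is the sample
    variance of the (normalized) log2 values across the batch's arrays.
    ``candidates`` restricts the ranking (e.g. to detection-passing genes).
    """
    if candidates is not None:
        values = values.loc[[g for g in values.index if g in set(candidates)]]
    batch_ids = sorted(set(batches))
    if len(batch_ids) < 2:
        raise ValueError("need at least two batches to intersect control lists")
    n = min(n_per_batch, len(values))
    if n < n_per_batch:
        log.warning("n_per_batch capped to %d (probe count)", n)
    per_batch: Dict[int, List[str]] = {}
    for b in batch_ids:
        cols = list(batches.index[batches == b])
        var = values[cols].var(axis=1, ddof=1)
        per_batch[b] = list(var.nsmallest(n, keep="first").index)
    inter = set(per_batch[batch_ids[0]])
    for b in batch_ids[1:]:
        inter &= set(per_batch[b])
    if not inter:
        warnings.warn("control-probe intersection across batches is empty")
    intersection = [g for g in values.index if g in inter]
    return ControlProbeSet(per_batch=per_batch, intersection=intersection,
                           n_per_batch=n)


# ---------------------------------------------------------------------------
# RUV
# ---------------------------------------------------------------------------

@dataclass
class RuvFactors:
    k: int
    W: pd.DataFrame             # arrays x k, orthonormal columns
    loadings: pd.DataFrame      # genes x k (least-squares fit of each row on W)
    control_genes: List[str] = field(default_factory=list)


def fit_ruv(values: pd.DataFrame, controls: ControlProbeSet | Sequence[str],
            k: int) -> RuvFactors:
    """Estimate k nuisance-factor scores from the control-probe submatrix.

    Factor scores are the first k array-side singular vectors of the
    row-centered control submatrix; per-gene loadings are the least-squares
    regression of each (centered) gene row on those scores.
    """
    genes = controls.intersection if isinstance(controls, ControlProbeSet) \
        else list(controls)
    if k < 0:
        raise ValueError("k must be >= 0")
    cols = list(values.columns)
    if k == 0:
        W = pd.DataFrame(np.zeros((len(cols), 0)), index=cols)
        L = pd.DataFrame(np.zeros((len(values), 0)), index=values.index)
        return RuvFactors(k=0, W=W, loadings=L, control_genes=genes)
    if not genes:
        raise ValueError("control set is empty")
    C = values.loc[genes].to_numpy(dtype=float)
    Cc = C - C.mean(axis=1, keepdims=True)
    rank = np.linalg.matrix_rank(Cc)
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank} of the control submatrix")
    _, _, Vt = np.linalg.svd(Cc, full_matrices=False)
    W = Vt[:k].T  # arrays x k, orthonormal
    Y = values.to_numpy(dtype=float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    L = Yc @ W  # least squares since W has orthonormal columns
    return RuvFactors(
        k=k,
        W=pd.DataFrame(W, index=cols, columns=[f"W{j+1}" for j in range(k)]),
        loadings=pd.DataFrame(L, index=values.index,
                              columns=[f"W{j+1}" for j in range(k)]),
        control_genes=genes,
    )


def apply_ruv(values: pd.DataFrame, factors: RuvFactors) -> pd.DataFrame:
    """Replace each gene row by its mean plus the residual after regressing
    on the factor scores. Residuals are orthogonal to every factor column."""
    if list(values.columns) != list(factors.W.index):
        raise ValueError("arrays of matrix and factors do not match")
    if factors.k == 0:
        return values.copy()
    W = factors.W.to_numpy()
    Y = values.to_numpy(dtype=float)
    mean = Y.mean(axis=1, keepdims=True)
    Yc = Y - mean
    resid = Yc - (Yc @ W) @ W.T
    return pd.DataFrame(mean + resid, index=values.index, columns=values.columns)


def adjust_matrix(mat: ExpressionMatrix, factors: RuvFactors) -> ExpressionMatrix:
    return mat.with_values(apply_ruv(mat.values, factors))


# ---------------------------------------------------------------------------
# control pooling
# ---------------------------------------------------------------------------

def pool_controls(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Average matched control arrays across batches into pooled profiles.

    Control arrays sharing a replicate index are averaged across the
    batches, yielding one pooled control profile per replicate index (six
    by default). Knockdown arrays are untouched.
    """
    meta = mat.arrays
    ctl = meta[meta["condition"] == CONTROL]
    kd_cols = [a for a in mat.array_ids if a not in set(ctl.index)]
    pooled_vals, pooled_det, rows = {}, {}, []
    for r, grp in ctl.groupby("replicate", sort=True):
        cols = list(grp.index)
        name = f"CTL_pool_r{r}"
        pooled_vals[name] = mat.values[cols].mean(axis=1)
        pooled_det[name] = mat.detection_p[cols].mean(axis=1)
        rows.append({"array_id": name, "batch": -1, "condition": CONTROL,
                     "replicate": r})
    values = pd.concat([mat.values[kd_cols], pd.DataFrame(pooled_vals)], axis=1)
    det = pd.concat([mat.detection_p[kd_cols], pd.DataFrame(pooled_det)], axis=1)
    arrays = pd.concat(
        [meta.loc[kd_cols], pd.DataFrame(rows).set_index("array_id")]
    )
    return ExpressionMatrix(values=values, detection_p=det, arrays=arrays)


# ---------------------------------------------------------------------------
# choosing k
# ---------------------------------------------------------------------------

def choose_k(
    mat: ExpressionMatrix,
    controls: ControlProbeSet | Sequence[str],
    k_grid: Sequence[int],
    fdr: float = 0.05,
    pool: bool = False,
    exclude_genes: Optional[Iterable[str]] = None,
) -> Tuple[int, pd.DataFrame]:
    """Replicate-concordance diagnostic for the number of removed factors.

    For each k: (a) DE genes between control-array groups across batches at
    the given FDR, summed over batch pairs; (b) DE genes shared within each
    replicated knockdown pair (same condition, different batch), summed;
    (c) mean correlation of -log10 p across replicated pairs. Selected k:
    among the k with (a) == 0 (or minimal (a) if none reach zero), the
    smallest k whose (b) is within counting noise (sqrt of the maximum) of
    the best — (b) is a small count, so a plain argmax would chase Poisson
    noise; the smallest qualifying k is the conservative choice.

    ``exclude_genes`` (typically the siRNA-targeted transcripts) are left
    out of criterion (a): residualizing a row that carries a large
    knockdown dip on batch-patterned factor scores displaces that gene's
    control arrays, so targeted transcripts show spurious control-group
    differences at every k.
    """
    from . import diffexpr  # local import to avoid a cycle at module load

    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k_grid is empty")
    meta = mat.arrays
    batches = sorted(set(meta["batch"]))
    ctl_groups = {b: mat.control_arrays(batch=b) for b in batches}
    exps = mat.experiments()
    rep_pairs = [
        list(grp["experiment"])
        for cond, grp in exps.groupby("condition")
        if len(grp) > 1
    ]

    excl = set(exclude_genes or [])
    a_genes = [g for g in mat.values.index if g not in excl]
    records = []
    for k in k_grid:
        factors = fit_ruv(mat.values, controls, k)
        adj = adjust_matrix(mat, factors)
        # (a) control-group DE across batches
        a = 0
        for i in range(len(batches)):
            for j in range(i + 1, len(batches)):
                g1, g2 = ctl_groups[batches[i]], ctl_groups[batches[j]]
                if len(g1) < 2 or len(g2) < 2:
                    continue
                tab = diffexpr.de_table(adj.values[g1 + g2], g1, g2,
                                        genes=a_genes)
                a += int((tab["q"] <= fdr).sum())
        # (b), (c) replicated knockdowns vs the control arrays
        pooled = pool_controls(adj) if pool else adj
        ctl_cols = pooled.control_arrays()
        b_common, cors = 0, []
        for pair in rep_pairs:
            sets, logps = [], []
            for exp in pair:
                kd = pooled.experiment_arrays(exp)
                tab = diffexpr.de_table(pooled.values, kd, ctl_cols)
                sets.append(set(tab.index[tab["q"] <= fdr]))
                logps.append(-np.log10(tab["p"]))
            for i in range(len(sets)):
                for j in range(i + 1, len(sets)):
                    b_common += len(sets[i] & sets[j])
                    cors.append(float(np.corrcoef(logps[i], logps[j])[0, 1]))
        records.append(
            {"k": k, "control_de": a, "replicated_de_common": b_common,
             "replicate_logp_cor": float(np.mean(cors)) if cors else np.nan}
        )
    table = pd.DataFrame(records)
    zero = table[table["control_de"] == 0]
    pool = zero if len(zero) else table[table["control_de"] == table["control_de"].min()]
    bmax = pool["replicated_de_common"].max()
    near = pool[pool["replicated_de_common"] >= bmax - np.sqrt(max(bmax, 1))]
    return int(near["k"].min()), table


# ---------------------------------------------------------------------------
# QC diagnostics
# ---------------------------------------------------------------------------

def rle_stats(values: pd.DataFrame) -> pd.DataFrame:
    """Relative log expression: per-array median and IQR of deviations from
    the gene-wise median across arrays."""
    dev = values.sub(values.median(axis=1), axis=0)
    q1 = dev.quantile(0.25)
    q3 = dev.quantile(0.75)
    return pd.DataFrame(
        {"median": dev.median(), "iqr": q3 - q1}
    ).rename_axis("array_id")


def pca_diagnostics(values: pd.DataFrame, metadata: pd.DataFrame,
                    n_components: int = 10) -> dict:
    """Array-space principal components, variance fractions, and per-component
    association with batch (one-way location test)."""
    if values.shape[1] < 3:
        raise ValueError("PCA diagnostics require at least 3 arrays")
    X = values.to_numpy(dtype=float).T  # arrays x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U * S
    varfrac = S**2 / np.sum(S**2)
    n_comp = min(n_components, scores.shape[1])
    batches = metadata.loc[values.columns, "batch"]
    groups_idx = [np.flatnonzero((batches == b).to_numpy())
                  for b in sorted(set(batches))]
    assoc = []
    for c in range(n_comp):
        if len(groups_idx) < 2:
            assoc.append(np.nan)
            continue
        samples = [scores[g, c] for g in groups_idx]
        assoc.append(float(f_oneway(*samples).pvalue))
    return {
        "scores": pd.DataFrame(scores[:, :n_comp], index=values.columns,
                               columns=[f"PC{i+1}" for i in range(n_comp)]),
        "variance_fraction": pd.Series(varfrac,
                                       index=[f"PC{i+1}" for i in range(len(varfrac))]),
        "batch_assoc_p": pd.Series(assoc,
                                   index=[f"PC{i+1}" for i in range(n_comp)]),
    }
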