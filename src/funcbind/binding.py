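"""Binding maps and their assignment to genes.

Binding evidence of two kinds — ChIP peaks and footprint-style sites with
occupancy posteriors — is unified per factor into a set of midpoint
coordinates, then assigned to genes either by distance to a single
reference TSS per gene (chosen as the candidate with the highest CAGE
score) or by membership in distal regulatory elements linked to genes.

Conventions: all interval files are 0-based half-open; midpoints are
floor((start + end) / 2); the window predicate is inclusive on absolute
distance (|midpoint - TSS| <= window), with an optional strict inner
exclusion radius for promoter-excluded analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

POSTERIOR_THRESHOLD = 0.95
UNANNOTATED = "unannotated"


# ---------------------------------------------------------------------------
# reference TSS
# ---------------------------------------------------------------------------

def select_reference_tss(candidates: pd.DataFrame) -> pd.DataFrame:
    """One reference TSS per gene: highest CAGE score, ties resolved to the
    floor midpoint of the tied positions (strand carried through).

    ``candidates`` needs columns gene, chrom, strand, position, cage_score.
    """
    rows = []
    for gene, grp in candidates.groupby("gene", sort=True):
        if grp["chrom"].nunique() > 1:
            raise ValueError(f"gene {gene} has candidate TSSs on multiple chromosomes")
        best = grp[grp["cage_score"] == grp["cage_score"].max()]
        if len(best) == 1:
            pos = int(best["position"].iloc[0])
        else:
            tied = best["position"].to_numpy()
            pos = int((int(tied.min()) + int(tied.max())) // 2)
        rows.append(
            {"gene": gene, "chrom": grp["chrom"].iloc[0],
             "strand": grp["strand"].iloc[0], "position": pos,
             "cage_score": float(best["cage_score"].iloc[0])}
        )
    return pd.DataFrame(rows, columns=["gene", "chrom", "strand",
                                       "position", "cage_score"])


# ---------------------------------------------------------------------------
# unification
# ---------------------------------------------------------------------------

def unify_binding_events(
    records: pd.DataFrame,
    posterior_threshold: float = POSTERIOR_THRESHOLD,
) -> pd.DataFrame:
    """Union of all binding records per factor, reduced to midpoints.

    Footprint-style records (source == 'dnase') are kept only with
    posterior strictly greater than the threshold; ChIP records carry no
    posterior and always pass. Each interval [start, end) becomes the
    single coordinate floor((start + end) / 2); duplicates are collapsed on
    (factor, chrom, midpoint).
    """
    df = records.copy()
    if "midpoint" not in df.columns:
        if (df["end"] <= df["start"]).any():
            raise ValueError("malformed interval: end <= start")
        df["midpoint"] = (df["start"] + df["end"]) // 2
    if "source" in df.columns:
        is_dnase = df["source"] == "dnase"
    else:
        is_dnase = df["posterior"].notna()
    keep = ~is_dnase | (df["posterior"] > posterior_threshold)
    df = df[keep]
    df = df.drop_duplicates(subset=["factor", "chrom", "midpoint"], keep="first")
    cols = ["factor", "chrom", "midpoint"] + [
        c for c in ["source", "posterior", "motif_score", "cons_score"]
        if c in df.columns
    ]
    return df[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

@dataclass
class TargetAssignment:
    """Events assigned to genes, as pair rows and (gene, factor) counts."""

    pairs: pd.DataFrame   # gene, factor, chrom, midpoint, distance
    counts: pd.DataFrame  # gene, factor, count
    window_min: int = 0   # exclusive inner radius (0 = none)
    window_max: Optional[int] = None  # inclusive outer radius (None for distal)

    def bound_genes(self, factors: Optional[Sequence[str]] = None) -> set:
        df = self.counts
        if factors is not None:
            df = df[df["factor"].isin(set(factors))]
        return set(df["gene"])


def _counts(pairs: pd.DataFrame) -> pd.DataFrame:
    if len(pairs) == 0:
        return pd.DataFrame(columns=["gene", "factor", "count"])
    return (
        pairs.groupby(["gene", "factor"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )


def assign_targets_window(
    events: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = 10_000,
    inner: int = 0,
) -> TargetAssignment:
    """Count events per (gene, factor) with inner < |midpoint - TSS| <= window
    on the same chromosome (inner = 0 recovers the plain window)."""
    if window <= 0:
        raise ValueError("window must be positive")
    pair_rows = []
    for chrom, ev in events.groupby("chrom"):
        ts = tss[tss["chrom"] == chrom]
        if len(ts) == 0:
            continue
        mids = ev["midpoint"].to_numpy()
        order = np.argsort(mids, kind="mergesort")
        mids_sorted = mids[order]
        ev_sorted = ev.iloc[order]
        for _, t in ts.iterrows():
            lo = np.searchsorted(mids_sorted, t["position"] - window, side="left")
            hi = np.searchsorted(mids_sorted, t["position"] + window, side="right")
            if hi <= lo:
                continue
            block = ev_sorted.iloc[lo:hi]
            dist = np.abs(block["midpoint"].to_numpy() - int(t["position"]))
            ok = dist > inner if inner > 0 else np.ones(len(block), dtype=bool)
            for (_, e), d in zip(block[ok].iterrows(), dist[ok]):
                pair_rows.append(
                    {"gene": t["gene"], "factor": e["factor"], "chrom": chrom,
                     "midpoint": int(e["midpoint"]), "distance": int(d)}
                )
    pairs = pd.DataFrame(pair_rows, columns=["gene", "factor", "chrom",
                                             "midpoint", "distance"])
    return TargetAssignment(pairs=pairs, counts=_counts(pairs),
                            window_min=inner, window_max=window)


def assign_targets_distal(events: pd.DataFrame,
                          links: pd.DataFrame) -> TargetAssignment:
    """Assign an event to gene g iff its midpoint lies inside a distal
    element linked to g (half-open intervals; multi-gene elements allowed)."""
    if len(links) and (links["end"] <= links["start"]).any():
        raise ValueError("malformed distal element: end <= start")
    pair_rows = []
    for chrom, ev in events.groupby("chrom"):
        ln = links[links["chrom"] == chrom]
        if len(ln) == 0:
            continue
        mids = ev["midpoint"].to_numpy()
        order = np.argsort(mids, kind="mergesort")
        mids_sorted = mids[order]
        ev_sorted = ev.iloc[order]
        for _, el in ln.iterrows():
            lo = np.searchsorted(mids_sorted, el["start"], side="left")
            hi = np.searchsorted(mids_sorted, el["end"] - 1, side="right")
            for _, e in ev_sorted.iloc[lo:hi].iterrows():
                pair_rows.append(
                    {"gene": el["gene"], "factor": e["factor"], "chrom": chrom,
                     "midpoint": int(e["midpoint"]),
                     "distance": np.nan}
                )
    pairs = pd.DataFrame(pair_rows, columns=["gene", "factor", "chrom",
                                             "midpoint", "distance"])
    pairs = pairs.drop_duplicates(subset=["gene", "factor", "chrom", "midpoint"])
    return TargetAssignment(pairs=pairs.reset_index(drop=True),
                            counts=_counts(pairs), window_max=None)


# ---------------------------------------------------------------------------
# chromatin states & distances
# ---------------------------------------------------------------------------

def annotate_site_state(events: pd.DataFrame, states: pd.DataFrame) -> pd.Series:
    """Label each event with the (unique) state segment containing its
    midpoint; midpoints outside every segment get 'unannotated'."""
    out = pd.Series(UNANNOTATED, index=events.index, dtype=object)
    for chrom, ev in events.groupby("chrom"):
        seg = states[states["chrom"] == chrom].sort_values("start")
        if len(seg) == 0:
            continue
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        labels = seg["state"].to_numpy()
        mids = ev["midpoint"].to_numpy()
        idx = np.searchsorted(starts, mids, side="right") - 1
        inside = (idx >= 0) & (mids < ends[np.clip(idx, 0, len(ends) - 1)])
        vals = np.where(inside, labels[np.clip(idx, 0, len(labels) - 1)],
                        UNANNOTATED)
        out.loc[ev.index] = vals
    return out


def site_distance_to_tss(pairs: pd.DataFrame, scale: str = "kb") -> pd.DataFrame:
    """Distance table per (event, gene) pair with a log10(d + 0.001)
    transform; the offset is applied on the kb scale by default (``scale='bp'``
    applies it to raw base pairs)."""
    out = pairs.copy()
    d = out["distance"].to_numpy(dtype=float)
    if scale == "kb":
        out["log10_distance"] = np.log10(d / 1000.0 + 0.001)
    elif scale == "bp":
        out["log10_distance"] = np.log10(d + 0.001)
    else:
        raise ValueError(f"unknown scale: {scale}")
    return out
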