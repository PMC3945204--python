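"""End-to-end analysis: normalization -> DE -> binding maps -> integration.

`run_analysis` executes the whole chain on a fixture directory (or
in-memory study objects) and returns an :class:`AnalysisResult` holding
every intermediate and final table; `write_results` serializes the result
tables as TSV. The experiment-level *mode* controls which factors count as
"relevant" for binding: ``direct`` uses only the siRNA-targeted factor
(experiments without binding data for it are skipped), ``downstream`` adds
every factor with binding data that is itself differentially expressed in
the experiment.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from . import binding as bnd
from . import diffexpr as de
from . import integrate as itg
from . import preprocess as pre
from .config import SimConfig
from .matrix import ExpressionMatrix
from .synthdata import read_fixtures

log = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    cfg: SimConfig
    k_selected: int
    k_table: pd.DataFrame
    n_control_probes: int
    expressed: Dict[str, List[str]]
    de_tables: Dict[str, pd.DataFrame]
    efficiencies: pd.DataFrame
    tss: pd.DataFrame
    events: pd.DataFrame
    assignment: bnd.TargetAssignment
    assignment_distal: Optional[bnd.TargetAssignment]
    overlap: pd.DataFrame
    overlap_distal: Optional[pd.DataFrame]
    calls: Dict[str, pd.DataFrame]          # downstream-mode calls per experiment
    calls_direct: Dict[str, pd.DataFrame]   # direct-mode calls per experiment
    state_enrichment: pd.DataFrame
    state_enrichment_pooled: pd.DataFrame
    site_features: pd.DataFrame
    cooccupancy_pairs: pd.DataFrame
    cooccupancy_bins: pd.DataFrame
    direction: pd.DataFrame
    window_sens: pd.DataFrame
    qc: Dict[str, pd.DataFrame] = field(default_factory=dict)


def _overlap_row(exp: str, mode: str, tab: itg.OverlapTable) -> dict:
    return {
        "experiment": exp, "mode": mode, "n_expressed": tab.n,
        "n_bound": tab.a + tab.b, "n_de": tab.a + tab.c, "n_overlap": tab.a,
        "frac_bound_de": tab.frac_bound_de, "frac_de_bound": tab.frac_de_bound,
        "odds_ratio": tab.odds_ratio, "fisher_p": tab.fisher_p,
        "rel_enrichment": tab.rel_enrichment,
    }


def run_analysis(
    datadir: Optional[str] = None,
    *,
    cfg: Optional[SimConfig] = None,
    mat: Optional[ExpressionMatrix] = None,
    probes: Optional[pd.DataFrame] = None,
    binding_records: Optional[pd.DataFrame] = None,
    tss_candidates: Optional[pd.DataFrame] = None,
    states: Optional[pd.DataFrame] = None,
    links: Optional[pd.DataFrame] = None,
    truth: Optional[dict] = None,
    fdr: Optional[float] = None,
    window: Optional[int] = None,
    inner: int = 0,
    k: Optional[int] = None,
    mode: str = "downstream",
    k_grid: Optional[Sequence[int]] = None,
    run_qc: bool = True,
) -> AnalysisResult:
    if datadir is not None:
        cfg, mat, probes, binding_records, tss_candidates, states, links, truth = (
            read_fixtures(datadir)
        )
    if cfg is None or mat is None or probes is None:
        raise ValueError("either datadir or in-memory study objects are required")
    if mode not in {"direct", "downstream"}:
        raise ValueError("mode must be 'direct' or 'downstream'")
    fdr = cfg.fdr if fdr is None else fdr
    window = cfg.window if window is None else window

    # --- normalization -----------------------------------------------------
    retained = pre.filter_probes(probes)
    gmat = pre.probes_to_genes(mat, retained)
    gmat = gmat.with_values(pre.quantile_normalize(gmat.values))
    log.info("normalized %d genes x %d arrays", *gmat.values.shape)

    exps = gmat.experiments()
    ctl_all = gmat.control_arrays()
    expressed = {
        row["experiment"]: pre.detection_filter(gmat, row["arrays"], ctl_all,
                                                cfg.detection_p)
        for _, row in exps.iterrows()
    }
    union_expressed = sorted(set().union(*expressed.values()))

    controls = pre.select_control_probes(
        gmat.values, gmat.arrays["batch"], cfg.n_control_probes,
        candidates=union_expressed,
    )
    if k is None:
        grid = list(k_grid) if k_grid is not None else list(range(cfg.k_grid_max + 1))
        targeted = set(exps["condition"])
        # run the diagnostic on expression-passing genes only: rows below
        # the detection floor are normalization artifacts, not biology
        k, k_table = pre.choose_k(gmat.subset_rows(union_expressed), controls,
                                  grid, fdr=fdr, pool=cfg.pool_controls_de,
                                  exclude_genes=targeted)
    else:
        k_table = pd.DataFrame()
    factors = pre.fit_ruv(gmat.values, controls, k)
    adj = pre.adjust_matrix(gmat, factors)
    log.info("removed k=%d components using %d control probes",
             k, len(controls.intersection))

    qc: Dict[str, pd.DataFrame] = {}
    if run_qc:
        qc["rle_before"] = pre.rle_stats(gmat.values)
        qc["rle_after"] = pre.rle_stats(adj.values)
        pca_b = pre.pca_diagnostics(gmat.values, gmat.arrays)
        pca_a = pre.pca_diagnostics(adj.values, adj.arrays)
        qc["pca_batch_assoc"] = pd.DataFrame(
            {"before": pca_b["batch_assoc_p"], "after": pca_a["batch_assoc_p"]}
        )
        qc["pca_varfrac"] = pd.DataFrame(
            {"before": pca_b["variance_fraction"].iloc[:10],
             "after": pca_a["variance_fraction"].iloc[:10]}
        )

    # --- differential expression ------------------------------------------
    pooled = pre.pool_controls(adj) if cfg.pool_controls_de else adj
    ctl_pool = pooled.control_arrays()
    de_tables: Dict[str, pd.DataFrame] = {}
    eff_rows = []
    for _, row in exps.iterrows():
        exp, cond = row["experiment"], row["condition"]
        tab = de.de_table(pooled.values, row["arrays"], ctl_pool,
                          genes=expressed[exp], dist=cfg.lrt_dist)
        de_tables[exp] = tab
        # knockdown efficiency against same-batch controls: within-batch
        # contrasts are unaffected by the batch-space component the factor
        # adjustment absorbs from the knockdown signature.
        ctl_batch = adj.control_arrays(batch=row["batch"])
        eff_tab = de.de_table(adj.values, row["arrays"],
                              ctl_batch or ctl_pool, genes=[cond]
                              if cond in adj.values.index else None,
                              dist=cfg.lrt_dist)
        eff_rows.append({
            "experiment": exp, "condition": cond,
            "n_expressed": len(expressed[exp]),
            "n_de": int((tab["q"] <= fdr).sum()),
            "efficiency_pct": de.knockdown_efficiency_array(eff_tab, cond),
        })
    efficiencies = pd.DataFrame(eff_rows)

    # --- binding maps ------------------------------------------------------
    tss = bnd.select_reference_tss(tss_candidates)
    events = bnd.unify_binding_events(binding_records)
    assignment = bnd.assign_targets_window(events, tss, window=window, inner=inner)
    assignment_distal = None
    if links is not None and len(links):
        assignment_distal = bnd.assign_targets_distal(events, links)
    site_states = bnd.annotate_site_state(events, states)
    events = events.assign(state=site_states.to_numpy())

    factors_with_binding = set(events["factor"])
    de_sets = {e: set(de.call_de(t, fdr)) for e, t in de_tables.items()}
    de_tf_sets = {}
    for _, row in exps.iterrows():
        exp, cond = row["experiment"], row["condition"]
        tfs = {f for f in factors_with_binding if f in de_sets[exp]}
        if cond in factors_with_binding:
            tfs.add(cond)
        de_tf_sets[exp] = tfs

    # --- classification & overlap ------------------------------------------
    overlap_rows = []
    calls: Dict[str, pd.DataFrame] = {}
    calls_direct: Dict[str, pd.DataFrame] = {}
    for _, row in exps.iterrows():
        exp, cond = row["experiment"], row["condition"]
        if cond in factors_with_binding:
            c, tab = itg.classify_functional(assignment, de_tables[exp], fdr, [cond])
            calls_direct[exp] = c
            overlap_rows.append(_overlap_row(exp, "direct", tab))
        else:
            log.info("experiment %s skipped in direct mode: no binding data "
                     "for %s", exp, cond)
        if de_tf_sets[exp]:
            c, tab = itg.classify_functional(assignment, de_tables[exp], fdr,
                                             sorted(de_tf_sets[exp]))
            calls[exp] = c
            overlap_rows.append(_overlap_row(exp, "downstream", tab))
    overlap = pd.DataFrame(overlap_rows)

    overlap_distal = None
    if assignment_distal is not None:
        rows = []
        for _, row in exps.iterrows():
            exp, cond = row["experiment"], row["condition"]
            if cond not in factors_with_binding:
                continue
            _, tab = itg.classify_functional(assignment_distal, de_tables[exp],
                                             fdr, [cond])
            rows.append(_overlap_row(exp, "direct", tab))
        overlap_distal = pd.DataFrame(rows)

    # --- chromatin-state enrichment ----------------------------------------
    state_key = events.set_index(["factor", "chrom", "midpoint"])["state"]
    se_rows, pooled_ev = [], []
    for _, row in exps.iterrows():
        exp = row["experiment"]
        rel = de_tf_sets[exp] if mode == "downstream" else {row["condition"]}
        pairs = assignment.pairs
        pairs = pairs[pairs["factor"].isin(rel)
                      & pairs["gene"].isin(set(expressed[exp]))]
        if len(pairs) == 0:
            continue
        ev = itg.event_de_status(pairs, de_sets[exp])
        ev["state"] = state_key.loc[
            list(zip(ev["factor"], ev["chrom"], ev["midpoint"]))
        ].to_numpy()
        ev["experiment"] = exp
        pooled_ev.append(ev)
        res = itg.state_enrichment(ev["state"], ev["de"])
        res.insert(0, "experiment", exp)
        se_rows.append(res)
    state_tab = pd.concat(se_rows, ignore_index=True) if se_rows else pd.DataFrame()
    if pooled_ev:
        allev = pd.concat(pooled_ev, ignore_index=True)
        state_pooled = itg.state_enrichment(allev["state"], allev["de"])
    else:
        state_pooled = pd.DataFrame()

    # --- site features ------------------------------------------------------
    feat_rows = []
    ev_feat = events.set_index(["factor", "chrom", "midpoint"])
    for _, row in exps.iterrows():
        exp = row["experiment"]
        rel = de_tf_sets[exp] if mode == "downstream" else {row["condition"]}
        pairs = assignment.pairs
        pairs = pairs[pairs["factor"].isin(rel)
                      & pairs["gene"].isin(set(expressed[exp]))].copy()
        if len(pairs) == 0:
            continue
        pairs["de"] = pairs["gene"].isin(de_sets[exp])
        keys = list(zip(pairs["factor"], pairs["chrom"], pairs["midpoint"]))
        for feat in ["motif_score", "cons_score"]:
            vals = ev_feat.loc[keys, feat].to_numpy()
            shift, stat, p = itg.compare_site_features(
                vals[pairs["de"].to_numpy()], vals[~pairs["de"].to_numpy()],
                method="asymptotic")
            feat_rows.append({"experiment": exp, "feature": feat,
                              "shift": shift, "stat": stat, "p": p})
        shift, stat, p = itg.compare_site_features(
            pairs.loc[pairs["de"], "distance"],
            pairs.loc[~pairs["de"], "distance"], method="asymptotic")
        feat_rows.append({"experiment": exp, "feature": "distance",
                          "shift": shift, "stat": stat, "p": p})
        per_gene = pairs.groupby("gene").agg(
            n_sites=("midpoint", "size"), n_factors=("factor", "nunique"))
        per_gene["de"] = per_gene.index.isin(de_sets[exp])
        for feat in ["n_sites", "n_factors"]:
            shift, stat, p = itg.compare_site_features(
                per_gene.loc[per_gene["de"], feat],
                per_gene.loc[~per_gene["de"], feat], method="asymptotic")
            feat_rows.append({"experiment": exp, "feature": feat,
                              "shift": shift, "stat": stat, "p": p})
    site_features = pd.DataFrame(feat_rows)

    # --- co-occupancy -------------------------------------------------------
    if len(de_tf_sets) >= 2:
        co_pairs, co_bins = itg.cooccupancy_enrichment(
            de_tf_sets, de_sets, {e: set(g) for e, g in expressed.items()},
            assignment)
    else:
        co_pairs, co_bins = pd.DataFrame(), pd.DataFrame()

    # --- direction of effect ------------------------------------------------
    dir_rows = []
    for exp, c in calls_direct.items():
        d = itg.direction_of_effect(c, de_tables[exp])
        d["experiment"] = exp
        dir_rows.append(d)
    direction = pd.DataFrame(dir_rows)

    # --- window sensitivity -------------------------------------------------
    per_exp = {}
    for _, row in exps.iterrows():
        exp, cond = row["experiment"], row["condition"]
        if cond not in factors_with_binding:
            continue
        per_exp[exp] = {"expressed": set(expressed[exp]),
                        "de": de_sets[exp], "factors": {cond}}
    window_sens = (
        itg.window_sensitivity(events, tss, per_exp) if per_exp else pd.DataFrame()
    )

    return AnalysisResult(
        cfg=cfg, k_selected=k, k_table=k_table,
        n_control_probes=len(controls.intersection),
        expressed=expressed, de_tables=de_tables, efficiencies=efficiencies,
        tss=tss, events=events, assignment=assignment,
        assignment_distal=assignment_distal, overlap=overlap,
        overlap_distal=overlap_distal, calls=calls, calls_direct=calls_direct,
        state_enrichment=state_tab, state_enrichment_pooled=state_pooled,
        site_features=site_features, cooccupancy_pairs=co_pairs,
        cooccupancy_bins=co_bins, direction=direction, window_sens=window_sens,
        qc=qc,
    )


def write_results(result: AnalysisResult, outdir: str) -> List[str]:
    """Serialize all result tables as TSV under ``outdir``; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    written = []

    def w(name: str, df: pd.DataFrame, index: bool = False) -> None:
        if df is None or len(df) == 0:
            return
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=index)
        written.append(path)

    w("overlap.tsv", result.overlap)
    if result.overlap_distal is not None:
        w("overlap_distal.tsv", result.overlap_distal)
    w("efficiencies.tsv", result.efficiencies)
    w("k_table.tsv", result.k_table)
    w("state_enrichment.tsv", result.state_enrichment)
    w("state_enrichment_pooled.tsv", result.state_enrichment_pooled)
    w("site_features.tsv", result.site_features)
    w("cooccupancy_pairs.tsv", result.cooccupancy_pairs)
    w("cooccupancy_bins.tsv", result.cooccupancy_bins)
    w("direction.tsv", result.direction)
    w("window_sensitivity.tsv", result.window_sens)
    w("binding_counts.tsv", result.assignment.counts)
    for name, df in result.qc.items():
        w(f"qc_{name}.tsv", df, index=True)
    de_dir = os.path.join(outdir, "de_tables")
    os.makedirs(de_dir, exist_ok=True)
    for exp, tab in result.de_tables.items():
        path = os.path.join(de_dir, f"de_{exp}.tsv")
        tab.rename_axis("gene").to_csv(path, sep="\t")
        written.append(path)
    return written
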