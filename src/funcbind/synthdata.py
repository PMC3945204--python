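"""Ground-truthed synthetic knockdown study.

Three generators build, in order, a regulatory network (which TF binds and
regulates which gene, with signed log2 effects), a genome annotation (one
synthetic chromosome with candidate TSSs, tiled chromatin states, binding
events, and distal-element links), and a raw expression matrix (knockdown
effects plus batch-correlated unwanted variation plus noise). Every
generator is a pure function of the :class:`~funcbind.config.SimConfig`:
randomness comes from per-stage substreams of the config seed
(stage 0 = network, 1 = annotation, 2 = expression).

The planted structure mirrors what the downstream analysis assumes:

* each knocked-down factor has both up- and down-regulated true targets,
  with median |fold change - 1| calibrated to ``median_effect_pct``;
* only ``functional_fraction`` of a factor's bound genes are true targets —
  the rest is decoy binding, concentrated near promoters;
* functional sites are preferentially placed in "strong enhancer" chromatin
  (weight ``enhancer_enrichment``) and carry motif scores shifted by
  ``motif_shift``; conservation is shifted by ``cons_shift`` (default 0);
* unwanted variation is ``k_true`` hidden factors with batch-level means and
  per-array jitter acting on all genes through Gaussian loadings — exactly
  the structure a control-gene factor adjustment can remove.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from .matrix import CONTROL, ExpressionMatrix

# 12 merged chromatin-state labels (duplicate enhancer/repetitive classes of
# the 15-state segmentation collapsed).
STATES = [
    "Active_Promoter",
    "Weak_Promoter",
    "Poised_Promoter",
    "Strong_Enhancer",
    "Weak_Enhancer",
    "Insulator",
    "Txn_Transition",
    "Txn_Elongation",
    "Weak_Txn",
    "Repressed",
    "Heterochrom",
    "Repetitive",
]
STRONG_ENHANCER = "Strong_Enhancer"
CHROM = "chrS"

_PROMOTER_STATES = ["Active_Promoter", "Weak_Promoter", "Poised_Promoter"]
_PROMOTER_W = [0.6, 0.3, 0.1]
_DISTAL_STATES = [
    "Strong_Enhancer", "Weak_Enhancer", "Insulator", "Txn_Transition",
    "Txn_Elongation", "Weak_Txn", "Repressed", "Heterochrom", "Repetitive",
]
_DISTAL_W = [0.18, 0.12, 0.06, 0.06, 0.12, 0.15, 0.12, 0.12, 0.07]

#: half-width (bp) of the neighborhood around each gene that is finely tiled
#: with chromatin-state segments and used for site placement.
NEIGHBORHOOD = 30_000
#: promoter zone half-width for state tiling.
PROMOTER_HALF = 1_000
#: events are placed within this margin of the gene's reference point so the
#: guaranteed site stays inside the 10 kb analysis window for any candidate TSS.
PLACEMENT_HALF = 9_600
#: candidates drawn per functional site for enhancer-weighted placement;
#: with the default segment weights this puts ~20% of functional sites in
#: strong-enhancer chromatin at enhancer_enrichment=5 (vs ~5% of decoys).
N_CANDIDATES = 12


def gene_ids(cfg: SimConfig) -> List[str]:
    return [f"G{i:04d}" for i in range(cfg.n_genes)]


def gene_positions(cfg: SimConfig) -> Dict[str, int]:
    """Deterministic locus anchor for each gene on the single chromosome."""
    return {g: cfg.gene_spacing * (i + 1) for i, g in enumerate(gene_ids(cfg))}


def chrom_length(cfg: SimConfig) -> int:
    return cfg.gene_spacing * (cfg.n_genes + 1)


@dataclass
class RegulatoryNetwork:
    """Signed TF -> target edges.

    ``bound`` marks binding relationships (events are generated for them),
    ``regulated`` marks targets whose expression responds to the knockdown
    (bound or not), and ``functional`` = bound & regulated — the planted
    version of the study's operational definition. Decoy binding is
    bound & ~regulated; indirect targets are regulated & ~bound.
    """

    edges: pd.DataFrame  # tf, target, sign, effect, functional, bound, regulated
    tf_list: List[str]
    modules: Dict[str, int]  # tf -> module index

    def functional_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["functional"]]

    def regulated_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["regulated"]]

    def bound_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["bound"]]

    def targets_of(self, tf: str, functional_only: bool = False) -> List[str]:
        e = self.edges[self.edges["tf"] == tf]
        if functional_only:
            e = e[e["functional"]]
        return list(e["target"])


@dataclass
class GenomeLayout:
    chrom: str
    length: int
    tss_candidates: pd.DataFrame   # gene, chrom, strand, position, cage_score
    states: pd.DataFrame           # chrom, start, end, state (0-based half-open tiling)
    events: pd.DataFrame           # factor, chrom, midpoint, source, posterior,
                                   # motif_score, cons_score, functional, target
    distal_links: pd.DataFrame     # chrom, start, end, gene, score


@dataclass
class SimTruth:
    """Ground truth recorded alongside the raw matrix."""

    experiments: pd.DataFrame      # experiment, condition, batch, kappa
    edges: pd.DataFrame            # as RegulatoryNetwork.edges
    events: pd.DataFrame           # factor, chrom, midpoint, functional, target
    factor_scores: pd.DataFrame    # arrays x k_true planted factor scores
    direct_effects: pd.DataFrame   # experiment x gene planted log2 deltas


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def generate_network(cfg: SimConfig) -> RegulatoryNetwork:
    """Draw the bound-gene sets and true-target effects for every TF.

    Each TF binds ~``mean_out_degree`` genes; a fraction
    ``functional_fraction`` of them are true targets with signed log2
    effects whose median |fold change - 1| equals ``median_effect_pct``.
    TFs in the same module share a target pool (and target each other),
    which plants the co-occupancy structure.
    """
    cfg.validate()
    rng = cfg.rng(0)
    genes = gene_ids(cfg)
    tfs = genes[: cfg.n_tfs]

    msize = max(1, int(cfg.tf_module_size))
    modules = {tf: i // msize for i, tf in enumerate(tfs)}

    # per-module shared target pools; include the module's own TFs so that
    # knockdowns within a module perturb each other (downstream DE factors).
    pool_size = max(4, int(round(cfg.mean_out_degree)))
    pools: Dict[int, np.ndarray] = {}
    for m in sorted(set(modules.values())):
        members = [tf for tf in tfs if modules[tf] == m]
        others = rng.choice(cfg.n_genes, size=pool_size, replace=False)
        pool = np.unique(
            np.concatenate([others, [genes.index(t) for t in members]])
        )
        pools[m] = pool

    scale = (cfg.median_effect_pct / 100.0) / math.log(2.0)

    def draw_effects(n):
        signs = np.where(rng.random(n) < cfg.up_fraction, 1, -1)
        frac = rng.exponential(scale=scale, size=n)
        return signs, signs * np.log2(1.0 + frac)

    rows = []
    for tf in tfs:
        i_tf = genes.index(tf)
        # per-(tf, target) edge records, keyed by target index
        edges_tf: Dict[int, dict] = {}

        def put(t: int, bound: bool, regulated: bool, sign=0, effect=0.0) -> None:
            rec = edges_tf.setdefault(
                t, {"tf": tf, "target": genes[t], "sign": 0, "effect": 0.0,
                    "functional": False, "bound": False, "regulated": False}
            )
            rec["bound"] = rec["bound"] or bound
            if regulated and not rec["regulated"]:
                rec["regulated"] = True
                rec["sign"], rec["effect"] = int(sign), float(effect)
            # functional = planted bound-and-regulated linkage only
            if bound and regulated:
                rec["functional"] = True

        # --- bound genes (module-shared pool + free draws) ---------------
        deg = max(1, rng.poisson(cfg.mean_out_degree))
        n_shared = int(round(cfg.module_target_overlap * deg)) if msize > 1 else 0
        pool = pools[modules[tf]]
        pool = pool[pool != i_tf]
        shared = rng.choice(pool, size=min(n_shared, len(pool)), replace=False)
        n_free = deg - len(shared)
        free = rng.choice(cfg.n_genes, size=max(n_free, 0) + 8, replace=False)
        free = free[(free != i_tf) & ~np.isin(free, shared)][: max(n_free, 0)]
        targets = np.unique(np.concatenate([shared, free]))
        func = rng.random(len(targets)) < cfg.functional_fraction
        signs, effects = draw_effects(len(targets))
        # guarantee both directions among functional targets when possible
        fidx = np.flatnonzero(func)
        if len(fidx) >= 2 and len(set(signs[fidx])) == 1:
            j = fidx[0]
            signs[j], effects[j] = -signs[j], -effects[j]
        for t, s, e, f in zip(targets, signs, effects, func):
            put(int(t), bound=True, regulated=bool(f), sign=s, effect=e)

        # --- regulated-but-unbound (indirect) targets ---------------------
        # Drawn independently of the bound set (a decoy-bound gene may be
        # independently regulated — that is what independence of binding
        # and regulation means; such chance overlaps are not flagged
        # functional). Module-shared draws plant co-regulation.
        n_unb = rng.poisson(cfg.mean_unbound_targets)
        n_unb_shared = int(round(cfg.module_target_overlap * n_unb)) if msize > 1 else 0
        cand_shared = rng.choice(pool, size=min(n_unb_shared, len(pool)),
                                 replace=False)
        cand_free = rng.choice(cfg.n_genes, size=max(n_unb - n_unb_shared, 0) + 8,
                               replace=False)
        cand_free = cand_free[cand_free != i_tf][: max(n_unb - n_unb_shared, 0)]
        s_u, e_u = draw_effects(n_unb + 8)
        for i, t in enumerate(np.concatenate([cand_shared, cand_free])):
            t = int(t)
            if t in edges_tf and edges_tf[t]["regulated"]:
                continue
            put(t, bound=False, regulated=True, sign=s_u[i], effect=e_u[i])

        # --- co-regulated module mates ------------------------------------
        for mate in tfs:
            if mate == tf or modules[mate] != modules[tf]:
                continue
            if rng.random() < cfg.module_tf_coupling:
                s_m, e_m = draw_effects(1)
                put(genes.index(mate), bound=False, regulated=True,
                    sign=s_m[0], effect=e_m[0])

        rows.extend(edges_tf[t] for t in sorted(edges_tf))
    edges = pd.DataFrame(rows, columns=["tf", "target", "sign", "effect",
                                        "functional", "bound", "regulated"])
    return RegulatoryNetwork(edges=edges, tf_list=tfs, modules=modules)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _tile_states(cfg: SimConfig, rng, anchors: np.ndarray) -> pd.DataFrame:
    """Tile the chromosome: finely segmented gene neighborhoods (promoter
    zone in the middle) separated by single broad filler segments."""
    L = chrom_length(cfg)
    starts, ends, labels = [], [], []
    cursor = 0

    def add(a: int, b: int, lab: str) -> None:
        if b > a:
            starts.append(a)
            ends.append(b)
            labels.append(lab)

    for pos in anchors:
        lo, hi = pos - NEIGHBORHOOD, pos + NEIGHBORHOOD
        if lo > cursor:
            add(cursor, lo, str(rng.choice(["Heterochrom", "Weak_Txn", "Repressed"])))
        # left flank
        c = max(cursor, lo)
        pz_lo, pz_hi = pos - PROMOTER_HALF, pos + PROMOTER_HALF
        while c < pz_lo:
            seg = min(int(rng.integers(600, 2400)), pz_lo - c)
            add(c, c + seg, str(rng.choice(_DISTAL_STATES, p=_DISTAL_W)))
            c += seg
        add(pz_lo, pz_hi, str(rng.choice(_PROMOTER_STATES, p=_PROMOTER_W)))
        c = pz_hi
        while c < hi:
            seg = min(int(rng.integers(600, 2400)), hi - c)
            add(c, c + seg, str(rng.choice(_DISTAL_STATES, p=_DISTAL_W)))
            c += seg
        cursor = hi
    if cursor < L:
        add(cursor, L, str(rng.choice(["Heterochrom", "Weak_Txn", "Repressed"])))
    return pd.DataFrame(
        {"chrom": CHROM, "start": starts, "end": ends, "state": labels}
    )


def _base_offsets(rng, n: int) -> np.ndarray:
    """Promoter-concentrated base placement: 70% tight around the anchor,
    30% uniform over the placement window."""
    near = np.clip(
        np.round(rng.normal(0.0, 400.0, size=n)), -PLACEMENT_HALF, PLACEMENT_HALF
    ).astype(int)
    far = rng.integers(-PLACEMENT_HALF, PLACEMENT_HALF + 1, size=n)
    return np.where(rng.random(n) < 0.7, near, far)


def generate_annotation(cfg: SimConfig, net: RegulatoryNetwork) -> GenomeLayout:
    """Lay out TSS candidates, chromatin states, binding events and distal links.

    Functional sites are placed by importance sampling: :data:`N_CANDIDATES`
    draws from the decoy base distribution, one chosen with weight
    ``enhancer_enrichment`` for candidates falling in strong-enhancer
    segments (weight 1 elsewhere). With ``enhancer_enrichment == 1`` this
    reduces exactly to the decoy placement.
    """
    cfg.validate()
    rng = cfg.rng(1)
    genes = gene_ids(cfg)
    known = set(genes)
    bad = set(net.edges["tf"]) | set(net.edges["target"])
    if not bad <= known:
        raise ConfigError(
            f"network references unknown genes: {sorted(bad - known)[:5]}"
        )
    pos = gene_positions(cfg)
    anchors = np.array([pos[g] for g in genes])

    # --- candidate TSSs ----------------------------------------------------
    trows = []
    for g in genes:
        n_cand = int(rng.integers(1, 4))
        offs = rng.choice(np.arange(-300, 301), size=n_cand, replace=False)
        strand = str(rng.choice(["+", "-"]))
        scores = np.round(rng.gamma(2.0, 50.0, size=n_cand), 3)
        for o, s in zip(np.sort(offs), scores):
            trows.append(
                {"gene": g, "chrom": CHROM, "strand": strand,
                 "position": int(pos[g] + o), "cage_score": float(s)}
            )
    tss = pd.DataFrame(trows)

    # --- chromatin states --------------------------------------------------
    states = _tile_states(cfg, rng, anchors)
    se = states[states["state"] == STRONG_ENHANCER]
    se_starts = se["start"].to_numpy()
    se_ends = se["end"].to_numpy()

    def in_strong_enhancer(p: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(se_starts, p, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(p), dtype=bool)
        out[ok] = p[ok] < se_ends[idx[ok]]
        return out

    # --- distal elements ---------------------------------------------------
    lrows = []
    for i, g in enumerate(genes):
        if rng.random() < 0.5:
            for _ in range(int(rng.integers(1, 3))):
                d = int(rng.integers(12_000, 40_000)) * (1 if rng.random() < 0.5 else -1)
                start = pos[g] + d
                row = {"chrom": CHROM, "start": start, "end": start + 400,
                       "gene": g, "score": round(float(rng.uniform(0.7, 1.0)), 3)}
                lrows.append(row)
                if rng.random() < 0.2 and i + 1 < len(genes):
                    lrows.append({**row, "gene": genes[i + 1]})
    links = pd.DataFrame(lrows, columns=["chrom", "start", "end", "gene", "score"])

    # --- binding events ----------------------------------------------------
    erows = []

    def add_event(factor: str, target: str, p: int, functional: bool) -> None:
        source = "dnase" if rng.random() < 0.5 else "chip"
        if source == "dnase":
            posterior = float(rng.uniform(0.951, 1.0))
            motif = float(rng.normal(10.0, 2.0))
            cons = float(np.clip(rng.normal(0.2, 0.1), 0.0, 1.0))
            if functional:
                motif += cfg.motif_shift
                cons = float(np.clip(cons + cfg.cons_shift, 0.0, 1.0))
        else:
            posterior, motif, cons = float("nan"), float("nan"), float("nan")
        erows.append(
            {"factor": factor, "chrom": CHROM, "midpoint": int(p),
             "source": source, "posterior": posterior,
             "motif_score": round(motif, 4) if motif == motif else motif,
             "cons_score": round(cons, 4) if cons == cons else cons,
             "functional": bool(functional), "target": target}
        )

    link_by_gene = links.groupby("gene") if len(links) else None
    for _, e in net.bound_edges().iterrows():
        anchor = pos[e["target"]]
        n_ev = 1 + int(rng.poisson(cfg.extra_events_mean))
        for j in range(n_ev):
            if (
                e["functional"]
                and j > 0
                and rng.random() < cfg.distal_event_fraction
                and link_by_gene is not None
                and e["target"] in link_by_gene.groups
            ):
                els = link_by_gene.get_group(e["target"])
                el = els.iloc[int(rng.integers(len(els)))]
                p = int(rng.integers(el["start"], el["end"]))
            elif e["functional"]:
                cand = anchor + _base_offsets(rng, N_CANDIDATES)
                w = np.where(in_strong_enhancer(cand), cfg.enhancer_enrichment, 1.0)
                p = int(rng.choice(cand, p=w / w.sum()))
            else:
                p = int(anchor + _base_offsets(rng, 1)[0])
            add_event(e["tf"], e["target"], p, bool(e["functional"]))

    # background sub-threshold footprints (removed by the posterior filter)
    n_bg = int(round(0.15 * len(erows)))
    for _ in range(n_bg):
        g = genes[int(rng.integers(cfg.n_genes))]
        p = int(pos[g] + _base_offsets(rng, 1)[0])
        factor = net.tf_list[int(rng.integers(len(net.tf_list)))]
        erows.append(
            {"factor": factor, "chrom": CHROM, "midpoint": p, "source": "dnase",
             "posterior": float(rng.uniform(0.5, 0.95)),
             "motif_score": round(float(rng.normal(10.0, 2.0)), 4),
             "cons_score": round(float(np.clip(rng.normal(0.2, 0.1), 0, 1)), 4),
             "functional": False, "target": ""}
        )

    events = pd.DataFrame(
        erows,
        columns=["factor", "chrom", "midpoint", "source", "posterior",
                 "motif_score", "cons_score", "functional", "target"],
    )
    return GenomeLayout(
        chrom=CHROM, length=chrom_length(cfg), tss_candidates=tss,
        states=states, events=events, distal_links=links,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _design(cfg: SimConfig, rng) -> pd.DataFrame:
    """Array metadata: knockdown triplicates (round-robin batches, the first
    ``n_repeated`` knockdowns repeated in a second batch) plus per-batch
    control arrays."""
    genes = gene_ids(cfg)
    kd_tfs = genes[: cfg.n_knockdowns]
    rows = []
    for i, tf in enumerate(kd_tfs):
        batches = [i % cfg.n_batches]
        if i < cfg.n_repeated and cfg.n_batches > 1:
            batches.append((i + 1) % cfg.n_batches)
        for b in batches:
            for r in range(1, cfg.replicates_per_kd + 1):
                rows.append(
                    {"array_id": f"{tf}_b{b}_r{r}", "batch": b,
                     "condition": tf, "replicate": r}
                )
    for b in range(cfg.n_batches):
        for r in range(1, cfg.controls_per_batch + 1):
            rows.append(
                {"array_id": f"CTL_b{b}_r{r}", "batch": b,
                 "condition": CONTROL, "replicate": r}
            )
    return pd.DataFrame(rows).set_index("array_id")


def _probe_table(cfg: SimConfig, rng) -> pd.DataFrame:
    """Probe annotation: one clean 3'-rank-1 probe per gene, extra rank-2
    probes for some genes, and rare disqualifying flags on non-TF genes."""
    genes = gene_ids(cfg)
    rows = []
    counter = 0
    flags = ["maps_uniquely", "secondary_hit_1mm", "on_chrY", "het_snp_overlap"]
    for i, g in enumerate(genes):
        is_tf = i < cfg.n_tfs
        bad = (not is_tf) and rng.random() < cfg.bad_probe_fraction
        rec = {"probe_id": f"PR{counter:05d}", "gene_id": g,
               "maps_uniquely": True, "secondary_hit_1mm": False,
               "on_chrY": False, "het_snp_overlap": False, "three_prime_rank": 1}
        if bad:
            which = flags[int(rng.integers(4))]
            rec[which] = which != "maps_uniquely"
            if which == "maps_uniquely":
                rec[which] = False
        rows.append(rec)
        counter += 1
        if rng.random() < cfg.extra_probe_fraction:
            rec2 = {"probe_id": f"PR{counter:05d}", "gene_id": g,
                    "maps_uniquely": True, "secondary_hit_1mm": False,
                    "on_chrY": False, "het_snp_overlap": False,
                    "three_prime_rank": 2}
            if rng.random() < 0.3:
                rec2["secondary_hit_1mm"] = True
            rows.append(rec2)
            counter += 1
    return pd.DataFrame(rows)


def detection_pvalue(values: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Per-cell detection p: logistic, decreasing in log2 intensity."""
    return 1.0 / (1.0 + np.exp((values - cfg.detection_tau) / cfg.detection_s))


def planted_deltas(cfg: SimConfig, net: RegulatoryNetwork,
                   experiments: pd.DataFrame) -> pd.DataFrame:
    """Per-experiment planted log2 shifts (knockdown + one-step propagation)."""
    genes = gene_ids(cfg)
    gi = {g: i for i, g in enumerate(genes)}
    reg = net.regulated_edges()
    by_tf = dict(tuple(reg.groupby("tf"))) if len(reg) else {}
    mean_eff = float(np.mean(cfg.kd_efficiency_range))
    ref = math.log2(1.0 - mean_eff)  # log2 change of a typical knockdown
    out = {}
    for _, ex in experiments.iterrows():
        delta = np.zeros(len(genes))
        tf, kappa = ex["condition"], ex["kappa"]
        delta[gi[tf]] += math.log2(1.0 - kappa)
        direct = by_tf.get(tf)
        if direct is not None:
            for _, e in direct.iterrows():
                delta[gi[e["target"]]] += e["effect"]
            # one step further: direct targets that are themselves TFs pass an
            # attenuated, magnitude-scaled effect to their own targets.
            for _, e in direct.iterrows():
                t = e["target"]
                if t in by_tf and t != tf:
                    scale = cfg.indirect_attenuation * (delta[gi[t]] / ref)
                    for _, e2 in by_tf[t].iterrows():
                        delta[gi[e2["target"]]] += e2["effect"] * scale
        out[ex["experiment"]] = delta
    return pd.DataFrame(out, index=genes).T


def simulate_expression(cfg: SimConfig, net: RegulatoryNetwork):
    """Raw probe-level expression with planted effects and unwanted variation.

    Returns ``(ExpressionMatrix, probe_annotation, SimTruth)``. Observed
    log2 intensity = gene baseline + probe offset + planted knockdown delta
    + loadings . (k_true batch-correlated factors) + N(0, noise_sd).
    """
    cfg.validate()
    rng = cfg.rng(2)
    genes = gene_ids(cfg)
    arrays = _design(cfg, rng)
    probes = _probe_table(cfg, rng)

    exps = []
    kd_meta = arrays[arrays["condition"] != CONTROL]
    for (cond, b), _ in kd_meta.groupby(["condition", "batch"], sort=True):
        exps.append({"experiment": f"{cond}_b{b}", "condition": cond, "batch": b,
                     "kappa": float(rng.uniform(*cfg.kd_efficiency_range))})
    experiments = pd.DataFrame(exps)

    deltas = planted_deltas(cfg, net, experiments)

    n_arr = len(arrays)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    # factors chosen for knockdown are robustly expressed in the cell line:
    # keep TF baselines comfortably above the detection threshold so the
    # targeted transcript is always measurable on the control arrays.
    tf_floor = cfg.baseline_mean - 0.5
    baseline[: cfg.n_tfs] = np.maximum(
        rng.normal(cfg.baseline_mean + 0.8, 1.0, size=cfg.n_tfs), tf_floor
    )
    gene_mat = np.tile(baseline[:, None], (1, n_arr))
    exp_key = {(r["condition"], r["batch"]): r["experiment"]
               for _, r in experiments.iterrows()}
    for j, (aid, meta) in enumerate(arrays.iterrows()):
        if meta["condition"] != CONTROL:
            gene_mat[:, j] += deltas.loc[exp_key[(meta["condition"], meta["batch"])]].to_numpy()

    # unwanted variation: batch means + array jitter, Gaussian gene loadings
    scores = np.zeros((n_arr, cfg.k_true))
    if cfg.k_true > 0:
        batch_means = rng.normal(0.0, cfg.batch_factor_sd,
                                 size=(cfg.n_batches, cfg.k_true))
        jitter = rng.normal(0.0, cfg.array_jitter_sd, size=(n_arr, cfg.k_true))
        scores = batch_means[arrays["batch"].to_numpy()] + jitter
        loadings = rng.normal(0.0, cfg.loading_sd, size=(len(genes), cfg.k_true))
        gene_mat = gene_mat + loadings @ scores.T

    # probe-level matrix
    gi = {g: i for i, g in enumerate(genes)}
    rows = probes["gene_id"].map(gi).to_numpy()
    offsets = rng.normal(0.0, 0.5, size=len(probes))
    # keep TF probes measurable: a strongly negative probe offset would push
    # the targeted transcript below the detection threshold on the arrays.
    offsets = np.where(rows < cfg.n_tfs, np.maximum(offsets, -0.3), offsets)
    values = gene_mat[rows] + offsets[:, None]
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)

    vdf = pd.DataFrame(values, index=probes["probe_id"].to_numpy(),
                       columns=arrays.index)
    ddf = pd.DataFrame(detection_pvalue(values, cfg),
                       index=vdf.index, columns=vdf.columns)
    mat = ExpressionMatrix(values=vdf, detection_p=ddf, arrays=arrays.copy())

    truth = SimTruth(
        experiments=experiments,
        edges=net.edges.copy(),
        events=pd.DataFrame(),  # filled by the caller once annotation exists
        factor_scores=pd.DataFrame(scores, index=arrays.index,
                                   columns=[f"F{c}" for c in range(cfg.k_true)]),
        direct_effects=deltas,
    )
    return mat, probes, truth


def simulate_study(cfg: SimConfig):
    """Convenience wrapper: network + annotation + expression, truth linked."""
    net = generate_network(cfg)
    layout = generate_annotation(cfg, net)
    mat, probes, truth = simulate_expression(cfg, net)
    truth.events = layout.events[["factor", "chrom", "midpoint",
                                  "functional", "target"]].copy()
    return net, layout, mat, probes, truth


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

FIXTURE_FILES = [
    "expression.tsv", "detection_p.tsv", "arrays.tsv", "probes.tsv",
    "binding.tsv", "tss_candidates.tsv", "chromatin_states.bed",
    "distal_links.tsv", "truth_experiments.tsv", "truth_edges.tsv",
    "truth_events.tsv", "config.yaml",
]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixtures(cfg: SimConfig, layout: GenomeLayout, mat: ExpressionMatrix,
                   probes: pd.DataFrame, truth: SimTruth, outdir: str) -> dict:
    """Write all study files as TSV/BED/YAML and return a checksum manifest."""
    os.makedirs(outdir, exist_ok=True)
    if not os.access(outdir, os.W_OK):
        raise IOError(f"output directory not writable: {outdir}")
    p = lambda name: os.path.join(outdir, name)

    mat.values.rename_axis("probe_id").to_csv(p("expression.tsv"), sep="\t")
    mat.detection_p.rename_axis("probe_id").to_csv(p("detection_p.tsv"), sep="\t")
    mat.arrays.rename_axis("array_id").to_csv(p("arrays.tsv"), sep="\t")
    probes.to_csv(p("probes.tsv"), sep="\t", index=False)

    ev = layout.events
    bed = pd.DataFrame(
        {"chrom": ev["chrom"], "start": ev["midpoint"],
         "end": ev["midpoint"] + 1, "factor": ev["factor"],
         "posterior": ev["posterior"], "motif_score": ev["motif_score"],
         "cons_score": ev["cons_score"], "source": ev["source"]}
    )
    bed.to_csv(p("binding.tsv"), sep="\t", index=False)
    layout.tss_candidates.to_csv(p("tss_candidates.tsv"), sep="\t", index=False)
    layout.states.to_csv(p("chromatin_states.bed"), sep="\t",
                         index=False, header=False)
    layout.distal_links.to_csv(p("distal_links.tsv"), sep="\t", index=False)

    truth.experiments.to_csv(p("truth_experiments.tsv"), sep="\t", index=False)
    truth.edges.to_csv(p("truth_edges.tsv"), sep="\t", index=False)
    truth.events.to_csv(p("truth_events.tsv"), sep="\t", index=False)
    cfg.to_yaml(p("config.yaml"))

    manifest = {
        "files": {
            name: {"sha256": _sha256(p(name)),
                   "bytes": os.path.getsize(p(name))}
            for name in FIXTURE_FILES
        },
        "n_probes": int(len(mat.values)),
        "n_arrays": int(len(mat.arrays)),
        "n_events": int(len(layout.events)),
        "seed": int(cfg.seed),
    }
    with open(p("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_fixtures(datadir: str):
    """Load a fixture directory back into memory.

    Returns ``(cfg, matrix, probes, binding, tss, states, links, truth)``
    where ``truth`` is a dict of the truth tables (may be empty when
    analyzing non-synthetic data without truth files).
    """
    p = lambda name: os.path.join(datadir, name)
    for required in ["expression.tsv", "detection_p.tsv", "arrays.tsv",
                     "probes.tsv", "binding.tsv", "tss_candidates.tsv",
                     "chromatin_states.bed"]:
        if not os.path.exists(p(required)):
            raise FileNotFoundError(f"missing fixture file: {p(required)}")
    cfg = SimConfig.from_yaml(p("config.yaml")) if os.path.exists(p("config.yaml")) \
        else SimConfig()
    values = pd.read_csv(p("expression.tsv"), sep="\t", index_col=0)
    det = pd.read_csv(p("detection_p.tsv"), sep="\t", index_col=0)
    arrays = pd.read_csv(p("arrays.tsv"), sep="\t", index_col=0)
    mat = ExpressionMatrix(values=values, detection_p=det, arrays=arrays)
    probes = pd.read_csv(p("probes.tsv"), sep="\t")
    binding = pd.read_csv(p("binding.tsv"), sep="\t")
    tss = pd.read_csv(p("tss_candidates.tsv"), sep="\t")
    states = pd.read_csv(p("chromatin_states.bed"), sep="\t", header=None,
                         names=["chrom", "start", "end", "state"])
    links_path = p("distal_links.tsv")
    links = pd.read_csv(links_path, sep="\t") if os.path.exists(links_path) \
        else pd.DataFrame(columns=["chrom", "start", "end", "gene", "score"])
    truth = {}
    for name in ["truth_experiments", "truth_edges", "truth_events"]:
        if os.path.exists(p(f"{name}.tsv")):
            truth[name.replace("truth_", "")] = pd.read_csv(p(f"{name}.tsv"), sep="\t")
    return cfg, mat, probes, binding, tss, states, links, truth
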