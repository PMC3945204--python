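"""Normalization, control-probe selection, RUV, and the k diagnostic."""

import numpy as np
import pandas as pd
import pytest

from funcbind import preprocess as pre
from funcbind.matrix import ExpressionMatrix
from funcbind.synthdata import simulate_study
from conftest import small_config

ORTHO_TOL = 1e-8


# ---------------------------------------------------------------------------
# probe filtering
# ---------------------------------------------------------------------------

def _probe(pid, gene, uniq=True, mm1=False, chry=False, snp=False, rank=1):
    return {"probe_id": pid, "gene_id": gene, "maps_uniquely": uniq,
            "secondary_hit_1mm": mm1, "on_chrY": chry,
            "het_snp_overlap": snp, "three_prime_rank": rank}


def test_filter_probes_hand_walk():
    """Six probes exercising every disqualifying flag: exactly two genes
    survive, each represented by its 3'-most clean probe."""
    ann = pd.DataFrame([
        _probe("p1", "gA", rank=2),                  # kept (gA, only clean)
        _probe("p2", "gA", snp=True, rank=1),        # SNP overlap -> out
        _probe("p3", "gB", uniq=False),              # multi-mapping -> out
        _probe("p4", "gB", chry=True),               # chrY -> out
        _probe("p5", "gC", rank=2),                  # clean but rank 2
        _probe("p6", "gC", rank=1),                  # kept (3'-most)
    ])
    kept = pre.filter_probes(ann)
    assert dict(zip(kept["gene_id"], kept["probe_id"])) == {"gA": "p1", "gC": "p6"}


def test_filter_probes_one_mismatch_hit_excluded():
    ann = pd.DataFrame([_probe("p1", "g", mm1=True)])
    assert len(pre.filter_probes(ann)) == 0


# ---------------------------------------------------------------------------
# detection filter
# ---------------------------------------------------------------------------

def _matrix(det: np.ndarray, kd_cols, ctl_cols):
    cols = kd_cols + ctl_cols
    genes = [f"g{i}" for i in range(det.shape[0])]
    values = pd.DataFrame(np.zeros_like(det, dtype=float), index=genes, columns=cols)
    detp = pd.DataFrame(det, index=genes, columns=cols)
    meta = pd.DataFrame(
        {"batch": 0,
         "condition": ["KD"] * len(kd_cols) + ["CONTROL"] * len(ctl_cols),
         "replicate": 1},
        index=cols)
    return ExpressionMatrix(values, detp, meta)


def test_detection_filter_brute_force():
    """5 genes x 9 arrays: the retained set equals an exhaustive evaluation
    of 'all knockdown replicates OR all controls below threshold'."""
    rng = np.random.default_rng(4)
    det = rng.choice([0.001, 0.005, 0.02, 0.5], size=(5, 9))
    kd_cols = [f"k{i}" for i in range(3)]
    ctl_cols = [f"c{i}" for i in range(6)]
    mat = _matrix(det, kd_cols, ctl_cols)
    got = set(pre.detection_filter(mat, kd_cols, ctl_cols, 0.01))
    expect = {
        f"g{i}" for i in range(5)
        if (det[i, :3] < 0.01).all() or (det[i, 3:] < 0.01).all()
    }
    assert got == expect


def test_detection_filter_disjuncts():
    det = np.array([[0.005, 0.005, 0.005, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
                    [0.02, 0.001, 0.001, 0.02, 0.001, 0.001, 0.001, 0.001, 0.001]])
    kd = [f"k{i}" for i in range(3)]
    ctl = [f"c{i}" for i in range(6)]
    mat = _matrix(det, kd, ctl)
    got = pre.detection_filter(mat, kd, ctl, 0.01)
    assert got == ["g0"]  # g1 fails both disjuncts (one bad array in each)


def test_detection_filter_unknown_array():
    mat = _matrix(np.zeros((2, 9)), [f"k{i}" for i in range(3)],
                  [f"c{i}" for i in range(6)])
    with pytest.raises(KeyError):
        pre.detection_filter(mat, ["nope"], mat.control_arrays())


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def test_quantile_normalize_rank_means_by_hand():
    values = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
    out = pre.quantile_normalize(values)
    assert out["a"].tolist() == [1.5, 3.5]
    assert out["b"].tolist() == [1.5, 3.5]


def test_quantile_normalize_tie_rule_by_hand():
    values = pd.DataFrame({"a": [5.0, 5.0], "b": [2.0, 4.0]})
    out = pre.quantile_normalize(values)
    # reference is [3.5, 4.5]; the tied entries share the spanned mean 4.0
    assert out["a"].tolist() == [4.0, 4.0]
    assert out["b"].tolist() == [3.5, 4.5]


def test_quantile_normalize_fixed_point_and_idempotence(rng):
    same = pd.DataFrame(np.tile(rng.normal(size=(40, 1)), (1, 5)))
    pd.testing.assert_frame_equal(pre.quantile_normalize(same), same,
                                  check_exact=False, atol=1e-12)
    X = pd.DataFrame(rng.normal(size=(60, 6)))
    once = pre.quantile_normalize(X)
    twice = pre.quantile_normalize(once)
    pd.testing.assert_frame_equal(once, twice, atol=1e-12)
    # column distribution equality
    ref = np.sort(once.iloc[:, 0].to_numpy())
    for j in range(once.shape[1]):
        np.testing.assert_allclose(np.sort(once.iloc[:, j]), ref, atol=1e-12)


def test_quantile_normalize_single_column_unchanged(rng):
    X = pd.DataFrame(rng.normal(size=(10, 1)))
    pd.testing.assert_frame_equal(pre.quantile_normalize(X), X)


# ---------------------------------------------------------------------------
# control probes
# ---------------------------------------------------------------------------

def test_select_control_probes_hand_ranking():
    """Three 2-array batches over 5 probes with hand-set variances."""
    cols = [f"b{b}r{r}" for b in range(3) for r in range(2)]
    base = np.zeros((5, 6))
    spread = {0: [0.0, 1.0, 2.0, 3.0, 4.0],
              1: [4.0, 0.0, 1.0, 2.0, 3.0],
              2: [0.0, 1.0, 4.0, 2.0, 3.0]}
    for b in range(3):
        for i in range(5):
            base[i, 2 * b] = -spread[b][i]
            base[i, 2 * b + 1] = spread[b][i]
    values = pd.DataFrame(base, index=[f"g{i}" for i in range(5)], columns=cols)
    batches = pd.Series([b for b in range(3) for _ in range(2)], index=cols)
    got = pre.select_control_probes(values, batches, n_per_batch=3)
    # per-batch 3 least variable: {g0,g1,g2}, {g1,g2,g3}, {g0,g1,g3} -> {g1}
    assert got.intersection == ["g1"]


def test_select_control_probes_empty_intersection_warns():
    cols = ["b0r0", "b0r1", "b1r0", "b1r1"]
    values = pd.DataFrame(
        [[0, 0, -9, 9], [-9, 9, 0, 0]], index=["g0", "g1"], columns=cols,
        dtype=float)
    batches = pd.Series([0, 0, 1, 1], index=cols)
    with pytest.warns(UserWarning, match="empty"):
        got = pre.select_control_probes(values, batches, n_per_batch=1)
    assert got.intersection == []


def test_control_set_depleted_of_regulated_targets():
    """On synthetic data the least-variable intersection avoids strongly
    regulated knockdown targets far beyond chance (hypergeometric)."""
    from scipy.stats import hypergeom

    pvals = []
    for seed in range(3):
        cfg = small_config(seed=900 + seed, n_control_probes=250)
        net, layout, mat, probes, truth = simulate_study(cfg)
        retained = pre.filter_probes(probes)
        g = pre.probes_to_genes(mat, retained)
        qn = g.with_values(pre.quantile_normalize(g.values))
        exps = qn.experiments()
        ctl = qn.control_arrays()
        expressed = sorted(set().union(*[
            pre.detection_filter(qn, r["arrays"], ctl, 0.01)
            for _, r in exps.iterrows()]))
        cps = pre.select_control_probes(qn.values, qn.arrays["batch"],
                                        cfg.n_control_probes,
                                        candidates=expressed)
        kd_tfs = set(net.tf_list[: cfg.n_knockdowns])
        reg = net.regulated_edges()
        strong = reg[(reg["tf"].isin(kd_tfs))
                     & (np.abs(2.0 ** np.abs(reg["effect"]) - 1) > 0.2)]
        targets = set(strong["target"]) & set(expressed)
        hits = len(set(cps.intersection) & targets)
        N, K, n = len(expressed), len(targets), len(cps.intersection)
        pvals.append(hypergeom.cdf(hits, N, K, n))
    assert all(p < 0.01 for p in pvals)


# ---------------------------------------------------------------------------
# RUV
# ---------------------------------------------------------------------------

def _planted_factor_study(rng, n_genes=300, n_arrays=30, sigma=0.0):
    scores = np.repeat(rng.normal(0, 1, size=3), n_arrays // 3)
    load = rng.normal(0, 0.5, size=n_genes)
    base = rng.normal(8, 1, size=n_genes)
    Y = base[:, None] + np.outer(load, scores)
    if sigma:
        Y = Y + rng.normal(0, sigma, size=Y.shape)
    cols = [f"a{j}" for j in range(n_arrays)]
    values = pd.DataFrame(Y, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    return values, scores


def test_fit_ruv_k0_identity(rng):
    values, _ = _planted_factor_study(rng)
    f = pre.fit_ruv(values, ["g0", "g1", "g2"], 0)
    assert f.k == 0 and f.W.shape == (values.shape[1], 0)
    pd.testing.assert_frame_equal(pre.apply_ruv(values, f), values)


def test_fit_ruv_orthonormal_scores(rng):
    values, _ = _planted_factor_study(rng, sigma=0.2)
    f = pre.fit_ruv(values, [f"g{i}" for i in range(50)], 4)
    W = f.W.to_numpy()
    np.testing.assert_allclose(W.T @ W, np.eye(4), atol=1e-10)


def test_fit_ruv_recovers_planted_factor(rng):
    values, scores = _planted_factor_study(rng, sigma=0.0)
    f = pre.fit_ruv(values, [f"g{i}" for i in range(100)], 1)
    r = np.corrcoef(f.W.iloc[:, 0], scores)[0, 1]
    assert abs(r) > 0.999


def test_fit_ruv_k_beyond_rank_raises(rng):
    values, _ = _planted_factor_study(rng, sigma=0.0)  # rank-2 (mean+factor)
    with pytest.raises(ValueError):
        pre.fit_ruv(values, [f"g{i}" for i in range(20)], 10)


def test_apply_ruv_residual_orthogonality_and_means(rng):
    values, _ = _planted_factor_study(rng, sigma=0.3)
    f = pre.fit_ruv(values, [f"g{i}" for i in range(80)], 2)
    adj = pre.apply_ruv(values, f)
    resid = adj.to_numpy() - adj.to_numpy().mean(axis=1, keepdims=True)
    assert np.abs(resid @ f.W.to_numpy()).max() < ORTHO_TOL
    np.testing.assert_allclose(adj.mean(axis=1), values.mean(axis=1), atol=1e-10)


def test_apply_ruv_removes_planted_batch_difference(rng):
    values, scores = _planted_factor_study(rng, sigma=0.0)
    controls = [f"g{i}" for i in range(100)]
    f = pre.fit_ruv(values, controls, 1)
    adj = pre.apply_ruv(values, f)
    b0 = values.columns[:10]
    b1 = values.columns[10:20]
    before = (values[b0].mean(1) - values[b1].mean(1)).abs().mean()
    after = (adj[b0].mean(1) - adj[b1].mean(1)).abs().mean()
    assert after < 0.05 * before


def test_apply_ruv_array_mismatch_raises(rng):
    values, _ = _planted_factor_study(rng)
    f = pre.fit_ruv(values, ["g0", "g1", "g2", "g3"], 1)
    with pytest.raises(ValueError):
        pre.apply_ruv(values.iloc[:, :-1], f)


# ---------------------------------------------------------------------------
# choosing k
# ---------------------------------------------------------------------------

def test_choose_k_null_data_selects_zero():
    """No batch structure at all: k=0 already satisfies the control
    criterion and the concordance criterion is flat."""
    cfg = small_config(seed=77, k_true=0)
    net, layout, mat, probes, truth = simulate_study(cfg)
    retained = pre.filter_probes(probes)
    g = pre.probes_to_genes(mat, retained)
    qn = g.with_values(pre.quantile_normalize(g.values))
    exps = qn.experiments()
    ctl = qn.control_arrays()
    expressed = sorted(set().union(*[
        pre.detection_filter(qn, r["arrays"], ctl, 0.01)
        for _, r in exps.iterrows()]))
    cps = pre.select_control_probes(qn.values, qn.arrays["batch"],
                                    cfg.n_control_probes,
                                    candidates=expressed)
    k, tab = pre.choose_k(qn.subset_rows(expressed), cps, range(0, 4),
                          exclude_genes=set(exps["condition"]))
    assert k == 0
    assert tab.loc[tab["k"] == 0, "control_de"].iloc[0] == 0


def test_choose_k_recovers_planted_factor_count():
    """Moderate Monte-Carlo version of the k recovery property: selection
    within k_true +/- 1 in most seeds."""
    hits = 0
    for seed in range(8):
        cfg = small_config(seed=150 + seed, n_genes=800, n_control_probes=200)
        net, layout, mat, probes, truth = simulate_study(cfg)
        retained = pre.filter_probes(probes)
        g = pre.probes_to_genes(mat, retained)
        qn = g.with_values(pre.quantile_normalize(g.values))
        exps = qn.experiments()
        ctl = qn.control_arrays()
        expressed = sorted(set().union(*[
            pre.detection_filter(qn, r["arrays"], ctl, 0.01)
            for _, r in exps.iterrows()]))
        cps = pre.select_control_probes(qn.values, qn.arrays["batch"],
                                        cfg.n_control_probes,
                                        candidates=expressed)
        k, tab = pre.choose_k(qn.subset_rows(expressed), cps, range(0, 7),
                              exclude_genes=set(exps["condition"]))
        hits += abs(k - cfg.k_true) <= 1
        # control-group DE declines broadly as factors are removed
        a = tab["control_de"].to_numpy()
        assert a[cfg.k_true:].max() <= max(3, 0.01 * a[0])
        # concordance at the selected k is no worse than unadjusted
        cor = tab.set_index("k")["replicate_logp_cor"]
        assert cor[k] >= cor[0] - 0.01
    assert hits >= 6


def test_choose_k_empty_grid_raises(small_study):
    net, layout, mat, probes, truth = small_study
    with pytest.raises(ValueError):
        pre.choose_k(mat, ["x"], [])


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_rle_stats_constant_and_shift(rng):
    const = pd.DataFrame(np.full((10, 4), 3.0))
    out = pre.rle_stats(const)
    assert (out["median"] == 0).all() and (out["iqr"] == 0).all()

    X = pd.DataFrame(rng.normal(size=(50, 5)))
    X.iloc[:, 2] += 1.0
    out = pre.rle_stats(X)
    assert out["median"].iloc[2] == pytest.approx(1.0, abs=0.15)

    # brute-force recomputation
    Y = pd.DataFrame(rng.normal(size=(10, 6)))
    out = pre.rle_stats(Y)
    dev = Y.to_numpy() - np.median(Y.to_numpy(), axis=1, keepdims=True)
    np.testing.assert_allclose(out["median"], np.median(dev, axis=0))
    np.testing.assert_allclose(
        out["iqr"],
        np.percentile(dev, 75, axis=0) - np.percentile(dev, 25, axis=0))


def test_pca_diagnostics_batch_association(rng):
    values, scores = _planted_factor_study(rng, sigma=0.2)
    meta = pd.DataFrame({"batch": np.repeat([0, 1, 2], 10)},
                        index=values.columns)
    d = pre.pca_diagnostics(values, meta)
    assert d["variance_fraction"].sum() == pytest.approx(1.0)
    assert d["batch_assoc_p"].iloc[0] < 0.01
    # after removing the factor the association disappears
    f = pre.fit_ruv(values, [f"g{i}" for i in range(100)], 1)
    adj = pre.apply_ruv(values, f)
    d2 = pre.pca_diagnostics(adj, meta)
    assert d2["batch_assoc_p"].iloc[0] > 0.01


def test_pca_requires_three_arrays(rng):
    values = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
    meta = pd.DataFrame({"batch": [0, 1]}, index=["a", "b"])
    with pytest.raises(ValueError):
        pre.pca_diagnostics(values, meta)


# ---------------------------------------------------------------------------
# control pooling
# ---------------------------------------------------------------------------

def test_pool_controls_averages_matched_replicates(small_study):
    mat = small_study[2]
    pooled = pre.pool_controls(mat)
    ctl = pooled.control_arrays()
    assert len(ctl) == 6
    r1 = [a for a in mat.control_arrays() if mat.arrays.loc[a, "replicate"] == 1]
    np.testing.assert_allclose(pooled.values["CTL_pool_r1"],
                               mat.values[r1].mean(axis=1))
    # knockdown arrays untouched
    kd = [a for a in mat.array_ids if a not in set(mat.control_arrays())]
    pd.testing.assert_frame_equal(pooled.values[kd], mat.values[kd])
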