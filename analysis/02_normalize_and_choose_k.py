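"""Normalization and removal of unwanted variation.

Reads the fixture directory, filters probes, quantile-normalizes all
arrays together, selects the least-variable control probes per batch, runs
the replicate-concordance diagnostic for the number of removed factors,
and writes the adjusted matrix (scratch) plus QC tables (results).

    python analysis/02_normalize_and_choose_k.py [--data scratch/study]
"""

import argparse
import os

from funcbind import preprocess as pre
from funcbind.synthdata import read_fixtures


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="scratch/study")
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    cfg, mat, probes, *_ = read_fixtures(args.data)
    gmat = pre.probes_to_genes(mat, pre.filter_probes(probes))
    gmat = gmat.with_values(pre.quantile_normalize(gmat.values))

    exps = gmat.experiments()
    ctl = gmat.control_arrays()
    expressed = sorted(set().union(*[
        pre.detection_filter(gmat, r["arrays"], ctl, cfg.detection_p)
        for _, r in exps.iterrows()]))
    controls = pre.select_control_probes(gmat.values, gmat.arrays["batch"],
                                         cfg.n_control_probes,
                                         candidates=expressed)
    k, ktab = pre.choose_k(gmat.subset_rows(expressed), controls,
                           range(cfg.k_grid_max + 1),
                           exclude_genes=set(exps["condition"]))
    factors = pre.fit_ruv(gmat.values, controls, k)
    adj = pre.adjust_matrix(gmat, factors)

    adj.values.to_csv(os.path.join("scratch", "adjusted_expression.tsv"),
                      sep="\t")
    ktab.to_csv(os.path.join(args.out, "k_table.tsv"), sep="\t", index=False)
    pre.rle_stats(adj.values).to_csv(os.path.join(args.out, "qc_rle.tsv"),
                                     sep="\t")
    pb = pre.pca_diagnostics(gmat.values, gmat.arrays)["batch_assoc_p"]
    pa = pre.pca_diagnostics(adj.values, adj.arrays)["batch_assoc_p"]

    print(f"{gmat.values.shape[0]} genes x {gmat.values.shape[1]} arrays; "
          f"{len(expressed)} pass the detection filter in >=1 experiment")
    print(f"control probes: {len(controls.intersection)} in the "
          f"cross-batch intersection of {controls.n_per_batch}-probe lists")
    print(f"selected k = {k} "
          f"(control-group DE zero, replicate concordance maximal)")
    print("PC1 batch-association p: "
          f"{pb.iloc[0]:.2e} before adjustment, {pa.iloc[0]:.2f} after")


if __name__ == "__main__":
    main()
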