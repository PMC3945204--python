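"""Per-knockdown differential expression and array-based efficiencies.

Runs the pipeline on the fixture directory and reports the DE facet:
number of expressed and differentially expressed genes per experiment,
effect sizes, and knockdown efficiencies recovered from the arrays
(compared against the planted truth when truth tables are present).

    python analysis/03_differential_expression.py [--data scratch/study]
"""

import argparse
import os

import numpy as np
import pandas as pd

from funcbind.pipeline import run_analysis
from funcbind.synthdata import read_fixtures


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="scratch/study")
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    res = run_analysis(args.data, run_qc=False)
    eff = res.efficiencies.copy()

    *_, truth = read_fixtures(args.data)
    if "experiments" in truth:
        kap = truth["experiments"].set_index("experiment")["kappa"]
        eff["planted_efficiency_pct"] = 100 * eff["experiment"].map(kap)
        eff["error_pp"] = eff["efficiency_pct"] - eff["planted_efficiency_pct"]
    eff.to_csv(os.path.join(args.out, "efficiencies.tsv"), sep="\t",
               index=False)
    de_dir = os.path.join(args.out, "de_tables")
    os.makedirs(de_dir, exist_ok=True)
    for exp, tab in res.de_tables.items():
        tab.rename_axis("gene").to_csv(os.path.join(de_dir, f"de_{exp}.tsv"),
                                       sep="\t")

    effects = np.concatenate([
        t.loc[t["q"] <= res.cfg.fdr, "effect_pct"].to_numpy()
        for t in res.de_tables.values()])
    print(f"{len(res.de_tables)} experiments "
          f"(k = {res.k_selected} factors removed)")
    print(f"expressed genes per experiment: "
          f"{eff['n_expressed'].min()}-{eff['n_expressed'].max()}")
    print(f"DE genes at FDR {res.cfg.fdr:.0%}: "
          f"{eff['n_de'].min()}-{eff['n_de'].max()} "
          f"(median {eff['n_de'].median():.0f})")
    print(f"median effect size among DE genes: "
          f"{np.median(effects):.1f}% ({len(effects)} gene calls)")
    print(f"array-based knockdown efficiency: "
          f"{eff['efficiency_pct'].min():.0f}-{eff['efficiency_pct'].max():.0f}%")
    if "error_pp" in eff:
        print(f"median |efficiency error| vs planted truth: "
              f"{eff['error_pp'].abs().median():.1f} percentage points")


if __name__ == "__main__":
    main()
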