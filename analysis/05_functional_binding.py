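"""Functional binding: overlap of binding and differential expression.

Runs the full pipeline and reports the integration facet: how much direct
binding is functional, overlap significance and relative enrichment,
chromatin-state enrichment of functional binding, site-feature shifts,
co-occupancy, and direction of effect.

    python analysis/05_functional_binding.py [--data scratch/study]
"""

import argparse
import os

from funcbind.pipeline import run_analysis, write_results
from funcbind.synthdata import STRONG_ENHANCER


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="scratch/study")
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()

    res = run_analysis(args.data, run_qc=False)
    write_results(res, args.out)

    direct = res.overlap[res.overlap["mode"] == "direct"]
    print(f"{len(direct)} experiments with direct binding maps")
    print(f"fraction of bound genes that are DE: "
          f"median {100 * direct['frac_bound_de'].median():.1f}% "
          f"(i.e. {100 * (1 - direct['frac_bound_de'].median()):.1f}% of "
          f"direct binding is non-functional)")
    print(f"fraction of DE genes that are bound: "
          f"median {100 * direct['frac_de_bound'].median():.1f}%")
    print(f"overlap significant (Fisher p<0.05) in "
          f"{(direct['fisher_p'] < 0.05).sum()}/{len(direct)} experiments; "
          f"mean relative enrichment {direct['rel_enrichment'].mean():.2f}")

    sp = res.state_enrichment_pooled.set_index("state")
    if STRONG_ENHANCER in sp.index:
        row = sp.loc[STRONG_ENHANCER]
        print(f"strong-enhancer binding near DE genes (pooled): "
              f"OR {row['odds_ratio']:.2f}, BH-adjusted p {row['p_adj']:.2g}")
    feats = res.site_features.groupby("feature")["p"].median()
    print("median per-experiment rank-sum p by site feature: "
          + ", ".join(f"{f} {p:.2f}" for f, p in feats.items()))

    d = res.direction.dropna(subset=["frac_up_de"])
    print(f"direction of effect: mean {100 * d['frac_up_de'].mean():.1f}% of "
          f"DE genes up-regulated after knockdown; majority-up in "
          f"{(d['frac_up_de'] > 0.5).sum()}/{len(d)} experiments")
    if len(res.cooccupancy_bins):
        med = res.cooccupancy_bins.sort_values("bin")["median_enrichment"]
        print("co-occupancy enrichment by shared-DE-factor bin: "
              + " -> ".join(f"{v:.2f}" for v in med))


if __name__ == "__main__":
    main()
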