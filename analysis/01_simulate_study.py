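"""Generate the synthetic knockdown study used by the downstream drivers.

Writes the full fixture set (expression + detection p-values, array
metadata, probe annotation, binding events, TSS candidates, chromatin
states, distal links, truth tables) to scratch/study/.

    python analysis/01_simulate_study.py [--seed 1] [--out scratch/study]
"""

import argparse

from funcbind.config import SimConfig
from funcbind.synthdata import simulate_study, write_fixtures


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="scratch/study")
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed)
    net, layout, mat, probes, truth = simulate_study(cfg)
    manifest = write_fixtures(cfg, layout, mat, probes, truth, args.out)

    func = net.functional_edges()
    print(f"simulated study (seed {cfg.seed}) -> {args.out}")
    print(f"  genes: {cfg.n_genes}, TFs: {cfg.n_tfs}, "
          f"knockdown experiments: {len(truth.experiments)} "
          f"({cfg.n_repeated} repeated across batches)")
    print(f"  arrays: {manifest['n_arrays']} "
          f"({cfg.n_batches} batches x {cfg.controls_per_batch} controls)")
    print(f"  binding events: {manifest['n_events']} "
          f"({int(net.edges['bound'].sum())} bound edges, "
          f"{len(func)} functional)")
    print(f"  planted knockdown efficiencies: "
          f"{truth.experiments['kappa'].min():.2f}-"
          f"{truth.experiments['kappa'].max():.2f}")


if __name__ == "__main__":
    main()
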