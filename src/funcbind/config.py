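"""Configuration for the synthetic study and the analysis pipeline.

A single :class:`SimConfig` drives every generator; all randomness derives
from ``seed`` via per-stage substreams (``numpy.random.default_rng([seed, stage])``),
so the whole study is a pure function of the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraints."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated knockdown study.

    Defaults emulate the statistical structure of a three-batch siRNA
    knockdown screen read out on expression arrays: triplicate knockdowns
    compared against per-batch control arrays, knockdown efficiencies of
    50-90%, modest (~10% median) expression effects on true targets, and
    batch-correlated unwanted variation that a control-gene factor
    adjustment can remove.
    """

    # --- study design -----------------------------------------------------
    n_genes: int = 4000
    n_tfs: int = 30
    n_knockdowns: int = 12
    n_batches: int = 3
    replicates_per_kd: int = 3
    controls_per_batch: int = 6
    #: number of knockdowns repeated in a second batch (replicate experiments
    #: used by the factor-number diagnostic).
    n_repeated: int = 2

    # --- knockdown / network ---------------------------------------------
    kd_efficiency_range: Tuple[float, float] = (0.5, 0.9)
    #: target of the median |fold change - 1| among true regulatory targets,
    #: in percent.
    median_effect_pct: float = 10.0
    #: fraction of bound genes per factor that are true regulatory targets;
    #: the remainder are decoy (non-functional) binding.
    functional_fraction: float = 0.2
    mean_out_degree: float = 150.0
    #: mean number of regulated-but-unbound targets per knocked factor
    #: (indirect regulation): most genes that respond to a knockdown are not
    #: bound by the factor near their TSS, and these keep differential
    #: expression informative even when functional_fraction is 0.
    mean_unbound_targets: float = 45.0
    #: TFs are grouped into co-regulating modules of this size which share a
    #: pool of targets (drives co-occupancy structure). 1 disables modules.
    tf_module_size: int = 4
    #: fraction of a TF's targets drawn from its module's shared pool.
    module_target_overlap: float = 0.5
    #: probability that a same-module TF is itself a regulated target of a
    #: knocked factor (plants co-regulated TF modules).
    module_tf_coupling: float = 0.6
    #: probability a true-target effect is positive (up-regulation on knockdown).
    up_fraction: float = 0.5
    #: scale applied to one-step downstream propagation through TF targets.
    indirect_attenuation: float = 0.5

    # --- unwanted variation & noise ---------------------------------------
    k_true: int = 3
    batch_factor_sd: float = 1.0
    #: small relative to noise_sd: the jitter component is full-rank and is
    #: not removable by a low-rank factor adjustment, so it must stay minor
    #: for the planted structure to be removable as designed.
    array_jitter_sd: float = 0.1
    loading_sd: float = 0.3
    #: residual per-cell log2 noise after normalization; typical replicate
    #: noise for bead arrays, and small enough that >=30% expression shifts
    #: are detectable from a triplicate at study-wide FDR 5%.
    noise_sd: float = 0.10
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5

    # --- genome / binding layout ------------------------------------------
    gene_spacing: int = 100_000
    enhancer_enrichment: float = 5.0
    motif_shift: float = 0.5
    cons_shift: float = 0.0
    #: mean number of extra binding events per edge beyond the guaranteed one.
    extra_events_mean: float = 0.7
    #: fraction of extra functional events placed inside a distal element of
    #: the target instead of the TSS-proximal window.
    distal_event_fraction: float = 0.15

    # --- detection p-value curve ------------------------------------------
    #: logistic midpoint/steepness; with the default baseline distribution
    #: ~85-95% of genes pass the detection filter in each experiment.
    detection_tau: float = 4.8
    detection_s: float = 0.25

    # --- probe annotation --------------------------------------------------
    #: fraction of genes given a second (3'-rank-2) probe.
    extra_probe_fraction: float = 0.10
    #: fraction of non-TF genes whose only probe carries a disqualifying flag.
    bad_probe_fraction: float = 0.02

    seed: int = 0

    # --- analysis defaults (consumed by the pipeline, not the generators) --
    detection_p: float = 0.01
    fdr: float = 0.05
    #: reference distribution for the per-gene likelihood-ratio statistic.
    #: "f" is exact under Gaussian errors at the study's small replicate
    #: counts; "chi2" is the asymptotic version and is sharply
    #: anti-conservative in the extreme tail at n=9 arrays.
    lrt_dist: str = "f"
    #: average matched control arrays across batches into pooled profiles
    #: before DE testing. Off by default: averaging shrinks the control
    #: group's variance threefold while the equal-variance model assumes
    #: none of that, and caps the error df at 7; testing against the raw
    #: control arrays keeps the test calibrated with df 19.
    pool_controls_de: bool = False
    window: int = 10_000
    #: least-variable probes per batch; ~25% of expressed genes, preserving
    #: the full-scale study's ratio (2,000 of ~8,000) at this gene count.
    n_control_probes: int = 1000
    k_grid_max: int = 10

    def validate(self) -> "SimConfig":
        lo, hi = self.kd_efficiency_range
        checks = [
            (self.n_genes > 0, "n_genes must be positive"),
            (0 < self.n_tfs <= self.n_genes, "n_tfs must be in [1, n_genes]"),
            (0 < self.n_knockdowns <= self.n_tfs,
             "n_knockdowns must be in [1, n_tfs]"),
            (self.n_batches >= 1, "n_batches must be >= 1"),
            (self.replicates_per_kd >= 2, "replicates_per_kd must be >= 2"),
            (self.controls_per_batch >= 2, "controls_per_batch must be >= 2"),
            (0 <= self.n_repeated <= self.n_knockdowns,
             "n_repeated must be in [0, n_knockdowns]"),
            (0 < lo <= hi < 1, "kd_efficiency_range must satisfy 0 < lo <= hi < 1"),
            (self.median_effect_pct > 0, "median_effect_pct must be positive"),
            (0 <= self.functional_fraction <= 1,
             "functional_fraction must be a fraction in [0, 1]"),
            (0 <= self.module_target_overlap <= 1,
             "module_target_overlap must be in [0, 1]"),
            (0 <= self.up_fraction <= 1, "up_fraction must be in [0, 1]"),
            (self.k_true >= 0, "k_true must be >= 0"),
            (self.noise_sd >= 0, "noise_sd must be >= 0"),
            (self.gene_spacing > 0, "gene_spacing must be positive"),
            (self.enhancer_enrichment > 0, "enhancer_enrichment must be positive"),
            (self.detection_s > 0, "detection_s must be positive"),
            (0 <= self.extra_probe_fraction <= 1,
             "extra_probe_fraction must be in [0, 1]"),
            (0 <= self.bad_probe_fraction <= 1,
             "bad_probe_fraction must be in [0, 1]"),
            (0 < self.fdr < 1, "fdr must be in (0, 1)"),
            (self.window > 0, "window must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        return self

    def rng(self, stage: int):
        """Per-stage random generator; stages are documented in synthdata."""
        import numpy as np

        return np.random.default_rng([int(self.seed) % (2**31), int(stage)])

    # --- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["kd_efficiency_range"] = list(self.kd_efficiency_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "kd_efficiency_range" in d:
            d["kd_efficiency_range"] = tuple(d["kd_efficiency_range"])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping of config fields")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
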