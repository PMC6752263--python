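"""Pipeline configuration: one flat namespace of per-module keys.

Every tunable threshold of the calling/filtering/phasing pipeline appears
here exactly once with its default. Config files are YAML mappings with
the same keys; unknown keys are rejected to catch typos.
"""
from __future__ import annotations

import yaml

DEFAULTS = {
    # depth
    "depth.expected_reads_per_bin": 100,
    "depth.grid_width_bp": 300,
    # segmentation / calling
    "segment.alpha": 0.01,
    "segment.n_permutations": 1000,
    "segment.min_bins_per_segment": 2,
    "segment.min_support_bins": 8,
    "segment.merge_gap_bp": 100_000,
    "segment.mosaic_gain_threshold": 2.25,
    "segment.mosaic_loss_threshold": 1.75,
    # annotation / filtering
    "annotate.graylist_max_fraction": 0.5,
    "annotate.gene_proximity_bp": 5_000,
    "annotate.population_max_frequency": 0.10,
    "annotate.loss_consistency_threshold": 1.75,
    "annotate.gain_consistency_threshold": 2.25,
    "annotate.min_interval_covered": 0.5,
    # phasing
    "phase.error_rate": 0.01,
    "phase.ambiguity_margin_nats": 2.0,
    # evaluation
    "evaluate.overlap_threshold_loose": 0.5,
    "evaluate.overlap_threshold_strict": 0.75,
    "evaluate.min_probes": 4,
    "evaluate.n_background_draws": 1000,
    # karyogram
    "karyogram.depth_segment_bp": 100_000,
    "karyogram.baf_segment_bp": 500_000,
    "karyogram.value_bin_step": 0.1,
    "karyogram.value_bin_max": 4.0,
}


def default_config() -> dict:
    return dict(DEFAULTS)


def load_config(path=None) -> dict:
    """Defaults overlaid with a YAML config file (if given)."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg
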