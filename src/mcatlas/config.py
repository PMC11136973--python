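"""Run configuration: YAML parsing, defaults, and range validation.

The default values of all analysis parameters are the published ones
(K = 100, K_cc = 30, 1000 bootstrap iterations at 75%, alpha = 2,
minimum metacell size 15, fold-change bins 1.5/1.1/1.0, motif similarity
0.95, 80%-of-max hit threshold, 2x GC-matched backgrounds, 10 GC bins,
...); the ``published`` preset is simply this default profile. Simulation
sizes are desk-scale defaults and are freely configurable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "validate_config", "DEFAULTS", "ALL_STAGES"]

ALL_STAGES = ["simulate", "cluster", "profile", "regmap", "motifs", "xspecies"]

DEFAULTS: dict = {
    "seed": 0,
    "stages": list(ALL_STAGES),
    "simulate": {
        "n_types": 4,
        "n_genes": 400,
        "markers_per_type": 10,
        "fold_levels": [8.0],
        "cells_per_type": 75,
        "depth_median": 1000.0,
        "depth_sigma": 0.6,
        "depth_min": 200,
        "depth_max": 20000,
        "chrom_length": 400000,
        "genome_genes": 40,
        "gc_target": 0.4,
        "min_spacing": 5000,
        "peaks_per_gene": 2,
        "extra_orphans": 5,
        "n_motifs": 4,
        "motif_width": 8,
        "motif_dominance": 0.92,
        "fg_rate": 0.4,
        "bg_rate": 0.05,
    },
    "cluster": {
        "K": 100,
        "K_cc": 30,
        "n_boot": 1000,
        "fraction": 0.75,
        "alpha": 2.0,
        "min_size": 15,
        "t_tot": 30,
        "t_prev_cells": 3,
        "t_prev_umi": 2,
        "t_szcor": -0.1,
        "t_niche": 0.01,
        "use_szcor": False,
        "use_niche": True,
        "low_quality_min_cells": 50,
        "low_quality_min_median_umi": 500,
    },
    "profile": {
        "eps": 0.1,
        "median_mode": "lower",
        "max_markers_per_cluster": 30,
        "min_marker_fc": 2.0,
        "annotation_floor": 0.0,
    },
    "regmap": {
        "min_neglog10_q": 6.0,
        "half_width": 125,
        "promoter_upstream": 50,
        "promoter_downstream": 200,
        "swap_promoter_orientation": False,
        "max_distance": 20000,
        "fc_high": 1.5,
        "fc_mild": 1.1,
        "fc_background": 1.0,
    },
    "motifs": {
        "ic_min": 0.5,
        "ic_run_len": 4,
        "ic_block_len": 3,
        "ic_n_blocks": 2,
        "similarity_threshold": 0.95,
        "min_overlap": 6,
        "score_fraction_min": 0.8,
        "background_multiple": 2,
        "n_gc_bins": 10,
    },
    "xspecies": {
        "one2one_frac": 0.8,
        "dup_frac": 0.1,
        "divergence_noise": 0.1,
        "cells_per_type": 75,
        "marker_fc_min": 1.0,
        "marker_p_max": 0.05,
        "tf_fc_min": 1.25,
        "corr_fc_floor": 1.05,
    },
}

# key -> (min, max, inclusive_low, inclusive_high); checked when present
_RANGES: dict[tuple[str, str], tuple[float, float, bool, bool]] = {
    ("cluster", "fraction"): (0.0, 1.0, False, True),
    ("cluster", "K"): (1, float("inf"), True, True),
    ("cluster", "K_cc"): (1, float("inf"), True, True),
    ("cluster", "n_boot"): (1, float("inf"), True, True),
    ("cluster", "min_size"): (1, float("inf"), True, True),
    ("cluster", "alpha"): (0.0, float("inf"), False, True),
    ("profile", "eps"): (0.0, float("inf"), False, True),
    ("regmap", "half_width"): (1, float("inf"), True, True),
    ("regmap", "max_distance"): (0, float("inf"), False, True),
    ("motifs", "score_fraction_min"): (0.0, 1.0, False, True),
    ("motifs", "similarity_threshold"): (0.0, 1.0, False, True),
    ("motifs", "n_gc_bins"): (1, float("inf"), True, True),
    ("motifs", "background_multiple"): (1, float("inf"), True, True),
    ("simulate", "fg_rate"): (0.0, 1.0, True, True),
    ("simulate", "bg_rate"): (0.0, 1.0, True, True),
    ("simulate", "gc_target"): (0.0, 1.0, True, True),
    ("xspecies", "one2one_frac"): (0.0, 1.0, True, True),
    ("xspecies", "dup_frac"): (0.0, 1.0, True, True),
    ("xspecies", "divergence_noise"): (0.0, float("inf"), True, True),
}


@dataclass
class RunConfig:
    """Validated, fully-defaulted pipeline configuration."""

    seed: int
    stages: list[str]
    sections: dict = field(default_factory=dict)

    def __getitem__(self, stage: str) -> dict:
        return self.sections[stage]

    def resolved(self) -> dict:
        out = {"seed": self.seed, "stages": list(self.stages)}
        out.update(copy.deepcopy(self.sections))
        return out


class ConfigError(ValueError):
    pass


def _check_range(section: str, key: str, value) -> None:
    rng = _RANGES.get((section, key))
    if rng is None:
        return
    lo, hi, inc_lo, inc_hi = rng
    ok_lo = value >= lo if inc_lo else value > lo
    ok_hi = value <= hi if inc_hi else value < hi
    if not (ok_lo and ok_hi):
        lob, hib = "[" if inc_lo else "(", "]" if inc_hi else ")"
        raise ConfigError(
            f"{section}.{key} = {value!r} out of range {lob}{lo}, {hi}{hib}"
        )


def validate_config(source: str | dict | None = None, preset: str = "published") -> RunConfig:
    """Parse and validate a YAML config file (or dict).

    Unknown keys are rejected; values are range-checked; anything not
    given falls back to the ``published`` preset defaults. An empty file (or
    None) yields the full default profile.
    """
    if preset != "published":
        raise ConfigError(f"unknown preset {preset!r}")
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = copy.deepcopy(source)
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config root must be a mapping")

    merged = copy.deepcopy(DEFAULTS)
    for key, value in user.items():
        if key not in merged:
            raise ConfigError(f"unknown config key: {key!r}")
        if key in ("seed", "stages"):
            merged[key] = value
            continue
        if not isinstance(value, dict):
            raise ConfigError(f"section {key!r} must be a mapping")
        for sub, v in value.items():
            if sub not in merged[key]:
                raise ConfigError(f"unknown config key: {key}.{sub}")
            merged[key][sub] = v

    if not isinstance(merged["seed"], int):
        raise ConfigError("seed must be an integer")
    unknown_stages = set(merged["stages"]) - set(ALL_STAGES)
    if unknown_stages:
        raise ConfigError(f"unknown stages: {sorted(unknown_stages)}")
    for section in ALL_STAGES:
        for key, value in merged[section].items():
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                _check_range(section, key, value)

    sections = {s: merged[s] for s in ALL_STAGES}
    return RunConfig(merged["seed"], list(merged["stages"]), sections)
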