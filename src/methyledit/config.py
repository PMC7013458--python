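"""Run configuration: schema-checked nested settings plus one global seed.

The serialized config together with the seed fully determines every
stochastic output of a pipeline run.  Unknown keys are rejected rather than
ignored — a typo silently falling back to a default is the classic way to
invalidate a re-run.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ConfigurationError

# Stage parameter defaults.  Sequencing-protocol values (2 x 250 reads,
# overlap 20, quality 20), binning (10 bp), re-calibration depth (K = 1000),
# off-target search depth (4 mismatches) and heatmap flank (1 kb) follow the
# experimental workflow this pipeline models; simulation-only knobs are the
# generator's documented defaults.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "methyledit_out",
    "log_level": "INFO",
    "amplicon": {
        "q_trim": 20,
        "min_overlap": 20,
        "max_mismatch_frac": 0.1,
        "min_identity": 0.9,
        "min_base_quality": 20,
        "min_reads": 100,
        "read_length": 250,
        "n_read_pairs": 5000,
        "conversion_rate": 0.998,
        "inappropriate_conversion": 0.002,
        "sequencing_error_rate": 0.001,
        "p_max": 0.6,
        "accessibility": 0.5,
        "target_length": 292,
        "target_n_cpgs": 19,
        "target_blocked": [16, 17, 18, 19],
        "target_analysis": list(range(1, 16)),
        "offtarget_length": 202,
        "offtarget_n_cpgs": 12,
        "reference_sample": "WT",
        "samples": [
            {"name": "WT", "theta": 1.0, "p_on": 0.84},
            {"name": "R887E", "theta": 0.12, "p_on": 0.64},
        ],
    },
    "mbd": {
        "bin_size": 10,
        "k": 1000,
        "n_cgis": 2400,
        "cgi_length": 300,
        "spacer_length": 700,
        "frac_methylated": 0.5,
        "n_fragments": 50000,
        "fragment_length_mean": 150.0,
        "fragment_length_sd": 30.0,
        "mbd_capture_q": 0.05,
        "p_max": 0.6,
        "p_on": 0.84,
        "background_quantile": 0.99,
        "min_differential": 0.0,
        "min_width": 100,
        "merge_gap": 50,
        "flank": 1000,
        "samples": [
            {"name": "WT", "theta": 1.0},
            {"name": "R887E", "theta": 0.12},
        ],
    },
    "offtarget": {
        "max_mismatches": 4,
        "pam": "NGG",
    },
}


def _merge_checked(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigurationError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and not isinstance(value, dict):
            raise ConfigurationError(f"{here} must be a mapping")
        if isinstance(defaults[key], dict):
            out[key] = _merge_checked(defaults[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


def make_config(overrides: dict | None = None) -> dict:
    """Defaults merged with ``overrides``; unknown keys raise."""
    return _merge_checked(DEFAULT_CONFIG, overrides or {})


def load_config(path) -> dict:
    """Read a YAML (or JSON — a YAML subset) config file and validate it."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping at top level")
    return make_config(raw)


def dump_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
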