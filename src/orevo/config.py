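"""Run configuration: defaults, validation, normalization.

Thresholds default to the standard OR-mining values: 250 aa minimum
protein length, 5 aa TM gap tolerance, 21-34 aa N-terminus, 30 bp
contig-end rule, search E-values 1e-10 (pass 1) and 1e-20 (pass 2),
1000 bootstrap replicates with a 70 merge floor.
"""

from __future__ import annotations

from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    # mining
    "derep_identity": 0.50,
    "evalue1": 1e-10,
    "evalue2": 1e-20,
    "min_protein_length": 250,
    "tm_gap_max": 5,
    "nterm_min": 21,
    "nterm_max": 34,
    "contig_end_max_bp": 30,
    "region_join_bp": 60,
    # classification
    "mcl_inflation": 1.5,
    "support_floor": 70,
    "class_support": 90,
    "bootstrap_replicates": 1000,
    # gain/loss
    "count_mode": "genes",
    # simulation (study conditions)
    "ancestral_family_count": 830,
    "beta": 0.003,
    "delta": 0.003,
    "marine_delta": None,  # float to raise loss on marine terminal branches
    "contig_count": 24,
    "contig_length": 30000,
    "gc_fraction": 0.42,
    "decoy_gpcr_count": 5,
    "pseudogenization_fraction": 0.25,
    "truncation_fraction": 0.08,
    "mutation_rate": 0.0005,
    "ogg_divergence": 0.35,
    "class1_fraction": 0.15,
    "tree_newick": None,  # None -> built-in 23-taxon dated tree
    "seed": 0,
}

_ALLOW_NONE = {"marine_delta", "tree_newick"}


class ConfigError(ValueError):
    pass


def validate_config(source=None) -> dict:
    """Merge a user mapping / YAML file over the defaults.

    Unknown keys are rejected; values must match the default's type
    (int accepted where float is expected).  Returns the normalized dict.
    """
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = dict(source)
    else:
        text = Path(source).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must hold a key: value mapping")
    errors = []
    cfg = dict(DEFAULT_CONFIG)
    for key, value in user.items():
        if key not in DEFAULT_CONFIG:
            errors.append(f"unknown key: {key}")
            continue
        default = DEFAULT_CONFIG[key]
        if value is None and key in _ALLOW_NONE:
            cfg[key] = None
            continue
        if default is None:
            expected = float if key == "marine_delta" else str
        else:
            expected = type(default)
        if expected is float and isinstance(value, int) and not isinstance(value, bool):
            value = float(value)
        if not isinstance(value, expected) or isinstance(value, bool) and expected is not bool:
            errors.append(f"{key}: expected {expected.__name__}, got {value!r}")
            continue
        cfg[key] = value
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg
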