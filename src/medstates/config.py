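"""Structured configuration with every stage tunable in one place.

Defaults follow the analysis conventions of the pipeline: 27-voxel ReHo
clusters, 90% row sparsity with cosine affinity for gradients, 200
eigenmodes, cubic-maximum polynomial trends, and 10,000 resamples for
permutation/bootstrap inference.  A YAML file with the same nested keys
overrides any subset.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

DEFAULTS: dict[str, Any] = {
    "io": {
        # desk-scale synthetic segments are shorter than the >=3 min of real
        # runs; below `warn_length` a warning is logged, below `min_length`
        # the segment is rejected
        "min_segment_length": 20,
        "warn_segment_length": 60,
    },
    "reho": {
        "cluster_size": 27,
        "fwhm_mm": 2.0,
        "min_neighbors": 4,
        "standardize": True,
        "smooth": True,
    },
    "gradients": {
        "sparsity": 0.90,
        "n_components": 10,
        "alpha": 0.5,
        "diffusion_time": 0,
        "procrustes_iterations": 10,
    },
    "eigenmodes": {
        "n_modes": 200,
        "log_base": 10,
        "log_floor": 1e-12,
        "projection": "mass",  # or "pseudoinverse"
    },
    "trends": {
        "max_degree": 3,
        "alpha": 0.05,
        "fdr_alpha": 0.05,
    },
    "plsc": {
        "n_permutations": 10000,
        "n_bootstraps": 10000,
    },
    "decoding": {
        "top_k": 10,
        "n_permutations": 10000,
    },
}


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Return the default configuration, optionally overridden by a YAML file."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, other: dict) -> None:
    for key, val in other.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
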