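"""Pipeline configuration: defaults and per-dataset presets.

Defaults follow the recommended settings of the algorithm: 10-frame
temporal averaging; 31x31 patches with the negative-seed circle at
radius 10 (< m/2 so the circle stays inside the patch); 3x3 positive
superpixels selected per 5x5-pixel grid block with the top 40% of
blocks processed; (sim)^2 sampling rate gamma = 0.32 and Gaussian scale
alpha = 1; sparse computation in p = 3 PCA dimensions with kappa = 25
grid sections; and the size-based postprocessor accepting 40-200 pixel
clusters with a preferred size of 80.

Named profiles carry the published per-dataset presets for the
Neurofinder benchmark movies (cell sizes differ across datasets).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = ["HNCcorrConfig", "PROFILES", "load_config"]


@dataclass(frozen=True)
class HNCcorrConfig:
    # temporal preprocessing
    temporal_downsample: int = 10
    # patch geometry
    patch_size: int = 31  # m, odd
    neg_radius: float = 10.0  # rho < patch_size / 2
    # seed selection
    superpixel_size: int = 3  # k, odd
    n_grid: int = 5
    p_seed: float = 0.40
    n_neg: int = 10
    # (sim)^2 similarity
    gamma: float = 0.32
    alpha: float = 1.0
    # sparse computation
    sparse_p: int = 3
    kappa: int = 25
    # size-based postprocessor
    n_min: int = 40
    n_max: int = 200
    n_avg: int = 80
    # pipeline
    overlap_max: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size % 2 == 0 or self.superpixel_size % 2 == 0:
            raise ValueError("patch_size and superpixel_size must be odd")
        if not self.neg_radius < self.patch_size / 2:
            raise ValueError("neg_radius must be less than half the patch size")
        if not (0 < self.n_min <= self.n_avg <= self.n_max):
            raise ValueError("need 0 < n_min <= n_avg <= n_max")

    def with_updates(self, **kwargs: Any) -> "HNCcorrConfig":
        return replace(self, **kwargs)


# Published per-dataset presets: patch size m, negative-seed radius rho,
# superpixel k, and postprocessor size bounds (n_min, n_max, n_avg).
PROFILES: dict[str, HNCcorrConfig] = {
    "00.00": HNCcorrConfig(patch_size=31, neg_radius=10, superpixel_size=5, n_min=40, n_max=150, n_avg=60),
    "00.01": HNCcorrConfig(patch_size=31, neg_radius=10, superpixel_size=5, n_min=40, n_max=150, n_avg=65),
    "01.00": HNCcorrConfig(patch_size=41, neg_radius=14, superpixel_size=5, n_min=40, n_max=380, n_avg=170),
    "01.01": HNCcorrConfig(patch_size=41, neg_radius=14, superpixel_size=5, n_min=40, n_max=380, n_avg=170),
    "02.00": HNCcorrConfig(patch_size=31, neg_radius=10, superpixel_size=1, n_min=40, n_max=200, n_avg=80),
    "02.01": HNCcorrConfig(patch_size=31, neg_radius=10, superpixel_size=1, n_min=40, n_max=200, n_avg=80),
    "03.00": HNCcorrConfig(patch_size=41, neg_radius=14, superpixel_size=5, n_min=40, n_max=300, n_avg=120),
    "04.00": HNCcorrConfig(patch_size=31, neg_radius=10, superpixel_size=3, n_min=50, n_max=190, n_avg=90),
    "04.01": HNCcorrConfig(patch_size=41, neg_radius=14, superpixel_size=3, n_min=50, n_max=370, n_avg=140),
}

# Dotted config-file keys -> dataclass fields.
_KEY_MAP = {
    "movie.downsample": "temporal_downsample",
    "patch.size": "patch_size",
    "patch.neg_radius": "neg_radius",
    "seed.k": "superpixel_size",
    "seed.n_grid": "n_grid",
    "seed.p_seed": "p_seed",
    "seed.n_neg": "n_neg",
    "sim.gamma": "gamma",
    "sim.alpha": "alpha",
    "sparse.p": "sparse_p",
    "sparse.kappa": "kappa",
    "post.n_min": "n_min",
    "post.n_max": "n_max",
    "post.n_avg": "n_avg",
    "post.overlap_max": "overlap_max",
    "rng.master_seed": "master_seed",
}

_INT_FIELDS = {
    "temporal_downsample", "patch_size", "superpixel_size", "n_grid", "n_neg",
    "sparse_p", "kappa", "n_min", "n_max", "n_avg", "master_seed",
}


def _coerce(field: str, value: Any) -> Any:
    return int(value) if field in _INT_FIELDS else value


def parse_overrides(pairs: dict[str, Any], base: HNCcorrConfig) -> HNCcorrConfig:
    """Apply ``{"seed.k": 1, ...}`` dotted-key overrides to a config."""
    updates = {}
    for key, value in pairs.items():
        if key in _KEY_MAP:
            field = _KEY_MAP[key]
        elif key in HNCcorrConfig.__dataclass_fields__:
            field = key
        else:
            raise KeyError(f"unknown config key {key!r}")
        updates[field] = _coerce(field, value)
    return base.with_updates(**updates)


def load_config(path: str | Path, base: HNCcorrConfig | None = None) -> HNCcorrConfig:
    """Load a YAML/JSON config file of dotted or nested keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    flat: dict[str, Any] = {}

    def flatten(prefix: str, obj: Any) -> None:
        if isinstance(obj, dict):
            for k, v in obj.items():
                flatten(f"{prefix}.{k}" if prefix else str(k), v)
        else:
            flat[prefix] = obj

    flatten("", raw)
    return parse_overrides(flat, base or HNCcorrConfig())
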