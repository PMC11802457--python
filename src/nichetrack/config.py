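"""Pipeline configuration: every tunable constant in one seeded, serializable place."""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .datatypes import ParameterError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Shared constants for all stages.

    Defaults follow the study conventions: counts scaled to 10,000 per cell
    before log transform, 5,000 highly variable genes, principal curves over
    the first 7 PCs, 8 temporal clusters, top-100 random-forest features,
    signatures shared by >= 2 niche populations, inflammatory spots called at
    module score > 0, two extended neighbor rings, 55-um microniche circles
    with 50% overlap, balanced 70/30 split with 10-fold cross-validation.
    """

    scale_factor: float = 10_000.0
    n_hvg: int = 5_000
    score_bins: int = 24
    score_ctrl: int = 100
    n_pcs_curve: int = 7
    n_temporal_clusters: int = 8
    fuzzifier: float = 1.25
    membership_threshold: float = 0.5
    n_modules: int = 4
    rf_top_features: int = 100
    rf_n_trees: int = 500
    markers_per_class: int = 50
    min_shared_celltypes: int = 2
    is_threshold: float = 0.0
    n_ens_layers: int = 2
    miche_radius_um: float = 55.0
    miche_overlap: float = 0.5
    train_frac: float = 0.7
    cv_folds: int = 10
    marker_alpha: float = 0.05
    marker_lfc_min: float = 0.25
    seed: int = 0

    def __post_init__(self):
        positive = (
            "scale_factor n_hvg score_bins score_ctrl n_pcs_curve n_temporal_clusters "
            "n_modules rf_top_features rf_n_trees markers_per_class min_shared_celltypes "
            "n_ens_layers miche_radius_um cv_folds"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"config field {name} must be positive")
        for name in ("train_frac", "miche_overlap"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"config field {name} must lie in (0, 1)")
        if not 0.0 < self.membership_threshold <= 1.0:
            raise ParameterError("membership_threshold must lie in (0, 1]")
        if self.fuzzifier <= 1.0:
            raise ParameterError("fuzzifier must be > 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
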