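"""Pipeline configuration.

Every numeric threshold used by the pipeline stages lives here, so no
operation hard-codes a cutoff.  Defaults follow the published protocol
parameters: 2 µm mask expansion, 20-neighbor microenvironments, 10
baso-luminal bins, the per-protocol QC cutoffs, the >1500-dot / <0.15
donor-variance / >0.05 layer-variability gene filters, the 50-cell niche
floor and the z > 2 enrichment threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys or semantically invalid threshold values."""


@dataclass
class PipelineConfig:
    # decoding
    min_quality: float = 0.5          # per-spot quality floor (0 disables)
    quality_aggregate: str = "min"    # "min" or "mean" over rounds
    # assignment
    expansion_um: float = 2.0         # nuclear mask expansion radius, µm
    qc_min_genes: int = 3             # high-plex protocol: distinct genes
    qc_min_counts: int = 5            # high-plex protocol: total counts
    qc_min_counts_scrinshot: int = 25
    qc_min_counts_scrinshot_copd: int = 8
    # typing
    n_neighbors: int = 20
    resolution: float = 1.5
    n_pcs: int = 7
    annotate_margin: float = 0.10     # fraction of top score
    rare_positivity: float = 0.20     # fraction of per-gene max count
    # niches
    k: int = 20                       # microenvironment size
    n_permutations: int = 1000
    enrichment_threshold: float = 2.0
    min_cluster_size: int = 50
    niche_resolution: float = 1.0
    # axes
    bins: int = 10
    min_dots_per_sample: int = 1500
    max_donor_variance: float = 0.15
    min_layer_std: float = 0.05
    min_membrane_length_mm: float = 2.0
    layer_stat: str = "bin_profile_sd"  # or "bin_mean_distance_sd"
    # stats
    permanova_distance: str = "bray-curtis"
    permanova_permutations: int = 999
    visium_top_n: int = 10
    visium_cells_per_spot: int = 10
    # randomness
    seed: int = 0

    _POSITIVE = (
        "expansion_um", "qc_min_genes", "qc_min_counts", "qc_min_counts_scrinshot",
        "qc_min_counts_scrinshot_copd", "n_neighbors", "resolution",
        "k", "n_permutations", "min_cluster_size", "niche_resolution", "bins",
        "min_dots_per_sample", "min_membrane_length_mm", "permanova_permutations",
        "visium_top_n", "visium_cells_per_spot",
    )

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.quality_aggregate not in ("min", "mean"):
            raise ConfigError("quality_aggregate must be 'min' or 'mean'")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected, absent keys take the
    defaults above.  Keyword overrides are applied last."""
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: expected a mapping of config keys")
        values.update(loaded)
    values.update(overrides)
    valid = {f.name for f in fields(PipelineConfig) if not f.name.startswith("_")}
    unknown = sorted(set(values) - valid)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {unknown}; valid keys: {sorted(valid)}")
    return PipelineConfig(**values)
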