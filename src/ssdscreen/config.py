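"""Pipeline configuration.

Every printed constant of the analysis lives here as a default, never hard-coded
in the stages: the 80% species-prevalence filter, the three-gene minimum, the
zero-variance removal (implicit), the BH alpha, the effect-size label threshold,
the 10,000-resample null, and the <50-family "small GO" pooling rule.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclasses.dataclass
class AnalysisConfig:
    """Declarative settings shared by all pipeline stages.

    Parameters
    ----------
    prevalence_threshold : float
        Minimum fraction of species in which a family must have a nonzero count
        (a family is kept when present in >= ceil(threshold * n_species) species).
    min_max_count : int
        A family must reach at least this count in at least one species.
    effect_r_threshold : float
        |r| above which a significant family is additionally labelled "strong".
    alpha : float
        Significance level applied to BH-adjusted (or raw, see ``use_raw_p``) p-values.
    n_resamples : int
        Number of random draws for the enrichment null and the expression bootstrap.
    random_seed : int
        Seed for every stochastic stage.
    brain_label : str
        Tissue identifier designating the brain in expression tables.
    small_go_min : int
        GO terms annotated to fewer than this many families are pooled into the
        excluded pseudo-term ``small_GO``.
    use_raw_p : bool
        Classify expansion/contraction on raw instead of BH-adjusted p-values.
    enrichment_two_sided : bool
        Report two-sided instead of upper-tail (enrichment-only) p from Z.
    assoc_method : str
        Correlation estimator for the SSD-vs-body-mass association
        ("pearson" or "spearman").
    """

    prevalence_threshold: float = 0.80
    min_max_count: int = 3
    effect_r_threshold: float = 0.3
    alpha: float = 0.05
    n_resamples: int = 10_000
    random_seed: int = 0
    brain_label: str = "brain"
    small_go_min: int = 50
    use_raw_p: bool = False
    enrichment_two_sided: bool = False
    assoc_method: str = "pearson"

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence_threshold <= 1.0):
            raise ConfigError(
                f"prevalence_threshold must be in (0, 1], got {self.prevalence_threshold}"
            )
        if self.n_resamples < 1:
            raise ConfigError(f"n_resamples must be >= 1, got {self.n_resamples}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_max_count < 0:
            raise ConfigError(f"min_max_count must be >= 0, got {self.min_max_count}")
        if self.small_go_min < 0:
            raise ConfigError(f"small_go_min must be >= 0, got {self.small_go_min}")
        if self.assoc_method not in ("pearson", "spearman"):
            raise ConfigError(f"assoc_method must be pearson or spearman, got {self.assoc_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a flat key: value YAML file; unknown keys are an error."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must be a mapping of key: value pairs")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
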