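"""Run configuration: every tunable threshold of the scoring and annotation engine.

The thresholds are the analytic constants of the method: a fold change
below ``fc_down`` after ectopic miRNA expression counts as repression, a
fold change above ``fc_up`` after miRNA knockout/knockdown counts as
induction, a Pearson coefficient below ``r_cut`` counts as
anti-correlation, and the prediction-call denominator is the configured
algorithm complement.  All comparisons are strict.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """A threshold or option is outside its legal range."""


@dataclass
class RunConfig:
    """Thresholds and options shared by every command.

    Parameters
    ----------
    fc_down : float
        Repression cutoff for ectopic-miRNA fold changes (linear scale,
        treated/control).  Must lie in (0, 1); a pair is supported when
        fold change < ``fc_down``.
    fc_up : float
        Induction cutoff for knockout/knockdown fold changes.  Must be
        > 1; supported when fold change > ``fc_up``.
    r_cut : float
        Anti-correlation cutoff for miRNA/mRNA Pearson coefficients.
        Must lie in (-1, 0); supported when r < ``r_cut``.
    alpha : float
        Significance level for clinical direction calls and enrichment
        summaries (applied to BH-adjusted p-values by default).
    dep_effect : float
        Gene-effect threshold for dependency: a cell line is dependent
        when its effect score is strictly below this value.
    dep_frac : float
        Minimum (inclusive) fraction of cell lines below ``dep_effect``
        for a gene to be flagged dependent in a cancer type.
    top_k : int
        Size of the per-miRNA top target set used by summary scores and
        user-list enrichment.
    n_perm : int
        Number of permutations for preranked GSEA p-values.
    seed : int
        Seed for every stochastic step (permutations, simulation).
    min_validated : int
        Minimum validated-target count for a miRNA to enter the GSEA
        benchmark.
    use_adjusted_p : bool
        Use BH-adjusted p-values (rather than raw) for clinical
        direction calls.
    """

    fc_down: float = 0.8
    fc_up: float = 1.25
    r_cut: float = -0.1
    alpha: float = 0.05
    dep_effect: float = -0.5
    dep_frac: float = 0.10
    top_k: int = 1000
    n_perm: int = 1000
    seed: int = 0
    min_validated: int = 10
    use_adjusted_p: bool = True
    algorithms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.fc_down < 1.0):
            raise ConfigurationError(
                f"fc_down must lie in (0, 1) -- a repression cutoff at or above 1 "
                f"would count unchanged or induced mRNAs as repressed (got {self.fc_down})"
            )
        if not (self.fc_up > 1.0):
            raise ConfigurationError(
                f"fc_up must exceed 1 -- an induction cutoff at or below 1 would "
                f"count unchanged or repressed mRNAs as induced (got {self.fc_up})"
            )
        if not (-1.0 < self.r_cut < 0.0):
            raise ConfigurationError(
                f"r_cut must lie in (-1, 0); anti-correlation is the evidence "
                f"(got {self.r_cut})"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha must lie in (0, 1) (got {self.alpha})")
        if not (self.dep_effect < 0.0):
            raise ConfigurationError(
                f"dep_effect must be negative (got {self.dep_effect})"
            )
        if not (0.0 < self.dep_frac <= 1.0):
            raise ConfigurationError(
                f"dep_frac must lie in (0, 1] (got {self.dep_frac})"
            )
        if self.top_k < 1:
            raise ConfigurationError(f"top_k must be >= 1 (got {self.top_k})")
        if self.n_perm < 100:
            raise ConfigurationError(f"n_perm must be >= 100 (got {self.n_perm})")
        if self.min_validated < 1:
            raise ConfigurationError(
                f"min_validated must be >= 1 (got {self.min_validated})"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML, overriding defaults with the file's keys."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys in {path}: {sorted(unknown)}"
            )
        return cls(**data)
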