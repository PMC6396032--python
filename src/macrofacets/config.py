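"""Analysis configuration shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Tunable parameters of the diversity/space/environment analysis.

    Parameters
    ----------
    alpha : float
        Significance level for permutation tests and forward selection.
    n_perm : int
        Number of Monte Carlo permutations (999 is the conventional choice
        for the tests this pipeline runs).
    percentile_step : float
        Width of the percentile bands for the spatial-congruence analysis;
        0.10 compares top-10%, top-20%, ... site sets.
    seed : int
        Seed for every stochastic step (permutation tests, randomization
        nulls, synthetic data).
    truncation_multiplier : float
        Beyond-threshold replacement for the dbMEM truncated distance
        matrix: distances larger than the minimum-spanning-tree threshold
        ``t`` are replaced by ``truncation_multiplier * t`` (4 is the
        classic PCNM convention).
    pcoa_correction : str
        Negative-eigenvalue correction applied before the trait-space
        principal coordinates analysis: ``sqrt`` (element-wise square root
        of dissimilarities), ``cailliez`` or ``none``.
    n_fric_axes : int or None
        Number of trait-space axes used for the convex-hull indices.
        ``None`` applies the policy ``min(3, min_site(S) - 1)`` bounded
        below by 2.
    moran_n_classes : int
        Number of equal-width distance classes in Moran's I correlograms.
    env_transforms : dict
        Per-column pre-standardization transform for the environment table,
        values in {"none", "log", "sqrt"}; columns not listed get "none".
    """

    alpha: float = 0.05
    n_perm: int = 999
    percentile_step: float = 0.10
    seed: int = 0
    truncation_multiplier: float = 4.0
    pcoa_correction: str = "sqrt"
    n_fric_axes: int | None = None
    moran_n_classes: int = 10
    env_transforms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {self.n_perm}")
        if not 0.0 < self.percentile_step <= 1.0:
            raise ValueError(
                f"percentile_step must be in (0, 1], got {self.percentile_step}"
            )
        if self.pcoa_correction not in {"sqrt", "cailliez", "none"}:
            raise ValueError(
                f"pcoa_correction must be one of sqrt/cailliez/none, "
                f"got {self.pcoa_correction!r}"
            )
        if self.moran_n_classes < 2:
            raise ValueError("moran_n_classes must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
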