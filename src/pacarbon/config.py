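"""Configuration dataclasses for the synthetic landscape and the analysis pipeline.

Two configs drive everything: :class:`LandscapeConfig` parameterises the synthetic
world (grid geometry, confounded protected-area placement, lidar sampling noise)
and :class:`RunConfig` parameterises the analysis stages (quality filters, buffer,
caliper, carbon factor, attribution thresholds).  Both validate on construction and
serialise to plain dicts so every run manifest can echo the full parameter set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic 1-km landscape.

    The grid is a flat equal-area plane of 1 km square cells; distances are
    Euclidean kilometres.  Protection placement is confounded: cells with high
    "suitability" (a fixed linear index of the quantitative covariates that also
    raises expected biomass) are more likely to seed a protected area, with the
    logistic weight scaled by ``confounding_strength``.

    Parameters
    ----------
    pa_effect_delta
        True additional aboveground biomass density (Mg/ha AGBD) caused by
        protection; may be any real number.
    confounding_strength
        Dimensionless multiplier on the suitability index in the placement
        logit. 0 gives randomised placement.
    pa_clustering
        Weight of an independent smooth "designation region" field in the
        placement logit; positive values cluster PAs into park complexes
        (their exclusion buffers then overlap, as in real PA networks) without
        adding confounding, since the field never enters biomass.
    loss_rate_protected, loss_rate_unprotected
        Expected 2000-2019 forest-cover-loss fraction per cell by status.
    shot_noise_sd
        Per-shot AGBD noise SD (Mg/ha), truncated so AGBD stays non-negative.
    cell_noise_sd
        SD of cell-level biomass heterogeneity not explained by the covariates
        (Mg/ha). Kept spatially white so paired differences are independent.
    track_gap_fraction
        Fraction of 5-km along-track segments dropped (cloud/quality masking at
        orbit-segment scale); this is what leaves some cells with few shots.
    sensitivity_beta
        (a, b) of the Beta distribution for the per-shot sensitivity metric.
    baseline_growth_per_year
        Extra year-2000 baseline AGBD (Mg/ha) accrued per year of protection
        before 2000; drives the preferential-placement check's age signal.
    """

    grid_rows: int = 100
    grid_cols: int = 100
    n_countries: int = 3
    n_biomes: int = 2
    n_ecoregions: int = 4
    n_landcovers: int = 3
    n_pas: int = 20
    pa_clustering: float = 1.5
    pa_effect_delta: float = 10.0
    confounding_strength: float = 1.25
    loss_rate_protected: float = 0.01
    loss_rate_unprotected: float = 0.05
    footprint_spacing_along_m: float = 60.0
    track_spacing_m: float = 600.0
    shot_noise_sd: float = 25.0
    cell_noise_sd: float = 15.0
    p_bad_quality: float = 0.1
    sensitivity_beta: Tuple[float, float] = (30.0, 1.0)
    track_gap_fraction: float = 0.3
    pa_halfwidth_range: Tuple[int, int] = (2, 3)
    pa_status_year_range: Tuple[int, int] = (1975, 2015)
    baseline_growth_per_year: float = 0.25
    baseline_mean_agbd: float = 120.0
    baseline_index_effect: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grid_rows", "grid_cols", "n_countries", "n_biomes",
                     "n_ecoregions", "n_landcovers", "n_pas"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("loss_rate_protected", "loss_rate_unprotected",
                     "p_bad_quality", "track_gap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("footprint_spacing_along_m", "track_spacing_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.shot_noise_sd < 0 or self.cell_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        a, b = self.sensitivity_beta
        if a <= 0 or b <= 0:
            raise ValueError("sensitivity_beta parameters must be > 0")
        lo, hi = self.pa_halfwidth_range
        if not (1 <= lo <= hi):
            raise ValueError("pa_halfwidth_range must satisfy 1 <= lo <= hi")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunConfig:
    """Parameters of the analysis pipeline, echoed verbatim into run manifests."""

    buffer_km: float = 10.0
    caliper_factor: float = 0.2
    match_rule: str = "nearest"
    min_shots: int = 5
    sensitivity_threshold: float = 0.95
    carbon_factor: float = 0.49
    pos_threshold: float = 5.0
    zero_halfwidth: float = 2.5
    model_rel_se: float = 0.02
    seed: int = 0
    verbosity: int = 1
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)

    def __post_init__(self) -> None:
        if self.match_rule not in ("nearest", "max_score"):
            raise ValueError("match_rule must be 'nearest' or 'max_score'")
        if self.buffer_km < 0 or self.caliper_factor <= 0:
            raise ValueError("buffer_km must be >= 0 and caliper_factor > 0")
        if self.min_shots < 1:
            raise ValueError("min_shots must be >= 1")
        if not 0.0 <= self.sensitivity_threshold <= 1.0:
            raise ValueError("sensitivity_threshold must be in [0, 1]")
        if self.carbon_factor <= 0:
            raise ValueError("carbon_factor must be > 0")
        if self.zero_halfwidth < 0 or self.pos_threshold < self.zero_halfwidth:
            raise ValueError("need 0 <= zero_halfwidth <= pos_threshold")
        if self.model_rel_se < 0:
            raise ValueError("model_rel_se must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d
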