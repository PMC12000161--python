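"""Run configuration shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


def critical_multiplier(level: float = 0.95) -> float:
    """One-sided normal quantile behind the critical-region multiplier.

    At the default 95% level this is Φ⁻¹(0.95) ≈ 1.645, the factor that
    scales the replicate-noise dsigma into the on-transit membership
    radius.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    return float(stats.norm.ppf(level))


@dataclass(frozen=True)
class RunConfig:
    """Tunable pipeline parameters with their conventional defaults.

    ``critical_mult`` defaults to the one-sided 95% normal quantile
    (rounded to the conventional 1.645 used in reporting); ``ci_level``
    is the two-sided level for the contrast null bands; ``geodesic_m``
    the discretization of each geodesic path; ``lever_threshold`` the α
    cutoff (degrees) between class-1 crushing and class-3 cutting
    designs.
    """

    station_count: int = 18
    critical_mult: float = 1.645
    mds_dims: int = 2
    geodesic_m: int = 201
    ci_level: float = 0.95
    lever_threshold: float = 90.0
    seed: int = 0
    jitter_rel: float = 1e-8

    def __post_init__(self) -> None:
        if min(
            self.station_count, self.critical_mult, self.mds_dims,
            self.geodesic_m, self.ci_level, self.lever_threshold, self.jitter_rel,
        ) <= 0:
            raise ValueError("all configuration values must be positive")
        if abs(self.critical_mult - critical_multiplier(self.ci_level)) > 0.05:
            raise ValueError(
                "critical_mult and ci_level are inconsistent: the multiplier "
                "should be the one-sided normal quantile of the CI level"
            )
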