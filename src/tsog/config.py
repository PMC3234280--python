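"""Configuration objects shared across pipeline stages.

Every threshold that the screens depend on is a named field with the study's
default, so a run's operating point is always visible and overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ConfigError(ValueError):
    pass


@dataclass
class ThresholdConfig:
    """Copy-number thresholds and inclusion rules.

    amp_threshold / del_threshold define the per-cell CNV state
    (amplified iff seg.mean >= amp_threshold, deleted iff seg.mean <
    del_threshold — the deletion bound is strict, so 0.00 is neutral).
    high/low_screen_threshold are the much more stringent cuts used to form
    the high- and low-copy groups of the rank-sum screen.  min_num_info
    drops CBS segments supported by fewer informative markers.
    near_zero_trim removes, per sign, the fraction of cells closest to
    seg.mean 0 before frequency analyses.  min_sample_fraction is the
    group-size gate ("a minimum 20% of the tumor samples").
    """

    amp_threshold: float = 0.50
    del_threshold: float = 0.00
    high_screen_threshold: float = 1.25
    low_screen_threshold: float = -0.50
    min_num_info: int = 4
    near_zero_trim: float = 0.05
    min_sample_fraction: float = 0.20
    #: gate used by the normal-deviation filter (|seg.mean| > dev_threshold)
    dev_threshold: float = 0.50
    #: extreme-deletion cut for the feature classifier's gene selection; at
    #: minimum a one-copy loss (LOH), unlike the permissive del_threshold
    #: that defines the per-cell state.  ROMA-style platforms with compressed
    #: dynamic range configure this back to 0.0.
    extreme_del_threshold: float = -0.50
    #: extreme-amplification cut for the feature classifier (one copy gained)
    extreme_amp_threshold: float = 0.50
    #: 'per_group' gates each of low/high separately; 'combined' gates the sum
    gate_mode: str = "per_group"

    def __post_init__(self):
        if not self.del_threshold < self.amp_threshold:
            raise ConfigError("del_threshold must be < amp_threshold")
        if not (0 <= self.near_zero_trim < 0.5):
            raise ConfigError("near_zero_trim must lie in [0, 0.5)")
        if not (0 < self.min_sample_fraction <= 1):
            raise ConfigError("min_sample_fraction must lie in (0, 1]")
        if self.min_num_info < 1:
            raise ConfigError("min_num_info must be >= 1")
        if self.gate_mode not in ("per_group", "combined"):
            raise ConfigError(f"unknown gate_mode {self.gate_mode!r}")
        if not self.extreme_del_threshold < self.extreme_amp_threshold:
            raise ConfigError("extreme_del_threshold must be < extreme_amp_threshold")

    def extreme_state_config(self) -> "ThresholdConfig":
        """States at the feature classifier's extreme-CNV cuts."""
        return ThresholdConfig(
            amp_threshold=self.extreme_amp_threshold,
            del_threshold=self.extreme_del_threshold,
            high_screen_threshold=self.high_screen_threshold,
            low_screen_threshold=self.low_screen_threshold,
            min_num_info=self.min_num_info,
            near_zero_trim=self.near_zero_trim,
            min_sample_fraction=self.min_sample_fraction,
            dev_threshold=self.dev_threshold,
            gate_mode=self.gate_mode,
            extreme_del_threshold=self.extreme_del_threshold,
            extreme_amp_threshold=self.extreme_amp_threshold,
        )

    def to_dict(self) -> dict:
        return asdict(self)


PLANTED_CLASSES = (
    "oncogene_like",
    "ts_like",
    "amplified_suppressed",
    "deleted_expressed",
)

METHYLATION_DIALECTS = ("moma_ratio", "beta")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic tumor/normal cohort generator.

    The planted classes follow the feature model: an oncogene-like gene is
    amplified, hypomethylated and over-expressed in the altered tumor
    fraction; a tumor-suppressor-like gene is the mirror image; the two
    cross classes carry discordant copy-number and methylation so that the
    methylation term dominates expression.

    Defaults mirror the study cohort geometry (42 tumors, 7 tissue normals,
    22 autosomes) at a desk-scale gene count.
    """

    n_genes: int = 1000
    n_tumor: int = 42
    n_normal: int = 7
    n_chromosomes: int = 22
    planted_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "oncogene_like": 0.05,
            "ts_like": 0.05,
            "amplified_suppressed": 0.02,
            "deleted_expressed": 0.02,
        }
    )
    #: mean |seg.mean| shift of altered cells (log2-ratio units)
    cnv_effect: float = 1.0
    #: log2-expression change per unit seg.mean
    expr_dosage_slope: float = 1.0
    #: methylation shift of altered cells (platform units)
    meth_effect: float = 0.3
    #: log2-expression change per unit methylation above the platform center
    meth_coupling: float = 5.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"cnv": 0.20, "methylation": 0.05, "expression": 0.30}
    )
    #: jitter of the planted seg.mean around +/- cnv_effect
    cnv_effect_jitter: float = 0.05
    #: seg.mean spread of normal samples (reference state)
    normal_cnv_sd: float = 0.02
    methylation_dialect: str = "beta"
    #: fraction of tumor samples carrying each planted alteration
    altered_sample_fraction: float = 0.5
    expr_baseline_mean: float = 7.0
    expr_baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.planted_fractions) - set(PLANTED_CLASSES)
        if unknown:
            raise ConfigError(f"unknown planted classes: {sorted(unknown)}")
        for cls, frac in self.planted_fractions.items():
            if not (0 <= frac <= 1):
                raise ConfigError(f"planted fraction for {cls} outside [0, 1]")
        if sum(self.planted_fractions.values()) > 1 + 1e-12:
            raise ConfigError("planted fractions must sum to <= 1")
        if self.n_tumor < 2 or self.n_normal < 1:
            raise ConfigError("need n_tumor >= 2 and n_normal >= 1")
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ConfigError("n_genes and n_chromosomes must be positive")
        for mod, sd in self.noise_sd.items():
            if sd <= 0:
                raise ConfigError(f"noise_sd[{mod!r}] must be > 0")
        if self.methylation_dialect not in METHYLATION_DIALECTS:
            raise ConfigError(f"unknown methylation dialect {self.methylation_dialect!r}")
        if not (0 < self.altered_sample_fraction <= 1):
            raise ConfigError("altered_sample_fraction must lie in (0, 1]")

    @property
    def platform_center(self) -> float:
        """Methylation value of the unaltered reference state."""
        return 0.5 if self.methylation_dialect == "beta" else 1.0

    def to_dict(self) -> dict:
        return asdict(self)


def round_half_up(x: float) -> int:
    """Deterministic round-half-up used for planted counts and tail sizes."""
    import math

    return int(math.floor(x + 0.5))
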