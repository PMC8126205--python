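"""Run configuration: dataclasses for the simulator and pipeline presets.

Two presets are shipped: ``study`` reproduces the design of the vitamin D3
supplementation cohort (80 participants sampled pre/post, a 264-gene targeted
panel with 8 housekeeping assays, 53 planted down-regulated genes and one
up-regulated gene), ``small`` is a fast miniature with the same structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    """Raised when a configuration is internally inconsistent."""


@dataclass(frozen=True)
class LevelParams:
    """Truncated-normal parameters for a serum 25(OH)D level distribution (ng/mL)."""

    mean: float
    sd: float
    low: float
    high: float

    def validate(self) -> None:
        if not (self.low < self.high):
            raise ConfigError(f"level bounds inverted: [{self.low}, {self.high}]")
        if self.sd <= 0:
            raise ConfigError("level sd must be positive")
        if self.low <= 0:
            raise ConfigError("25(OH)D levels must be strictly positive")


@dataclass(frozen=True)
class RepertoireConfig:
    """Parameters for simulating a blood co-expression module repertoire.

    The repertoire mimics a catalogue of co-expression modules whose activity
    (signed percent of member genes up/down-regulated) was profiled across a
    reference collection of blood transcriptome datasets.  Modules are planted
    in well-separated subgroups so that partition-recovery is testable.
    """

    n_modules: int = 382
    n_datasets: int = 16
    n_subgroups_planted: int = 66
    genes_per_module_min: int = 4
    genes_per_module_max: int = 30
    responsive_fraction: float = 1.0
    separation: float = 40.0  # per-coordinate centroid spread, activity units
    noise_sd: float = 2.0     # within-subgroup spread, activity units
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_modules, self.n_datasets, self.n_subgroups_planted) <= 0:
            raise ConfigError("all repertoire counts must be positive")
        if self.n_subgroups_planted > self.n_modules:
            raise ConfigError(
                f"n_subgroups_planted={self.n_subgroups_planted} exceeds "
                f"n_modules={self.n_modules}"
            )
        if self.separation <= 0:
            raise ConfigError("separation must be > 0")
        if not (0 < self.genes_per_module_min <= self.genes_per_module_max):
            raise ConfigError("invalid genes-per-module range")
        if not (0.0 <= self.responsive_fraction <= 1.0):
            raise ConfigError("responsive_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters for simulating the paired pre/post supplementation cohort.

    Effects are planted on the Ct scale: a down-regulated gene with fold
    change F gets a phase-II dCt shift of +log2(F) (later cycles = less
    transcript), the up-regulated gene a shift of -log2(F).
    ``pair_noise_sd`` is the standard deviation of the paired dCt difference
    (each measurement receives Gaussian noise of sd pair_noise_sd/sqrt(2)).
    """

    n_participants: int = 80
    n_target_genes: int = 264
    n_housekeeping: int = 8
    n_down_planted: int = 53
    n_up_planted: int = 1
    planted_fc_low: float = 2.0
    planted_fc_high: float = 2.6
    up_fc: float = 2.4
    pair_noise_sd: float = 0.5   # Ct units, sd of dCt_II - dCt_I
    hk_sd: float = 0.2           # Ct units, housekeeping assay noise
    sample_offset_sd: float = 0.5  # Ct units, per-sample loading offset
    baseline_dct_low: float = 0.0  # target baseline dCt range, Ct units
    baseline_dct_high: float = 5.0
    detect_max_ct: float = 28.0
    missing_rate: float = 0.01
    n_failing_samples: int = 0
    n_responders: int = 70
    pre_level_params: LevelParams = field(
        default_factory=lambda: LevelParams(11.0, 4.5, 2.5, 22.8)
    )
    post_level_params_r: LevelParams = field(
        default_factory=lambda: LevelParams(37.5, 10.0, 20.01, 62.72)
    )
    post_level_params_nr: LevelParams = field(
        default_factory=lambda: LevelParams(9.0, 4.0, 2.96, 19.0)
    )
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_participants, self.n_target_genes, self.n_housekeeping) <= 0:
            raise ConfigError("cohort counts must be positive")
        if self.n_down_planted + self.n_up_planted > self.n_target_genes:
            raise ConfigError("planted gene count exceeds panel size")
        if self.planted_fc_low <= 1.0:
            raise ConfigError("planted fold changes must exceed 1")
        if self.planted_fc_low > self.planted_fc_high:
            raise ConfigError("planted FC range inverted")
        if self.up_fc <= 1.0:
            raise ConfigError("up_fc must exceed 1")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ConfigError("missing_rate must be a probability")
        if self.n_responders > self.n_participants:
            raise ConfigError("responder count exceeds cohort size")
        if self.n_failing_samples > 2 * self.n_participants:
            raise ConfigError("more failing samples than samples")
        for sd in (self.pair_noise_sd, self.hk_sd, self.sample_offset_sd):
            if sd < 0:
                raise ConfigError("noise sds must be >= 0")
        for lp in (self.pre_level_params, self.post_level_params_r,
                   self.post_level_params_nr):
            lp.validate()
        if self.post_level_params_r.low < 20.0:
            raise ConfigError("responder post levels must start at >= 20 ng/mL")
        if self.post_level_params_nr.high >= 20.0:
            raise ConfigError("non-responder post levels must stay below 20 ng/mL")


#: Study-design presets. "study" mirrors the supplementation trial geometry;
#: "study-qc" additionally plants two failing samples for the QC stage;
#: "small" is a fast miniature for smoke tests and examples.
PRESETS: dict[str, dict[str, Any]] = {
    "study": {"repertoire": {}, "cohort": {}},
    "study-qc": {"repertoire": {}, "cohort": {"n_failing_samples": 2}},
    "small": {
        "repertoire": {
            "n_modules": 24,
            "n_datasets": 6,
            "n_subgroups_planted": 6,
            "genes_per_module_max": 8,
        },
        "cohort": {
            "n_participants": 12,
            "n_target_genes": 24,
            "n_housekeeping": 4,
            "n_down_planted": 4,
            "n_up_planted": 1,
            "n_responders": 10,
        },
    },
}


def _build(cls, overrides: Mapping[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(overrides)
    for key in ("pre_level_params", "post_level_params_r", "post_level_params_nr"):
        if key in kwargs and isinstance(kwargs[key], Mapping):
            kwargs[key] = LevelParams(**kwargs[key])
    obj = cls(**kwargs)
    obj.validate()
    return obj


def repertoire_config(preset: str = "study", **overrides: Any) -> RepertoireConfig:
    """Build a :class:`RepertoireConfig` from a preset plus overrides."""
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    merged = {**PRESETS[preset]["repertoire"], **overrides}
    return _build(RepertoireConfig, merged)


def cohort_config(preset: str = "study", **overrides: Any) -> CohortConfig:
    """Build a :class:`CohortConfig` from a preset plus overrides."""
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    merged = {**PRESETS[preset]["cohort"], **overrides}
    return _build(CohortConfig, merged)


@dataclass
class RunConfig:
    """Nested run configuration for the command-line pipeline.

    Every parameter has a default; unknown keys are rejected so that typos in
    config files fail loudly rather than silently running with defaults.
    """

    preset: str = "study"
    seed: int = 0
    repertoire: RepertoireConfig = field(default_factory=RepertoireConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    panel: dict[str, Any] = field(default_factory=lambda: {
        "k": 66, "threshold": 25.0, "n_pick": 4, "n_restarts": 25,
    })
    preprocess: dict[str, Any] = field(default_factory=lambda: {
        "detect_max_ct": 28.0, "max_missing_frac": 0.5,
        "hk_sd_max": 1.5, "impute_rank": 2,
    })
    dge: dict[str, Any] = field(default_factory=lambda: {
        "fc_threshold": 2.0, "alpha": 0.01, "exact_n_max": 25,
    })

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        preset = raw.get("preset", "study")
        cfg = cls(preset=preset, seed=int(raw.get("seed", 0)))
        cfg.repertoire = repertoire_config(preset, **(raw.get("repertoire") or {}))
        cfg.cohort = cohort_config(preset, **(raw.get("cohort") or {}))
        for section in ("panel", "preprocess", "dge"):
            defaults = getattr(cfg, section)
            extra = raw.get(section) or {}
            bad = set(extra) - set(defaults)
            if bad:
                raise ConfigError(f"unknown {section} keys: {sorted(bad)}")
            defaults.update(extra)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        out = asdict(self)
        return out
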