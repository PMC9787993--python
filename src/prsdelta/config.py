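"""Configuration objects for simulation and pipeline runs.

``SimulationConfig`` fully determines a synthetic cohort: the SNP panel
(sizes, allele frequencies, per-allele weights), the phenotype model
(baseline sampling ranges, per-SD polygenic effects on trait changes,
covariate effects, residual noise) and a single integer seed from which
all random streams are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError
from .traits import (
    TRAITS,
    DEFAULT_BASELINE_RANGES,
    DEFAULT_NOISE_SD,
)


@dataclass
class SnpSpec:
    """Explicit specification of one simulated SNP.

    ``beta_t2d`` / ``beta_obesity`` are per-allele log odds ratios for the
    effect allele; ``None`` means the SNP does not enter that score.
    """

    rsid: str
    maf: float
    beta_t2d: float | None = None
    beta_obesity: float | None = None


@dataclass
class SimulationConfig:
    """Parameters of the synthetic prediabetic cohort generator."""

    n_individuals: int = 446
    n_t2d_snps: int = 68
    n_obesity_snps: int = 21
    n_overlap_snps: int = 20
    #: Optional explicit SNP panel; when ``None`` a panel is drawn from
    #: ``maf_range`` / ``beta_range``.
    snp_specs: list[SnpSpec] | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: |log OR| magnitudes drawn uniformly from this interval, positive
    #: for the risk (effect) allele.
    beta_range: tuple[float, float] = (0.01, 0.15)
    #: Which standardized score drives the injected trait effects.
    effect_score: str = "t2d"
    #: Per-trait slope of the trait *change* on the standardized PRS
    #: (trait units per SD); traits absent from the map get 0.
    trait_effects: dict[str, float] = field(default_factory=dict)
    #: Per-trait slope of the *baseline* trait on the standardized PRS.
    baseline_effects: dict[str, float] = field(default_factory=dict)
    #: Per-trait constant offset added to every change (secular drift).
    trait_shifts: dict[str, float] = field(default_factory=dict)
    #: Per-trait covariate slopes on the change: trait -> {age, sex, bmi}.
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    #: Residual SD of the change; a float applies to every trait,
    #: a mapping overrides per trait.
    noise_sd: float | dict[str, float] = DEFAULT_NOISE_SD
    missing_rate: float = 0.0
    #: Fraction of individuals sampled inside the prediabetic glycemic
    #: ranges; the remainder is sampled just below the thresholds.
    prediabetic_fraction: float = 0.9
    baseline_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RANGES)
    )
    sex_female_prob: float = 0.549
    age_range: tuple[float, float] = (30.33, 55.73)
    seed: int = 0

    # -- validation -----------------------------------------------------

    def validate(self) -> "SimulationConfig":
        if self.n_individuals < 1:
            raise ConfigError("n_individuals", "must be >= 1")
        for name in ("n_t2d_snps", "n_obesity_snps", "n_overlap_snps"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")
        if self.n_overlap_snps > min(self.n_t2d_snps, self.n_obesity_snps):
            raise ConfigError(
                "n_overlap_snps",
                "cannot exceed min(n_t2d_snps, n_obesity_snps)",
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("maf_range", "frequencies must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate", "must lie in [0, 1)")
        if not (0.0 <= self.prediabetic_fraction <= 1.0):
            raise ConfigError("prediabetic_fraction", "must lie in [0, 1]")
        if not (0.0 <= self.sex_female_prob <= 1.0):
            raise ConfigError("sex_female_prob", "must lie in [0, 1]")
        if self.effect_score not in ("t2d", "obesity"):
            raise ConfigError("effect_score", "must be 't2d' or 'obesity'")
        for trait, sd in self._noise_map().items():
            if sd < 0:
                raise ConfigError("noise_sd", f"negative SD for trait {trait}")
        for trait in list(self.trait_effects) + list(self.trait_shifts) + list(
            self.baseline_effects
        ):
            if trait not in TRAITS:
                raise ConfigError("trait_effects", f"unknown trait {trait!r}")
        if self.snp_specs is not None:
            seen = set()
            for s in self.snp_specs:
                if not (0.0 < s.maf < 1.0):
                    raise ConfigError("snp_specs", f"{s.rsid}: maf outside (0, 1)")
                if s.rsid in seen:
                    raise ConfigError("snp_specs", f"duplicate rsid {s.rsid}")
                seen.add(s.rsid)
        return self

    # -- helpers --------------------------------------------------------

    def _noise_map(self) -> dict[str, float]:
        if isinstance(self.noise_sd, Mapping):
            out = {t: DEFAULT_NOISE_SD for t in TRAITS}
            out.update(self.noise_sd)
            return out
        return {t: float(self.noise_sd) for t in TRAITS}

    def noise_for(self, trait: str) -> float:
        return self._noise_map()[trait]

    def effect_for(self, trait: str) -> float:
        return float(self.trait_effects.get(trait, 0.0))

    def shift_for(self, trait: str) -> float:
        return float(self.trait_shifts.get(trait, 0.0))

    def baseline_effect_for(self, trait: str) -> float:
        return float(self.baseline_effects.get(trait, 0.0))

    def covariate_for(self, trait: str) -> dict[str, float]:
        base = {"age": 0.0, "sex": 0.0, "bmi": 0.0}
        base.update(self.covariate_effects.get(trait, {}))
        return base

    # -- (de)serialization ----------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        if self.snp_specs is not None:
            data["snp_specs"] = [asdict(s) for s in self.snp_specs]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if data.get("snp_specs") is not None:
            data["snp_specs"] = [SnpSpec(**s) for s in data["snp_specs"]]
        for key in ("maf_range", "beta_range", "age_range"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        if "baseline_ranges" in data and data["baseline_ranges"] is not None:
            data["baseline_ranges"] = {
                k: tuple(v) for k, v in data["baseline_ranges"].items()
            }
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown field")
        return cls(**data).validate()
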