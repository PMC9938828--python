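"""Configuration registry.

Holds the per-metal regulatory and toxicological constants (permissible
standards S_i per agency, ideal values I_i, reference dose RfD or tolerable
daily intake TDI, carcinogenic slope factor SF), the receptor exposure
profiles used by the ingestion-dose equation, and the study design (seasonal
concentration moments) that drives both the synthetic generator and the
mean-based reports.

Defaults ship in ``ptew/data/defaults.yaml``; other agencies, metals or
populations are drop-in through a user YAML file with the same layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError

SEASONS = ("winter", "summer")


@dataclass(frozen=True)
class MetalSpec:
    """Regulatory and toxicological constants for one metal.

    ``standards`` maps agency name (e.g. ``"EPA"``) to the permissible
    concentration S_i in µg/L. ``ideal`` is the desirable concentration I_i
    used as the reference point of the pollution sub-index. Exactly one of
    ``rfd``/``tdi`` (mg/kg/day) may be set; ``sf`` ((mg/kg/day)^-1) is only
    present for carcinogens.
    """

    name: str
    standards: Mapping[str, float]
    ideal: float = 0.0
    rfd: float | None = None
    tdi: float | None = None
    sf: float | None = None

    def __post_init__(self) -> None:
        if not self.standards:
            raise ConfigError(f"{self.name}: at least one agency standard is required")
        for agency, s in self.standards.items():
            if not (math.isfinite(s) and s > 0):
                raise ConfigError(f"{self.name}: standard for {agency} must be > 0, got {s}")
            if s == self.ideal:
                raise ConfigError(
                    f"{self.name}: ideal value equals the {agency} standard; "
                    "the sub-index denominator would vanish"
                )
        if self.rfd is not None and self.tdi is not None:
            raise ConfigError(f"{self.name}: give either rfd or tdi, not both")
        for label, v in (("rfd", self.rfd), ("tdi", self.tdi), ("sf", self.sf)):
            if v is not None and not (math.isfinite(v) and v > 0):
                raise ConfigError(f"{self.name}: {label} must be > 0, got {v}")

    @property
    def reference_dose(self) -> float:
        """RfD if present, else TDI (the hazard-quotient denominator)."""
        if self.rfd is not None:
            return self.rfd
        if self.tdi is not None:
            return self.tdi
        raise ConfigError(f"{self.name}: neither rfd nor tdi is configured")

    @property
    def has_reference_dose(self) -> bool:
        return self.rfd is not None or self.tdi is not None


@dataclass(frozen=True)
class ExposureProfile:
    """Receptor-group parameters of the chronic-daily-intake equation.

    ``ir`` L/day, ``ef_*`` days/year (triangular min/mode/max), ``ed`` years,
    ``bw`` kg, ``f`` the µg→mg conversion (1000), ``lifetime_years`` the
    carcinogenic averaging lifetime.
    """

    group: str
    ir: float
    ef_min: float
    ef_mode: float
    ef_max: float
    ed: float
    bw: float
    f: float = 1000.0
    lifetime_years: float = 70.0

    def __post_init__(self) -> None:
        if not (0 < self.ef_min <= self.ef_mode <= self.ef_max <= 365):
            raise ConfigError(
                f"{self.group}: exposure frequency must satisfy "
                f"0 < min <= mode <= max <= 365, got "
                f"({self.ef_min}, {self.ef_mode}, {self.ef_max})"
            )
        for label in ("ir", "ed", "bw", "f", "lifetime_years"):
            v = getattr(self, label)
            if not (math.isfinite(v) and v > 0):
                raise ConfigError(f"{self.group}: {label} must be > 0, got {v}")


@dataclass(frozen=True)
class SeasonMoments:
    """Arithmetic mean/sd (µg/L) and observed range of one metal in one season."""

    mean: float
    sd: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean) and self.mean > 0):
            raise ConfigError(f"mean must be > 0, got {self.mean}")
        if not (math.isfinite(self.sd) and self.sd >= 0):
            raise ConfigError(f"sd must be >= 0, got {self.sd}")
        if self.low is not None and self.high is not None:
            if not (self.low <= self.mean <= self.high):
                raise ConfigError(
                    f"mean {self.mean} outside the stated range [{self.low}, {self.high}]"
                )


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: per-metal, per-season concentration moments."""

    n_per_season: int
    concentrations: Mapping[str, Mapping[str, SeasonMoments]]

    def __post_init__(self) -> None:
        if self.n_per_season < 1:
            raise ConfigError("n_per_season must be >= 1")
        for metal, by_season in self.concentrations.items():
            missing = set(SEASONS) - set(by_season)
            if missing:
                raise ConfigError(f"{metal}: missing seasons {sorted(missing)}")

    def mean_concentrations(self, season: str) -> dict[str, float]:
        """Seasonal mean concentration (µg/L) per metal."""
        return {m: by[season].mean for m, by in self.concentrations.items()}


@dataclass(frozen=True)
class MCSAssumptions:
    """Spread assumptions for inputs whose distribution family alone is known."""

    ir_cv: float = 0.20
    bw_cv: float = 0.20


@dataclass(frozen=True)
class Config:
    version: int
    metals: Mapping[str, MetalSpec]
    profiles: Mapping[str, ExposureProfile]
    study: StudyDesign
    mcs: MCSAssumptions = field(default_factory=MCSAssumptions)


def default_config_path() -> Path:
    return Path(str(resources.files("ptew") / "data" / "defaults.yaml"))


def load_config(path: str | Path | None = None) -> Config:
    """Load a configuration YAML; with no argument, the packaged defaults."""
    path = default_config_path() if path is None else Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        metals = {
            name: MetalSpec(name=name, **entry) for name, entry in raw["metals"].items()
        }
        profiles = {}
        for group, entry in raw["profiles"].items():
            ef = entry.pop("ef")
            profiles[group] = ExposureProfile(
                group=group,
                ef_min=float(ef["min"]),
                ef_mode=float(ef["mode"]),
                ef_max=float(ef["max"]),
                **{k: float(v) for k, v in entry.items()},
            )
        conc = {
            metal: {season: SeasonMoments(**m) for season, m in by_season.items()}
            for metal, by_season in raw["study"]["concentrations"].items()
        }
        study = StudyDesign(
            n_per_season=int(raw["study"]["n_per_season"]), concentrations=conc
        )
        mcs = MCSAssumptions(**raw.get("mcs", {}))
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed configuration {path}: {exc}") from exc
    return Config(
        version=int(raw.get("version", 1)),
        metals=metals,
        profiles=profiles,
        study=study,
        mcs=mcs,
    )
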