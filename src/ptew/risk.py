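"""Deterministic ingestion health-risk assessment.

Chronic daily intake through drinking water:

    CDI = C · IR · EF · ED / (f · BW · AT)      [mg/kg/day]

with C in µg/L, IR in L/day, EF in days/year, ED in years, f = 1000 the
µg→mg conversion, BW in kg, and the averaging time AT = ED·365 days for the
noncarcinogenic endpoint (so ED cancels) or lifetime·365 days for the
carcinogenic endpoint. HQ = CDI / (RfD or TDI), HI = Σ HQ, CR = CDI · SF.

Point estimates use EF at the mode of its triangular distribution
(345 days/year) unless another value is passed explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .config import ExposureProfile, MetalSpec
from .errors import ConfigError, NoDataError, ValidationError

NONCARCINOGENIC = "noncarcinogenic"
CARCINOGENIC = "carcinogenic"

#: USEPA lifetime excess cancer-risk bands; both edges of the threshold band
#: are inclusive.
CR_NEGLIGIBLE_BELOW = 1e-6
CR_POTENT_ABOVE = 1e-4


def cdi(
    concentration: float,
    profile: ExposureProfile,
    endpoint: str = NONCARCINOGENIC,
    ef: float | None = None,
) -> float:
    """Chronic daily intake (mg/kg/day) for one concentration (µg/L)."""
    if concentration < 0:
        raise ValidationError(f"concentration must be >= 0, got {concentration}")
    if ef is None:
        ef = profile.ef_mode
    if not (profile.ef_min <= ef <= profile.ef_max):
        raise ValidationError(
            f"EF {ef} outside the profile range [{profile.ef_min}, {profile.ef_max}]"
        )
    if endpoint == NONCARCINOGENIC:
        at_days = profile.ed * 365.0
    elif endpoint == CARCINOGENIC:
        if profile.lifetime_years <= 0:
            raise ConfigError("carcinogenic endpoint requires lifetime_years > 0")
        at_days = profile.lifetime_years * 365.0
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    return (
        concentration
        * profile.ir
        * ef
        * profile.ed
        / (profile.f * profile.bw * at_days)
    )


def hq(cdi_value: float, spec: MetalSpec) -> float:
    """Hazard quotient CDI / (RfD or TDI)."""
    if cdi_value < 0:
        raise ValidationError(f"CDI must be >= 0, got {cdi_value}")
    if not spec.has_reference_dose:
        raise ConfigError(f"{spec.name}: no RfD or TDI configured, HQ undefined")
    return cdi_value / spec.reference_dose


def hi(hqs: Mapping[str, float] | Iterable[float]) -> float:
    """Hazard index, the sum of hazard quotients."""
    values = list(hqs.values()) if isinstance(hqs, Mapping) else list(hqs)
    if not values:
        raise NoDataError("hazard index is undefined for an empty HQ set")
    return math.fsum(values)


def cr(cdi_carcinogenic: float, sf: float) -> float:
    """Lifetime excess cancer risk CDI · SF (dimensionless probability)."""
    if not sf > 0:
        raise ConfigError(f"slope factor must be > 0, got {sf}")
    if cdi_carcinogenic < 0:
        raise ValidationError(f"CDI must be >= 0, got {cdi_carcinogenic}")
    return cdi_carcinogenic * sf


def classify_hq(value: float) -> str:
    """``acceptable`` (≤1) vs ``unacceptable`` noncarcinogenic risk."""
    if value < 0:
        raise ValidationError(f"HQ must be >= 0, got {value}")
    return "acceptable" if value <= 1.0 else "unacceptable"


classify_hi = classify_hq


def classify_cr(value: float) -> str:
    """``negligible`` (<1e-6), ``threshold`` (1e-6..1e-4) or ``potent`` (>1e-4)."""
    if value < 0:
        raise ValidationError(f"CR must be >= 0, got {value}")
    if value < CR_NEGLIGIBLE_BELOW:
        return "negligible"
    if value <= CR_POTENT_ABOVE:
        return "threshold"
    return "potent"


@dataclass(frozen=True)
class RiskResult:
    """Deterministic risk chain for one receptor group in one season."""

    group: str
    season: str | None
    cdi: Mapping[str, float]
    hq: Mapping[str, float]
    hi: float
    cr: Mapping[str, float]
    hq_class: Mapping[str, str]
    hi_class: str
    cr_class: Mapping[str, str]


def risk_report(
    mean_concentrations: Mapping[str, float],
    metals: Mapping[str, MetalSpec],
    profile: ExposureProfile,
    season: str | None = None,
    ef: float | None = None,
) -> RiskResult:
    """CDI/HQ per metal, HI, and CR for slope-factor metals, at mean C."""
    cdis = {
        m: cdi(c, profile, NONCARCINOGENIC, ef=ef)
        for m, c in mean_concentrations.items()
    }
    hqs = {m: hq(v, metals[m]) for m, v in cdis.items() if metals[m].has_reference_dose}
    crs = {
        m: cr(cdi(c, profile, CARCINOGENIC, ef=ef), metals[m].sf)
        for m, c in mean_concentrations.items()
        if metals[m].sf is not None
    }
    hi_value = hi(hqs)
    return RiskResult(
        group=profile.group,
        season=season,
        cdi=cdis,
        hq=hqs,
        hi=hi_value,
        cr=crs,
        hq_class={m: classify_hq(v) for m, v in hqs.items()},
        hi_class=classify_hi(hi_value),
        cr_class={m: classify_cr(v) for m, v in crs.items()},
    )
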