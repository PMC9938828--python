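"""Water-quality contamination indices.

Implements the contamination factor Cf_i = M_i/S_i − 1, the degree of
contamination C_d = Σ Cf_i, the unit weight W_i = k/S_i, the sub-index
Q_i = |M_i − I_i| / |S_i − I_i| × 100, and the heavy-metal pollution index
HPI = Σ W_i Q_i / Σ W_i, together with their classification bands.

Q_i uses absolute differences in both numerator and denominator, so a metal
whose ideal value exceeds its standard (Mn here: I=100 > S=50 µg/L) is
well-defined.

Two HPI rounding modes are provided. ``"full"`` keeps full precision and is
the default for new analyses. ``"table2"`` reproduces the arithmetic of a
tabulated report in which weights are truncated at 4 decimals, Q_i and the
products W_iQ_i are rounded at 2 decimals, and the two column sums are
rounded (numerator) / truncated (denominator) at 2 decimals before the final
division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .config import MetalSpec
from .errors import NoDataError, ValidationError

#: (upper bound, label); a value on a bound takes the label whose band it opens
CD_BANDS: tuple[tuple[float, str], ...] = (
    (1.0, "significantly_low"),
    (3.0, "moderate"),
    (math.inf, "high"),
)

HPI_BANDS: tuple[tuple[float, str], ...] = (
    (50.0, "excellent"),
    (100.0, "good"),
    (200.0, "poor"),
    (300.0, "very_poor"),
    (math.inf, "unsuitable"),
)


def contamination_factor(concentration: float, standard: float) -> float:
    """Cf_i = M_i/S_i − 1; negative whenever the water is below standard."""
    if not standard > 0:
        raise ValidationError(f"standard must be > 0, got {standard}")
    if concentration < 0:
        raise ValidationError(f"concentration must be >= 0, got {concentration}")
    return concentration / standard - 1.0


def degree_of_contamination(cfs: Iterable[float]) -> float:
    """C_d = Σ Cf_i (exact, order-independent compensated sum)."""
    cfs = list(cfs)
    if not cfs:
        raise NoDataError("degree of contamination is undefined for an empty set")
    return math.fsum(cfs)


def unit_weight(standard: float, k: float = 1.0) -> float:
    """W_i = k/S_i; with k = 1 and standards ≥ 1 µg/L this lies in (0, 1]."""
    if not standard > 0:
        raise ValidationError(f"standard must be > 0, got {standard}")
    if not k > 0:
        raise ValidationError(f"k must be > 0, got {k}")
    return k / standard


def sub_index(concentration: float, standard: float, ideal: float = 0.0) -> float:
    """Q_i = |M_i − I_i| / |S_i − I_i| × 100."""
    if standard == ideal:
        raise ValidationError(
            f"standard ({standard}) equals ideal ({ideal}); sub-index undefined"
        )
    if concentration < 0:
        raise ValidationError(f"concentration must be >= 0, got {concentration}")
    return abs(concentration - ideal) / abs(standard - ideal) * 100.0


def _truncate(value: float, decimals: int) -> float:
    scale = 10.0**decimals
    return math.floor(value * scale) / scale


def hpi(
    weights: Mapping[str, float],
    subindices: Mapping[str, float],
    rounding: str = "full",
) -> float:
    """Weighted arithmetic mean Σ W_i Q_i / Σ W_i over a common metal set."""
    if set(weights) != set(subindices):
        diff = set(weights).symmetric_difference(subindices)
        raise ValidationError(f"weight/sub-index metal sets differ: {sorted(diff)}")
    if not weights:
        raise NoDataError("HPI is undefined for an empty metal set")
    if rounding == "full":
        num = math.fsum(weights[m] * subindices[m] for m in weights)
        den = math.fsum(weights.values())
    elif rounding == "table2":
        w4 = {m: _truncate(w, 4) for m, w in weights.items()}
        q2 = {m: round(q, 2) for m, q in subindices.items()}
        num = round(math.fsum(round(w4[m] * q2[m], 2) for m in weights), 2)
        den = _truncate(math.fsum(w4.values()), 2)
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    if not den > 0:
        raise ValidationError("sum of weights must be > 0")
    return num / den


def _classify(value: float, bands: Sequence[tuple[float, str]]) -> str:
    for upper, label in bands:
        if value < upper:
            return label
    return bands[-1][1]


def classify_cd(cd: float, bands: Sequence[tuple[float, str]] = CD_BANDS) -> str:
    """Contamination class; boundary values take the lower-severity class."""
    if not math.isfinite(cd):
        raise ValidationError(f"C_d must be finite, got {cd}")
    # boundaries belong to the band below (C_d = 1 -> significantly_low)
    for upper, label in bands:
        if cd <= upper:
            return label
    return bands[-1][1]


def classify_hpi(value: float, bands: Sequence[tuple[float, str]] = HPI_BANDS) -> str:
    """Water-quality class; a boundary opens its band (HPI = 50 → good)."""
    if value < 0:
        raise ValidationError(f"HPI must be >= 0, got {value}")
    return _classify(value, bands)


@dataclass(frozen=True)
class IndexResult:
    """All indices for one (agency, season) evaluated at mean concentrations."""

    agency: str
    season: str | None
    cf: Mapping[str, float]
    cd: float
    w: Mapping[str, float]
    q: Mapping[str, float]
    hpi: float
    hpi_full: float
    cd_class: str
    hpi_class: str


def index_report(
    mean_concentrations: Mapping[str, float],
    metals: Mapping[str, MetalSpec],
    agency: str,
    season: str | None = None,
    k: float = 1.0,
    rounding: str = "full",
) -> IndexResult:
    """Compute Cf/C_d/W/Q/HPI for one agency from mean concentrations (µg/L)."""
    missing = set(mean_concentrations) - set(metals)
    if missing:
        raise ValidationError(f"metals without a configured spec: {sorted(missing)}")
    cf = {
        m: contamination_factor(c, metals[m].standards[agency])
        for m, c in mean_concentrations.items()
    }
    cd = degree_of_contamination(cf.values())
    w = {m: unit_weight(metals[m].standards[agency], k) for m in mean_concentrations}
    q = {
        m: sub_index(c, metals[m].standards[agency], metals[m].ideal)
        for m, c in mean_concentrations.items()
    }
    value = hpi(w, q, rounding=rounding)
    full = value if rounding == "full" else hpi(w, q, rounding="full")
    return IndexResult(
        agency=agency,
        season=season,
        cf=cf,
        cd=cd,
        w=w,
        q=q,
        hpi=value,
        hpi_full=full,
        cd_class=classify_cd(cd),
        hpi_class=classify_hpi(value),
    )
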