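"""Water-sample records and their CSV I/O.

One :class:`WaterSample` is a single site×season record of per-metal
concentrations in µg/L. The canonical on-disk format is CSV, either *wide*
(one column per metal) or *long* (``metal``/``concentration`` columns); the
reader detects which. All concentrations are µg/L externally and internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SEASONS
from .errors import NoDataError, SchemaError, ValidationError

_META_COLUMNS = ("site", "season", "latitude", "longitude")


@dataclass
class WaterSample:
    """One site×season record of per-metal concentrations (µg/L)."""

    site_id: str
    season: str
    concentrations: dict[str, float]
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValidationError(
                f"site {self.site_id}: season must be one of {SEASONS}, got {self.season!r}"
            )
        for metal, c in self.concentrations.items():
            if not (isinstance(c, (int, float)) and math.isfinite(c) and c >= 0):
                raise ValidationError(
                    f"site {self.site_id}: {metal} concentration must be finite and >= 0, got {c!r}"
                )


@dataclass(frozen=True)
class SeasonSummary:
    """Descriptive statistics of one metal in one season (µg/L)."""

    metal: str
    season: str
    n: int
    min: float
    max: float
    mean: float
    sd: float


def read_samples(
    path: str | Path, metals: Sequence[str] | None = None
) -> list[WaterSample]:
    """Read water samples from a wide or long CSV.

    Wide format: columns ``site, season[, latitude, longitude], <metal>...``.
    Long format: columns ``site, season, metal, concentration``.
    Unparseable or negative concentration cells are reported (all of them,
    with row numbers), never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"samples file not found: {path}")
    df = pd.read_csv(
        path, dtype={"site": str, "season": str}, float_precision="round_trip"
    )
    for required in ("site", "season"):
        if required not in df.columns:
            raise SchemaError(f"{path}: missing required column '{required}'")
    if {"metal", "concentration"}.issubset(df.columns):
        df = _long_to_wide(df)
    metal_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if metals is not None:
        unknown = set(metal_cols) - set(metals)
        if unknown:
            raise SchemaError(
                f"{path}: metal columns {sorted(unknown)} are not in the configured registry"
            )
    if not metal_cols:
        raise SchemaError(f"{path}: no metal columns found")

    problems: list[str] = []
    samples: list[WaterSample] = []
    for idx, row in df.iterrows():
        conc: dict[str, float] = {}
        for m in metal_cols:
            value = pd.to_numeric(pd.Series([row[m]]), errors="coerce").iloc[0]
            if pd.isna(value):
                problems.append(f"row {idx}: unparseable {m} value {row[m]!r}")
                continue
            if value < 0:
                problems.append(f"row {idx}: negative {m} concentration {value}")
                continue
            conc[m] = float(value)
        season = str(row["season"]).strip().lower()
        if season not in SEASONS:
            problems.append(f"row {idx}: season must be one of {SEASONS}, got {row['season']!r}")
            continue
        if len(conc) == len(metal_cols):
            samples.append(
                WaterSample(
                    site_id=str(row["site"]),
                    season=season,
                    concentrations=conc,
                    latitude=_optional_float(row, "latitude"),
                    longitude=_optional_float(row, "longitude"),
                )
            )
    if problems:
        raise ValidationError(f"{path}: invalid cells:\n  " + "\n  ".join(problems))
    return samples


def _optional_float(row: pd.Series, column: str) -> float | None:
    if column in row.index and pd.notna(row[column]):
        return float(row[column])
    return None


def _long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    index = [c for c in _META_COLUMNS if c in df.columns]
    wide = df.pivot_table(
        index=index, columns="metal", values="concentration", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    return wide


def write_samples(samples: Iterable[WaterSample], path: str | Path) -> Path:
    """Write samples as a wide CSV that round-trips through :func:`read_samples`."""
    samples = list(samples)
    if not samples:
        raise NoDataError("nothing to write: empty sample collection")
    metals = list(samples[0].concentrations)
    has_coords = any(s.latitude is not None for s in samples)
    rows = []
    for s in samples:
        row: dict[str, object] = {"site": s.site_id, "season": s.season}
        if has_coords:
            row["latitude"] = s.latitude
            row["longitude"] = s.longitude
        row.update({m: s.concentrations[m] for m in metals})
        rows.append(row)
    path = Path(path)
    # %.17g guarantees float64 values survive the text round-trip bit-exactly
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def concentration_values(
    samples: Iterable[WaterSample], metal: str, season: str | None = None
) -> np.ndarray:
    """Concentrations of one metal, optionally restricted to one season."""
    values = [
        s.concentrations[metal]
        for s in samples
        if metal in s.concentrations and (season is None or s.season == season)
    ]
    return np.asarray(values, dtype=float)


def summarize(
    samples: Iterable[WaterSample], metal: str, season: str
) -> SeasonSummary:
    """Min/max/mean/sample-sd of one metal in one season.

    The standard deviation uses the n−1 denominator; a single observation has
    sd defined as 0 (with a warning).
    """
    values = concentration_values(samples, metal, season)
    if values.size == 0:
        raise NoDataError(f"no data for metal {metal!r} in season {season!r}")
    if values.size == 1:
        warnings.warn(
            f"{metal}/{season}: single observation, sd reported as 0", stacklevel=2
        )
        sd = 0.0
    else:
        sd = float(np.std(values, ddof=1))
    return SeasonSummary(
        metal=metal,
        season=season,
        n=int(values.size),
        min=float(values.min()),
        max=float(values.max()),
        mean=float(values.mean()),
        sd=sd,
    )


def season_mean_concentrations(
    samples: Iterable[WaterSample], season: str, metals: Sequence[str] | None = None
) -> dict[str, float]:
    """Seasonal mean concentration per metal, the input of the index/risk reports."""
    samples = list(samples)
    if metals is None:
        metals = sorted({m for s in samples for m in s.concentrations})
    return {m: summarize(samples, m, season).mean for m in metals}
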