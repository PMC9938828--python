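"""Synthetic sample generator.

Emulates the study design: 45 winter + 45 summer tap-water samples per metal,
drawn from lognormal distributions moment-matched to the seasonal means and
standard deviations of the survey (lognormal because that is the family the
uncertainty analysis itself assigns to concentrations). Metals are drawn
independently by default; :func:`inject_correlation` retrofits a target
Spearman correlation between two metals through a Gaussian-copula rank
coupling that leaves every marginal multiset untouched.

Optional rejection-truncation to the observed ranges is available but off by
default, since truncation biases the moments the generator is asked to hit.
Site identifiers and jittered coordinates are cosmetic.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import SEASONS, SeasonMoments, load_config
from .errors import ConfigError, ValidationError
from .mcs import lognormal_parameters
from .samples import WaterSample

_MAX_REJECTION_ROUNDS = 1000

#: rough bounding box around the study city, decimal degrees (cosmetic only)
DEFAULT_BBOX = (29.55, 29.75, 52.45, 52.60)


def _default_moments() -> dict[str, dict[str, SeasonMoments]]:
    return {
        m: dict(by) for m, by in load_config().study.concentrations.items()
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Per-metal seasonal moments, sample size, seed and truncation switch."""

    moments: Mapping[str, Mapping[str, SeasonMoments]] = field(
        default_factory=_default_moments
    )
    n_per_season: int = 45
    seed: int = 0
    truncate: bool = False
    site_prefix: str = "site"
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX

    def __post_init__(self) -> None:
        if self.n_per_season < 1:
            raise ConfigError("n_per_season must be >= 1")


def _child(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


def _draw_metal(
    moments: SeasonMoments, n: int, rng: np.random.Generator, truncate: bool
) -> np.ndarray:
    if moments.sd == 0:
        return np.full(n, moments.mean)
    mu, sigma = lognormal_parameters(moments.mean, moments.sd)
    draws = rng.lognormal(mu, sigma, size=n)
    if truncate and moments.low is not None and moments.high is not None:
        for _ in range(_MAX_REJECTION_ROUNDS):
            bad = (draws < moments.low) | (draws > moments.high)
            if not bad.any():
                break
            draws[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
        else:
            raise ConfigError(
                f"truncation range [{moments.low}, {moments.high}] rejects "
                "nearly all of the distribution's mass"
            )
    return draws


def generate(config: GeneratorConfig | None = None) -> list[WaterSample]:
    """Generate ``n_per_season`` samples per season; deterministic under seed.

    Each metal×season pair has its own child random stream, so adding a metal
    to the configuration does not perturb the draws of the others.
    """
    config = config or GeneratorConfig()
    n = config.n_per_season
    draws: dict[tuple[str, str], np.ndarray] = {}
    for metal, by_season in config.moments.items():
        for season in SEASONS:
            draws[(metal, season)] = _draw_metal(
                by_season[season],
                n,
                _child(config.seed, f"{metal}:{season}"),
                config.truncate,
            )
    coords_rng = _child(config.seed, "coordinates")
    lat_lo, lat_hi, lon_lo, lon_hi = config.bbox
    lats = coords_rng.uniform(lat_lo, lat_hi, size=n)
    lons = coords_rng.uniform(lon_lo, lon_hi, size=n)
    width = len(str(n))
    samples = []
    for season in SEASONS:
        for i in range(n):
            samples.append(
                WaterSample(
                    site_id=f"{config.site_prefix}-{i + 1:0{width}d}",
                    season=season,
                    concentrations={
                        metal: float(draws[(metal, season)][i])
                        for metal in config.moments
                    },
                    latitude=float(lats[i]),
                    longitude=float(lons[i]),
                )
            )
    return samples


def inject_correlation(
    samples: Sequence[WaterSample],
    season: str,
    pair: tuple[str, str],
    rho_target: float,
    seed: int = 0,
) -> list[WaterSample]:
    """Reorder one metal's seasonal values toward a target Spearman ρ.

    The second metal of ``pair`` is permuted via a Gaussian-copula rank
    coupling (Pearson latent correlation 2·sin(πρ/6)), so the realised
    Spearman correlation approaches ``rho_target`` while the marginal
    multiset of values is exactly preserved. ρ = ±1 uses the exact
    co-/antimonotone rearrangement.
    """
    if not -1.0 <= rho_target <= 1.0:
        raise ValidationError(f"|rho_target| must be <= 1, got {rho_target}")
    anchor, moved = pair
    idx = [i for i, s in enumerate(samples) if s.season == season]
    if len(idx) < 5:
        raise ValidationError(
            f"need at least 5 samples in {season!r} to steer a correlation, got {len(idx)}"
        )
    x = np.array([samples[i].concentrations[anchor] for i in idx])
    y = np.array([samples[i].concentrations[moved] for i in idx])
    n = len(idx)
    # rank of x per position, ties broken deterministically by position
    rank_x = np.empty(n, dtype=int)
    rank_x[np.argsort(x, kind="stable")] = np.arange(n)
    y_sorted = np.sort(y)
    if abs(rho_target) == 1.0:
        target_rank = rank_x if rho_target > 0 else n - 1 - rank_x
        y_new = y_sorted[target_rank]
    else:
        rng = _child(seed, f"copula:{season}:{anchor}:{moved}")
        latent = 2.0 * np.sin(np.pi * rho_target / 6.0)
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        v = latent * z1 + np.sqrt(1.0 - latent**2) * z2
        # align the latent pair's first coordinate with x's ranks, then give
        # y the ranks of the second coordinate
        v_by_u = v[np.argsort(z1, kind="stable")]
        v_aligned = v_by_u[rank_x]
        rank_v = np.empty(n, dtype=int)
        rank_v[np.argsort(v_aligned, kind="stable")] = np.arange(n)
        y_new = y_sorted[rank_v]
    out = [
        WaterSample(
            site_id=s.site_id,
            season=s.season,
            concentrations=dict(s.concentrations),
            latitude=s.latitude,
            longitude=s.longitude,
        )
        for s in samples
    ]
    for pos, i in enumerate(idx):
        out[i].concentrations[moved] = float(y_new[pos])
    return out
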