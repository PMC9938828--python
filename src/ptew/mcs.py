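"""Monte Carlo uncertainty propagation of HI and CR.

Each stochastic input (per-metal concentration, intake rate, exposure
frequency, body weight, and the fixed constants ED, AT, RfD, SF) is described
by a :class:`DistributionSpec`. The engine draws every input independently
from its own child random stream (derived from one root seed and the input's
name, so adding an input never perturbs the others' draws), pushes the draws
through the CDI→HQ→HI or CDI→CR chain, and reports the mean, requested
percentiles, and a signed contribution-to-variance sensitivity measure.

Sensitivity follows the rank-correlation convention: for each varying input
j, the Spearman correlation ρ_j with the output is computed and the signed
contribution is sign(ρ_j)·ρ_j²/Σ_k ρ_k² × 100; inputs held fixed contribute
exactly 0.

Lognormal draws are parameterised by moment matching, so their *arithmetic*
mean and sd converge to the spec's values: σ² = ln(1 + (s/m)²),
µ = ln m − σ²/2.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .config import Config, ExposureProfile, MetalSpec, SEASONS
from .errors import ConfigError, NoDataError, ValidationError

FAMILIES = ("fixed", "normal", "lognormal", "triangular", "mixture")

_MAX_REJECTION_ROUNDS = 100


@dataclass(frozen=True)
class DistributionSpec:
    """A named stochastic (or fixed) model input.

    Families and their ``params``:

    - ``fixed``: ``value``
    - ``normal``: ``mean``, ``sd``, optional ``low`` (truncation by rejection)
    - ``lognormal``: arithmetic ``mean`` and ``sd`` (moment-matched)
    - ``triangular``: ``low``, ``mode``, ``high`` (inverse-CDF sampling)
    - ``mixture``: ``components`` (list of DistributionSpec), optional
      ``weights`` (default equal) — used for season-pooled concentrations
    """

    name: str
    family: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"{self.name}: unknown family {self.family!r}")
        p = self.params
        if self.family == "fixed" and "value" not in p:
            raise ConfigError(f"{self.name}: fixed spec needs a value")
        if self.family in ("normal", "lognormal"):
            mean, sd = p.get("mean"), p.get("sd")
            if mean is None or sd is None:
                raise ConfigError(f"{self.name}: {self.family} spec needs mean and sd")
            if sd < 0:
                raise ConfigError(f"{self.name}: sd must be >= 0, got {sd}")
            if self.family == "lognormal" and not mean > 0:
                raise ConfigError(f"{self.name}: lognormal mean must be > 0, got {mean}")
        if self.family == "triangular":
            low, mode, high = p.get("low"), p.get("mode"), p.get("high")
            if low is None or mode is None or high is None:
                raise ConfigError(f"{self.name}: triangular spec needs low/mode/high")
            if not (low <= mode <= high):
                raise ConfigError(
                    f"{self.name}: triangular requires low <= mode <= high, "
                    f"got ({low}, {mode}, {high})"
                )
        if self.family == "mixture":
            comps = p.get("components")
            if not comps:
                raise ConfigError(f"{self.name}: mixture spec needs components")

    @property
    def is_fixed(self) -> bool:
        if self.family == "fixed":
            return True
        if self.family in ("normal", "lognormal"):
            return self.params["sd"] == 0
        if self.family == "triangular":
            return self.params["low"] == self.params["high"]
        return False


def lognormal_parameters(mean: float, sd: float) -> tuple[float, float]:
    """(µ, σ) of the underlying normal matching an arithmetic mean/sd."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` independent values from one input distribution."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    p = spec.params
    if spec.family == "fixed":
        return np.full(n, float(p["value"]))
    if spec.family == "normal":
        mean, sd = float(p["mean"]), float(p["sd"])
        if sd == 0:
            return np.full(n, mean)
        draws = rng.normal(mean, sd, size=n)
        low = p.get("low")
        if low is not None:
            for _ in range(_MAX_REJECTION_ROUNDS):
                bad = draws < low
                if not bad.any():
                    break
                draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            else:
                raise ConfigError(
                    f"{spec.name}: truncation at {low} rejects nearly all mass"
                )
        return draws
    if spec.family == "lognormal":
        mean, sd = float(p["mean"]), float(p["sd"])
        if sd == 0:
            return np.full(n, mean)
        mu, sigma = lognormal_parameters(mean, sd)
        return rng.lognormal(mu, sigma, size=n)
    if spec.family == "triangular":
        low, mode, high = float(p["low"]), float(p["mode"]), float(p["high"])
        if low == high:
            return np.full(n, low)
        return rng.triangular(low, mode, high, size=n)
    # mixture: pick components first, then draw each component stream
    components: Sequence[DistributionSpec] = p["components"]  # type: ignore[assignment]
    weights = p.get("weights")
    if weights is None:
        weights = [1.0 / len(components)] * len(components)
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(components) or not math.isclose(weights.sum(), 1.0):
        raise ConfigError(f"{spec.name}: mixture weights must sum to 1")
    idx = rng.choice(len(components), size=n, p=weights)
    out = np.empty(n)
    for k, comp in enumerate(components):
        out_k = sample(comp, n, rng)
        out[idx == k] = out_k[idx == k]
    return out


@dataclass(frozen=True)
class MCSConfig:
    n_iter: int = 10_000
    seed: int = 0
    percentiles: tuple[float, ...] = (5.0, 95.0)

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ConfigError("n_iter must be >= 1")
        if any(not (0 < q < 100) for q in self.percentiles):
            raise ConfigError("percentiles must lie strictly within (0, 100)")


@dataclass(frozen=True)
class MCSResult:
    """Draws plus summary statistics of one simulated output."""

    name: str
    group: str | None
    draws: np.ndarray
    mean: float
    percentiles: Mapping[float, float]
    sensitivity: Mapping[str, float]


class _Inputs(dict):
    def __missing__(self, key: str):
        raise ConfigError(f"model input {key!r} has no distribution spec")


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Per-input stream keyed on (root seed, input name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def sensitivity_contribution(
    input_draws: Mapping[str, np.ndarray], output: np.ndarray
) -> dict[str, float]:
    """Signed contribution-to-variance (%) of each input, from Spearman ρ."""
    output = np.asarray(output, dtype=float)
    if np.ptp(output) == 0:
        raise NoDataError("output is constant: no variance to attribute")
    rho: dict[str, float] = {}
    for name, draws in input_draws.items():
        draws = np.asarray(draws, dtype=float)
        if draws.shape != output.shape:
            raise ValidationError(f"{name}: draws length differs from output length")
        if np.ptp(draws) == 0:
            rho[name] = 0.0
        else:
            rho[name] = float(sps.spearmanr(draws, output).statistic)
    total = math.fsum(r * r for r in rho.values())
    if total == 0:
        return {name: 0.0 for name in rho}
    return {
        name: math.copysign(r * r / total * 100.0, r) if r != 0 else 0.0
        for name, r in rho.items()
    }


def run_mcs(
    model: Callable[[Mapping[str, np.ndarray]], np.ndarray],
    specs: Mapping[str, DistributionSpec] | Sequence[DistributionSpec],
    config: MCSConfig,
    name: str = "output",
    group: str | None = None,
) -> MCSResult:
    """Propagate the input distributions through ``model``.

    Deterministic given ``config.seed``. The model receives a mapping from
    input name to a draw vector and must return a vector of equal length.
    """
    if not isinstance(specs, Mapping):
        specs = {s.name: s for s in specs}
    draws = {
        nm: sample(sp, config.n_iter, child_rng(config.seed, nm))
        for nm, sp in specs.items()
    }
    output = np.asarray(model(_Inputs(draws)), dtype=float)
    if output.shape != (config.n_iter,):
        raise ValidationError(
            f"model returned shape {output.shape}, expected ({config.n_iter},)"
        )
    if np.ptp(output) == 0:
        # all inputs fixed: the simulation collapses onto the point estimate
        mean = float(output[0])
        sensitivity: dict[str, float] = {}
    else:
        mean = float(output.mean())
        sensitivity = sensitivity_contribution(draws, output)
    percentiles = {
        float(q): float(np.percentile(output, q)) for q in config.percentiles
    }
    return MCSResult(
        name=name,
        group=group,
        draws=output,
        mean=mean,
        percentiles=percentiles,
        sensitivity=sensitivity,
    )


# ---------------------------------------------------------------------------
# Risk-chain models and their default input specs


def concentration_spec(
    metal: str, config: Config, season: str = "pooled"
) -> DistributionSpec:
    """Lognormal concentration input; ``"pooled"`` mixes the two seasons 50/50."""
    by_season = config.study.concentrations[metal]
    if season in SEASONS:
        m = by_season[season]
        return DistributionSpec(
            f"C_{metal}", "lognormal", {"mean": m.mean, "sd": m.sd}
        )
    if season != "pooled":
        raise ConfigError(f"unknown season {season!r}")
    components = [
        DistributionSpec(
            f"C_{metal}_{s}",
            "lognormal",
            {"mean": by_season[s].mean, "sd": by_season[s].sd},
        )
        for s in SEASONS
    ]
    return DistributionSpec(f"C_{metal}", "mixture", {"components": components})


def _exposure_specs(profile: ExposureProfile, config: Config) -> dict[str, DistributionSpec]:
    return {
        "IR": DistributionSpec(
            "IR",
            "normal",
            {"mean": profile.ir, "sd": profile.ir * config.mcs.ir_cv, "low": 0.0},
        ),
        "EF": DistributionSpec(
            "EF",
            "triangular",
            {"low": profile.ef_min, "mode": profile.ef_mode, "high": profile.ef_max},
        ),
        "ED": DistributionSpec("ED", "fixed", {"value": profile.ed}),
        "BW": DistributionSpec(
            "BW",
            "lognormal",
            {"mean": profile.bw, "sd": profile.bw * config.mcs.bw_cv},
        ),
    }


def hi_model(
    metals: Mapping[str, MetalSpec], profile: ExposureProfile
) -> Callable[[Mapping[str, np.ndarray]], np.ndarray]:
    """HI = Σ_m C_m·IR·EF·ED / (f·BW·ED·365·RfD_m); ED cancels through AT."""
    names = [m for m in metals if metals[m].has_reference_dose]

    def model(x: Mapping[str, np.ndarray]) -> np.ndarray:
        at_days = x["ED"] * 365.0
        dose_rate = x["IR"] * x["EF"] * x["ED"] / (profile.f * x["BW"] * at_days)
        total = 0.0
        for m in names:
            total = total + x[f"C_{m}"] * dose_rate / x[f"RfD_{m}"]
        return total

    return model


def cr_model(
    metal: str, profile: ExposureProfile
) -> Callable[[Mapping[str, np.ndarray]], np.ndarray]:
    """CR = C·IR·EF·ED / (f·BW·AT) · SF with the lifetime averaging time."""

    def model(x: Mapping[str, np.ndarray]) -> np.ndarray:
        return (
            x[f"C_{metal}"]
            * x["IR"]
            * x["EF"]
            * x["ED"]
            / (profile.f * x["BW"] * x["AT"])
            * x["SF"]
        )

    return model


def default_hi_specs(
    group: str, config: Config, season: str = "pooled"
) -> dict[str, DistributionSpec]:
    profile = config.profiles[group]
    specs = _exposure_specs(profile, config)
    for m, spec in config.metals.items():
        if not spec.has_reference_dose:
            continue
        specs[f"C_{m}"] = concentration_spec(m, config, season)
        specs[f"RfD_{m}"] = DistributionSpec(
            f"RfD_{m}", "fixed", {"value": spec.reference_dose}
        )
    return specs


def default_cr_specs(
    group: str, config: Config, metal: str = "Pb", season: str = "pooled"
) -> dict[str, DistributionSpec]:
    profile = config.profiles[group]
    spec = config.metals[metal]
    if spec.sf is None:
        raise ConfigError(f"{metal}: no slope factor configured, CR undefined")
    specs = _exposure_specs(profile, config)
    specs[f"C_{metal}"] = concentration_spec(metal, config, season)
    specs["AT"] = DistributionSpec(
        "AT", "fixed", {"value": profile.lifetime_years * 365.0}
    )
    specs["SF"] = DistributionSpec("SF", "fixed", {"value": spec.sf})
    return specs


def run_hi_mcs(
    group: str, config: Config, mcs_config: MCSConfig, season: str = "pooled"
) -> MCSResult:
    """Monte Carlo hazard index for one receptor group."""
    profile = config.profiles[group]
    return run_mcs(
        hi_model(config.metals, profile),
        default_hi_specs(group, config, season),
        mcs_config,
        name="HI",
        group=group,
    )


def run_cr_mcs(
    group: str,
    config: Config,
    mcs_config: MCSConfig,
    metal: str = "Pb",
    season: str = "pooled",
) -> MCSResult:
    """Monte Carlo carcinogenic risk for one slope-factor metal."""
    profile = config.profiles[group]
    return run_mcs(
        cr_model(metal, profile),
        default_cr_specs(group, config, metal, season),
        mcs_config,
        name="CR",
        group=group,
    )
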