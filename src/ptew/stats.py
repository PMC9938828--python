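"""Seasonal statistics: normality, season comparison, rank correlations.

Each metal's winter and summer concentration sets are first checked for
normality (one-sample Kolmogorov–Smirnov against a normal with estimated
parameters, as classic SPSS does; a Lilliefors-corrected variant is available
via ``normality="lilliefors"``). If both seasons look normal at α the
comparison uses Welch's t-test, otherwise the Mann–Whitney rank test;
two-sided at a 95% confidence level by default.

Pairwise Spearman correlations are classified by |ρ| into weak (<0.5),
moderate (0.5–0.7) and strong (>0.7); a boundary value joins the higher band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import NoDataError, ValidationError
from .samples import WaterSample, concentration_values


def classify_rho(rho: float) -> str:
    """Correlation strength band of |ρ|; 0.5 → moderate, 0.7 → strong."""
    if math.isnan(rho):
        return "undefined"
    a = abs(rho)
    if a > 1:
        raise ValidationError(f"|rho| must be <= 1, got {rho}")
    if a < 0.5:
        return "weak"
    if a < 0.7:
        return "moderate"
    return "strong"


def normality_pvalue(values: np.ndarray, method: str = "ks") -> float:
    """P-value of a normality test with estimated mean/sd.

    ``"ks"`` is the plain one-sample KS test at the fitted parameters;
    ``"lilliefors"`` applies the correction for estimating them.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise NoDataError("normality test needs at least 3 observations")
    if np.ptp(values) == 0:
        return 0.0  # a degenerate constant sample is not normal
    if method == "ks":
        return float(
            sps.kstest(values, "norm", args=(values.mean(), values.std(ddof=1))).pvalue
        )
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        return float(lilliefors(values, dist="norm")[1])
    raise ValueError(f"unknown normality method {method!r}")


@dataclass(frozen=True)
class SeasonComparison:
    """Winter-vs-summer location comparison for one metal."""

    metal: str
    n: Mapping[str, int]
    normality_p: Mapping[str, float]
    test: str  # "welch-t" | "mann-whitney" | "degenerate"
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def compare_seasons(
    samples: Iterable[WaterSample],
    metal: str,
    alpha: float = 0.05,
    normality: str = "ks",
) -> SeasonComparison:
    """Two-sided seasonal difference test, parametric iff both seasons normal."""
    samples = list(samples)
    winter = concentration_values(samples, metal, "winter")
    summer = concentration_values(samples, metal, "summer")
    for season, values in (("winter", winter), ("summer", summer)):
        if values.size < 3:
            raise NoDataError(
                f"{metal}/{season}: need at least 3 samples, got {values.size}"
            )
    if np.ptp(np.concatenate([winter, summer])) == 0:
        # both seasons one identical constant: no evidence of any difference
        return SeasonComparison(
            metal=metal,
            n={"winter": winter.size, "summer": summer.size},
            normality_p={"winter": 0.0, "summer": 0.0},
            test="degenerate",
            statistic=float("nan"),
            p_value=1.0,
            significant=False,
            alpha=alpha,
        )
    p_norm = {
        "winter": normality_pvalue(winter, normality),
        "summer": normality_pvalue(summer, normality),
    }
    if min(p_norm.values()) > alpha:
        test = "welch-t"
        res = sps.ttest_ind(winter, summer, equal_var=False)
    else:
        test = "mann-whitney"
        res = sps.mannwhitneyu(winter, summer, alternative="two-sided")
    return SeasonComparison(
        metal=metal,
        n={"winter": winter.size, "summer": summer.size},
        normality_p=p_norm,
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
        alpha=alpha,
    )


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Spearman ρ, p-values and strength classes for one season."""

    season: str
    metals: tuple[str, ...]
    rho: pd.DataFrame
    p_values: pd.DataFrame
    strength: pd.DataFrame


def spearman_matrix(
    samples: Iterable[WaterSample],
    season: str,
    metals: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Symmetric Spearman matrix with two-sided p-values and strength bands."""
    samples = [s for s in samples if s.season == season]
    if metals is None:
        metals = sorted({m for s in samples for m in s.concentrations})
    metals = tuple(metals)
    if len(metals) < 2:
        raise NoDataError("correlation needs at least 2 metals")
    if len(samples) < 3:
        raise NoDataError("correlation needs at least 3 samples")
    data = np.column_stack([concentration_values(samples, m, season) for m in metals])
    constant = [m for j, m in enumerate(metals) if np.ptp(data[:, j]) == 0]
    if constant:
        warnings.warn(
            f"{season}: constant concentration column(s) {constant}; "
            "their correlations are undefined and reported as NaN",
            stacklevel=2,
        )
    k = len(metals)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if metals[i] in constant or metals[j] in constant:
                r, p = float("nan"), float("nan")
            else:
                res = sps.spearmanr(data[:, i], data[:, j])
                r, p = float(res.statistic), float(res.pvalue)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    rho_df = pd.DataFrame(rho, index=metals, columns=metals)
    p_df = pd.DataFrame(pval, index=metals, columns=metals)
    strength = rho_df.map(classify_rho)
    return CorrelationMatrix(
        season=season, metals=metals, rho=rho_df, p_values=p_df, strength=strength
    )
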