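"""Derived quantitative-genetics statistics for NC design II analyses.

Under the NC II random-effects decomposition, the covariance of half sibs
estimates Cov(HS) = sigma^2_GCA per parent sex and the extra covariance of
full sibs estimates sigma^2_SCA, which translate into additive and
dominance variance (no epistasis, no inbreeding) as

    sigma^2_A = 2 (sigma^2_GCA-F + sigma^2_GCA-M)
    sigma^2_D = 4 sigma^2_SCA.

Phenotypic variance on a plot-mean basis with r replicates is
sigma^2_P = sigma^2_G + sigma^2_e / r; heritabilities, Baker's
predictability ratio, the average degree of dominance
sqrt(2 sigma^2_D / sigma^2_A) and the expected genetic advance at 5%
selection intensity (i = 2.06) follow.  All ratios are returned at full
precision; rounding to two decimals is left to report writers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError

#: standardized selection differential at 5% selected fraction
SELECTION_INTENSITY_5PCT: float = 2.06


def _check_nonneg(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v}")


def genetic_variances(
    var_gca_f: float, var_gca_m: float, var_sca: float
) -> tuple[float, float]:
    """Additive and dominance variance from combining-ability components."""
    _check_nonneg(var_gca_f=var_gca_f, var_gca_m=var_gca_m, var_sca=var_sca)
    sigma2_a = 2.0 * (var_gca_f + var_gca_m)
    sigma2_d = 4.0 * var_sca
    return sigma2_a, sigma2_d


def phenotypic_variance(
    sigma2_a: float, sigma2_d: float, resid: float, r: int
) -> float:
    """sigma^2_P = sigma^2_A + sigma^2_D + sigma^2_e / r."""
    _check_nonneg(sigma2_a=sigma2_a, sigma2_d=sigma2_d, resid=resid)
    if r < 1:
        raise ValidationError(f"replicate count must be >= 1, got {r}")
    return sigma2_a + sigma2_d + resid / r


def broad_h2_single_year(sigma2_g: float, resid: float, r: int) -> float:
    """Per-year broad-sense heritability sigma^2_G / (sigma^2_G + sigma^2_e/r)."""
    _check_nonneg(sigma2_g=sigma2_g, resid=resid)
    if r < 1:
        raise ValidationError(f"replicate count must be >= 1, got {r}")
    denom = sigma2_g + resid / r
    if denom == 0:
        raise ValidationError("zero phenotypic variance; H2 undefined")
    return sigma2_g / denom


def broad_h2_across_years(
    sigma2_g: float, sigma2_gxy: float, resid: float, n: int, r: int
) -> float:
    """Across-year H2 = sigma^2_G / (sigma^2_G + sigma^2_GxY/n + sigma^2_e/(n r))."""
    _check_nonneg(sigma2_g=sigma2_g, sigma2_gxy=sigma2_gxy, resid=resid)
    if n < 1 or r < 1:
        raise ValidationError("year and replicate counts must be >= 1")
    denom = sigma2_g + sigma2_gxy / n + resid / (n * r)
    if denom == 0:
        raise ValidationError("zero phenotypic variance; H2 undefined")
    return sigma2_g / denom


def narrow_h2_set(
    sigma2_a: float,
    sigma2_d: float,
    var_gca_f: float,
    var_gca_m: float,
    resid: float,
    r: int,
) -> tuple[float, float, float]:
    """(h2, h2_F, h2_M): narrow-sense heritability and its sex-specific parts.

    h2 = sigma^2_A / sigma^2_P; the female/male components use 4x the
    corresponding GCA variance over the same phenotypic variance.
    """
    _check_nonneg(var_gca_f=var_gca_f, var_gca_m=var_gca_m)
    sigma2_p = phenotypic_variance(sigma2_a, sigma2_d, resid, r)
    if sigma2_p == 0:
        raise ValidationError("zero phenotypic variance; h2 undefined")
    return (
        sigma2_a / sigma2_p,
        4.0 * var_gca_f / sigma2_p,
        4.0 * var_gca_m / sigma2_p,
    )


def degree_of_dominance(sigma2_a: float, sigma2_d: float) -> float:
    """Average degree of dominance sqrt(2 sigma^2_D / sigma^2_A).

    Values above 1 indicate overdominance-like gene action at the
    variance-component level.
    """
    _check_nonneg(sigma2_d=sigma2_d)
    if sigma2_a <= 0:
        raise ValidationError("sigma2_A must be > 0 for the degree of dominance")
    return float(np.sqrt(2.0 * sigma2_d / sigma2_a))


def predictability_ratio(
    var_gca_f: float, var_gca_m: float, var_sca: float
) -> float:
    """Baker's ratio: GCA share of the combining-ability variance."""
    _check_nonneg(var_gca_f=var_gca_f, var_gca_m=var_gca_m, var_sca=var_sca)
    total = var_gca_f + var_gca_m + var_sca
    if total == 0:
        raise ValidationError("all combining-ability variances are zero")
    return (var_gca_f + var_gca_m) / total


def genetic_advance(
    h2: float,
    sigma2_p: float,
    mean: float,
    i: float = SELECTION_INTENSITY_5PCT,
) -> tuple[float, float]:
    """(GA, GAM): expected response to selection and its percent of the mean.

    GA = i * H2 * sigma_P (phenotypic standard deviation), GAM = 100 GA/mu.
    Pass the unrounded heritability.
    """
    _check_nonneg(sigma2_p=sigma2_p)
    if mean == 0:
        raise ValidationError("mean must be nonzero for GAM")
    ga = i * h2 * float(np.sqrt(sigma2_p))
    return ga, 100.0 * ga / mean


@dataclass
class GeneticSummary:
    """All derived statistics for one population x trait x year."""

    trait: str
    year: int | None
    population: str
    mean: float
    r: int
    sigma2_g: float
    sigma2_e: float
    sigma2_a: float | None = None
    sigma2_d: float | None = None
    sigma2_p: float | None = None
    H2: float | None = None
    h2: float | None = None
    h2_F: float | None = None
    h2_M: float | None = None
    degree_of_dominance: float | None = None
    predictability_ratio: float | None = None
    GA: float | None = None
    GAM: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_parents(
    trait: str, year: int, sigma2_g: float, sigma2_e: float, mean: float, r: int
) -> GeneticSummary:
    """Parent-population summary: H2 and genetic advance from model-1 components."""
    h2b = broad_h2_single_year(sigma2_g, sigma2_e, r)
    sigma2_p = sigma2_g + sigma2_e / r
    ga, gam = genetic_advance(h2b, sigma2_p, mean)
    return GeneticSummary(
        trait=trait,
        year=year,
        population="parent",
        mean=mean,
        r=r,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        sigma2_p=sigma2_p,
        H2=h2b,
        GA=ga,
        GAM=gam,
    )


def summarize_hybrids(
    trait: str,
    year: int,
    var_gca_f: float,
    var_gca_m: float,
    var_sca: float,
    resid_model5: float,
    sigma2_g_model1: float,
    sigma2_e_model1: float,
    mean: float,
    r: int,
) -> GeneticSummary:
    """Hybrid-population summary combining the model-5 and model-1 fits.

    The combining-ability decomposition (model 5) feeds sigma^2_A/sigma^2_D,
    narrow-sense heritabilities, dominance degree and the predictability
    ratio; the overall genotypic variance (model 1) feeds broad-sense
    heritability and the genetic advance, which target total genotypic
    selection among hybrids rather than additive transmission.
    """
    sigma2_a, sigma2_d = genetic_variances(var_gca_f, var_gca_m, var_sca)
    sigma2_p = phenotypic_variance(sigma2_a, sigma2_d, resid_model5, r)
    h2, h2f, h2m = narrow_h2_set(
        sigma2_a, sigma2_d, var_gca_f, var_gca_m, resid_model5, r
    )
    dom = degree_of_dominance(sigma2_a, sigma2_d) if sigma2_a > 0 else np.nan
    pr = (
        predictability_ratio(var_gca_f, var_gca_m, var_sca)
        if (var_gca_f + var_gca_m + var_sca) > 0
        else np.nan
    )
    h2b = broad_h2_single_year(sigma2_g_model1, sigma2_e_model1, r)
    sigma2_p_m1 = sigma2_g_model1 + sigma2_e_model1 / r
    ga, gam = genetic_advance(h2b, sigma2_p_m1, mean)
    return GeneticSummary(
        trait=trait,
        year=year,
        population="hybrid",
        mean=mean,
        r=r,
        sigma2_g=sigma2_g_model1,
        sigma2_e=sigma2_e_model1,
        sigma2_a=sigma2_a,
        sigma2_d=sigma2_d,
        sigma2_p=sigma2_p,
        H2=h2b,
        h2=h2,
        h2_F=h2f,
        h2_M=h2m,
        degree_of_dominance=dom,
        predictability_ratio=pr,
        GA=ga,
        GAM=gam,
    )


def summary_frame(summaries: list[GeneticSummary]) -> pd.DataFrame:
    """Stack summaries into a tidy frame (one row per population x trait x year)."""
    return pd.DataFrame([s.to_dict() for s in summaries]).set_index(
        ["population", "trait", "year"]
    )
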