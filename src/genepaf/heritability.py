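"""The PAF <-> heritability identity and the liability-scale transform.

For a binary trait the PAF estimate and the observed-scale heritability
estimate are linked one-to-one through coefficients of variation:

    PAF ~= h * CV_Y / CV_Xbeta,

where CV_Y = sqrt((1-P_Y)/P_Y) is the coefficient of variation of the
Bernoulli trait and CV_Xbeta is the CV of the genotype linear predictor.
The identity comes from approximating the log-linear (or logistic) risk model
by a linear regression via a quadratic Taylor expansion in the genotype
count Z; the expansion design is (Z, Z^2) with coefficients (delta, delta^2/2)
for a log link and (delta, (1-e^{d0})/(2(1+e^{d0})) * delta^2) for a logit
link with baseline log-odds d0.

Observed-scale heritability depends on trait prevalence, so it is customarily
rescaled to the liability scale of a threshold model: h_L^2 = c h^2 with
c = P_Y (1-P_Y) / v^2, v the standard-normal density at the threshold
T = Phi^{-1}(1 - P_Y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_paf import GenotypeDistribution

__all__ = [
    "TraitSpec",
    "ExpandedDesign",
    "LiabilityConstants",
    "liability_constants",
    "cv_binary_trait",
    "cv_linear_predictor",
    "h2_observed",
    "h_star_from_h2",
    "h2_liability",
]

EXPANSIONS = ("linear_only", "quadratic_loglinear", "quadratic_logistic")

#: Below this baseline risk the logistic expansion collapses to the log-linear
#: one, since 1 + e^{d0} ~= 1 - e^{d0} ~= 1.
RARE_BASELINE = 0.01


@dataclass(frozen=True)
class TraitSpec:
    """Disease prevalence, optional baseline (unexposed) risk, and link."""

    prevalence: float
    baseline_risk: float | None = None
    link: str = "loglinear"

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        if self.baseline_risk is not None and not (0.0 < self.baseline_risk < 1.0):
            raise ValueError(f"baseline risk must lie in (0, 1), got {self.baseline_risk}")
        if self.link not in ("loglinear", "logistic"):
            raise ValueError("link must be 'loglinear' or 'logistic'")


@dataclass(frozen=True)
class ExpandedDesign:
    """Per-variant Taylor-expansion contribution c1*Z + c2*Z^2 to the predictor."""

    first_order: float
    second_order: float
    expansion: str

    def values(self, z: np.ndarray | float) -> np.ndarray | float:
        return self.first_order * z + self.second_order * np.square(z)

    @classmethod
    def linear_only(cls, delta: float) -> "ExpandedDesign":
        return cls(delta, 0.0, "linear_only")

    @classmethod
    def quadratic_loglinear(cls, delta: float) -> "ExpandedDesign":
        return cls(delta, delta * delta / 2.0, "quadratic_loglinear")

    @classmethod
    def quadratic_logistic(cls, delta: float, baseline_risk: float) -> "ExpandedDesign":
        """Logit-link expansion; collapses to the log-link form for rare disease."""
        if baseline_risk < RARE_BASELINE:
            return cls(delta, delta * delta / 2.0, "quadratic_logistic")
        e0 = baseline_risk / (1.0 - baseline_risk)  # e^{delta_0}
        return cls(delta, (1.0 - e0) / (2.0 * (1.0 + e0)) * delta * delta,
                   "quadratic_logistic")


@dataclass(frozen=True)
class LiabilityConstants:
    threshold: float
    density_at_threshold: float
    scale_factor: float


def liability_constants(prevalence: float) -> LiabilityConstants:
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence must lie in (0, 1), got {prevalence}")
    t = stats.norm.ppf(1.0 - prevalence)
    v = stats.norm.pdf(t)
    c = prevalence * (1.0 - prevalence) / (v * v)
    return LiabilityConstants(threshold=t, density_at_threshold=v, scale_factor=c)


def cv_binary_trait(prevalence: float) -> float:
    """Coefficient of variation sqrt((1-P_Y)/P_Y) of a Bernoulli trait."""
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence must lie in (0, 1), got {prevalence}")
    return math.sqrt((1.0 - prevalence) / prevalence)


def _designs(designs: ExpandedDesign | Sequence[ExpandedDesign], k: int) -> list[ExpandedDesign]:
    if isinstance(designs, ExpandedDesign):
        designs = [designs]
    designs = list(designs)
    if len(designs) != k:
        raise ValueError(f"got {len(designs)} designs for {k} variants")
    return designs


def _predictor(dist: GenotypeDistribution,
               designs: ExpandedDesign | Sequence[ExpandedDesign]) -> np.ndarray:
    ds = _designs(designs, dist.k)
    values = np.zeros(dist.support.shape[0])
    for j, d in enumerate(ds):
        values += d.values(dist.support[:, j].astype(float))
    return values


def cv_linear_predictor(dist: GenotypeDistribution,
                        designs: ExpandedDesign | Sequence[ExpandedDesign]) -> float:
    """CV of the expanded linear predictor X*beta over the genotype support.

    Exact enumeration; errors if the mean predictor is not positive (the
    identity assumes a risk-increasing orientation and is undefined at the
    null).
    """
    xb = _predictor(dist, designs)
    mean = float(xb @ dist.pmf)
    if mean <= 0.0:
        raise ValueError("mean linear predictor must be positive (re-orient alleles; "
                         "the identity is undefined for all-null effects)")
    var = float(np.square(xb - mean) @ dist.pmf)
    return math.sqrt(var) / mean


def h2_observed(paf: float, trait: TraitSpec, dist: GenotypeDistribution,
                designs: ExpandedDesign | Sequence[ExpandedDesign]) -> float:
    """Observed-scale heritability implied by a PAF through the CV identity."""
    if not (0.0 <= paf < 1.0):
        raise ValueError(f"PAF must lie in [0, 1), got {paf}")
    h = paf * cv_linear_predictor(dist, designs) / cv_binary_trait(trait.prevalence)
    if h >= 1.0:
        raise ValueError(
            f"implied h = {h:.3f} >= 1: the Taylor-expansion identity broke down "
            "for these inputs (effects too large relative to prevalence)"
        )
    return h * h


def h_star_from_h2(h2: float, trait: TraitSpec, dist: GenotypeDistribution,
                   designs: ExpandedDesign | Sequence[ExpandedDesign]) -> float:
    """PAF-scale statistic h * CV_Y / CV_Xbeta (the inverse of h2_observed)."""
    if not (0.0 <= h2 < 1.0):
        raise ValueError(f"h2 must lie in [0, 1), got {h2}")
    return math.sqrt(h2) * cv_binary_trait(trait.prevalence) / cv_linear_predictor(dist, designs)


def h2_liability(h2: float, prevalence: float) -> float:
    """Transform observed-scale h^2 to the liability scale: h_L^2 = c h^2."""
    if h2 < 0.0:
        raise ValueError(f"h2 must be nonnegative, got {h2}")
    return liability_constants(prevalence).scale_factor * h2
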