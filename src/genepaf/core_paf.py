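"""Closed-form population attributable fraction (PAF) for risk alleles.

The PAF of a set of risk alleles is the proportional reduction in population
disease risk if every copy of those alleles were replaced by the reference
allele, other risk factors unchanged (Levin-type attributable fraction).  For
a single variant with risk-allele frequency ``p`` under Hardy-Weinberg
equilibrium and a per-allele relative risk ``RR`` acting multiplicatively on
the log risk scale,

    PAF = 1 - 1 / [ (1-p)^2 + 2 RR p (1-p) + RR^2 p^2 ],

and for K variants with joint per-allele log relative risks ``beta_k`` and
joint genotype distribution P(X_1,...,X_K),

    PAF = 1 - 1 / sum_{i_1..i_K} exp(sum_k beta_k i_k) P(i_1,...,i_K),

evaluated by exact enumeration of the 3^K genotype support.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EFFECT_MODELS",
    "VariantSummary",
    "RelativeRisk",
    "GenotypeDistribution",
    "paf_single",
    "orient_risk_allele",
    "paf_joint",
    "paf_product_independent",
    "genotype_multipliers",
]

EFFECT_MODELS = ("additive", "dominant", "recessive")

#: Exact enumeration of the 3^K genotype support is refused beyond this K.
MAX_ENUMERATION_K = 15


class OrientationError(ValueError):
    """A protective allele (RR < 1) was passed where a risk allele is required."""


@dataclass(frozen=True)
class RelativeRisk:
    """Per-allele relative risk ``e^beta`` together with its log ``beta``."""

    rr_per_allele: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.rr_per_allele) or self.rr_per_allele <= 0:
            raise ValueError(f"relative risk must be positive and finite, got {self.rr_per_allele}")

    @property
    def log_rr(self) -> float:
        return math.log(self.rr_per_allele)

    @classmethod
    def from_log(cls, log_rr: float) -> "RelativeRisk":
        return cls(math.exp(log_rr))


@dataclass(frozen=True)
class VariantSummary:
    """One variant's GWAS summary statistics.

    ``raf`` is the population risk-allele frequency (Hardy-Weinberg assumed);
    ``or_point`` the per-allele odds ratio; the optional 95% CI bounds and
    two-sided p-value let downstream code recover a standard error.
    """

    variant_id: str
    raf: float
    or_point: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    effect_model: str = "additive"

    def __post_init__(self) -> None:
        if not (0.0 <= self.raf <= 1.0) or not math.isfinite(self.raf):
            raise ValueError(f"{self.variant_id}: RAF must lie in [0, 1], got {self.raf}")
        if not math.isfinite(self.or_point) or self.or_point <= 0:
            raise ValueError(f"{self.variant_id}: OR must be positive, got {self.or_point}")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError(f"{self.variant_id}: both CI bounds are required")
        if self.ci_low is not None:
            if self.ci_low <= 0:
                raise ValueError(f"{self.variant_id}: CI bounds must be positive")
            if not (self.ci_low <= self.or_point <= self.ci_high):
                raise ValueError(
                    f"{self.variant_id}: CI ({self.ci_low}, {self.ci_high}) "
                    f"does not bracket OR {self.or_point}"
                )
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"{self.variant_id}: p-value must lie in (0, 1]")
        for name in ("n_cases", "n_controls"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.variant_id}: {name} must be nonnegative")
        if self.effect_model not in EFFECT_MODELS:
            raise ValueError(f"effect_model must be one of {EFFECT_MODELS}")

    @property
    def n_total(self) -> int | None:
        if self.n_cases is None or self.n_controls is None:
            return None
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float | None:
        n = self.n_total
        if n in (None, 0):
            return None
        return self.n_cases / n


class GenotypeDistribution:
    """Joint pmf of K allele-count variables on {0,1,2}^K.

    Stored as an (M, K) integer support array plus an (M,) probability vector;
    M may be smaller than 3^K when the distribution is empirical and some
    genotype tuples were never observed.
    """

    def __init__(self, variant_ids: Sequence[str], support: np.ndarray, pmf: np.ndarray):
        support = np.asarray(support, dtype=np.int64)
        pmf = np.asarray(pmf, dtype=float)
        if support.ndim != 2 or support.shape[1] != len(variant_ids):
            raise ValueError("support must be (M, K) with K == len(variant_ids)")
        if pmf.shape != (support.shape[0],):
            raise ValueError("pmf length must match support rows")
        if np.any(pmf < -1e-12):
            raise ValueError("pmf entries must be nonnegative")
        if abs(pmf.sum() - 1.0) > 1e-9:
            raise ValueError(f"pmf must sum to 1, got {pmf.sum()!r}")
        if support.min() < 0 or support.max() > 2:
            raise ValueError("genotype counts must lie in {0, 1, 2}")
        self.variant_ids = list(variant_ids)
        self.support = support
        self.pmf = pmf

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    @classmethod
    def from_hwe(cls, rafs: Sequence[float], variant_ids: Sequence[str] | None = None,
                 max_k: int = MAX_ENUMERATION_K) -> "GenotypeDistribution":
        """Independent Hardy-Weinberg product distribution for the given RAFs."""
        rafs = np.asarray(rafs, dtype=float)
        k = rafs.size
        if k > max_k:
            raise ValueError(
                f"K={k} exceeds the exact-enumeration cap ({max_k}); "
                "use the Monte-Carlo joint distribution instead (3^K blow-up)"
            )
        if variant_ids is None:
            variant_ids = [f"X{i + 1}" for i in range(k)]
        support = np.array(list(itertools.product((0, 1, 2), repeat=k)), dtype=np.int64)
        marg = np.stack([(1 - rafs) ** 2, 2 * rafs * (1 - rafs), rafs ** 2])  # (3, K)
        pmf = np.prod(marg[support, np.arange(k)], axis=1)
        return cls(variant_ids, support, pmf)

    @classmethod
    def from_samples(cls, genotypes: np.ndarray,
                     variant_ids: Sequence[str] | None = None) -> "GenotypeDistribution":
        """Empirical joint pmf from an (n, K) matrix of 0/1/2 allele counts."""
        genotypes = np.asarray(genotypes)
        if genotypes.ndim == 1:
            genotypes = genotypes[:, None]
        if variant_ids is None:
            variant_ids = [f"X{i + 1}" for i in range(genotypes.shape[1])]
        support, counts = count_genotype_cells(genotypes)
        return cls(variant_ids, support, counts / counts.sum())

    def marginal(self, index: int) -> np.ndarray:
        """Marginal pmf (length 3) of variant ``index``."""
        out = np.zeros(3)
        np.add.at(out, self.support[:, index], self.pmf)
        return out


def encode_genotype_cells(genotypes: np.ndarray) -> tuple[np.ndarray, int]:
    """Base-3 integer code of each genotype row; far faster than row-wise
    uniqueness for the tiny {0,1,2}^K support."""
    genotypes = np.asarray(genotypes)
    k = genotypes.shape[1]
    powers = 3 ** np.arange(k, dtype=np.int64)
    return genotypes.astype(np.int64) @ powers, k


def decode_genotype_cells(codes: np.ndarray, k: int) -> np.ndarray:
    out = np.empty((codes.size, k), dtype=np.int64)
    rem = codes.astype(np.int64).copy()
    for j in range(k):
        out[:, j] = rem % 3
        rem //= 3
    return out


def count_genotype_cells(genotypes: np.ndarray,
                         weights: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Observed genotype tuples and their (optionally weighted) counts."""
    codes, k = encode_genotype_cells(genotypes)
    counts = np.bincount(codes, weights=weights, minlength=3 ** k)
    observed = np.flatnonzero(counts) if weights is None else \
        np.flatnonzero(np.bincount(codes, minlength=3 ** k))
    return decode_genotype_cells(observed, k), counts[observed]


def genotype_multipliers(rr: RelativeRisk, effect_model: str = "additive") -> np.ndarray:
    """Relative risk of genotype classes (0, 1, 2 copies) under a coding model."""
    r = rr.rr_per_allele
    if effect_model == "additive":
        return np.array([1.0, r, r * r])
    if effect_model == "dominant":
        return np.array([1.0, r, r])
    if effect_model == "recessive":
        return np.array([1.0, 1.0, r])
    raise ValueError(f"effect_model must be one of {EFFECT_MODELS}")


def paf_single(raf: float, rr: RelativeRisk | float, effect_model: str = "additive") -> float:
    """PAF of one variant from its risk-allele frequency and relative risk.

    Protective alleles (RR < 1) must be re-oriented to the complementary
    allele first (see :func:`orient_risk_allele`); otherwise the "attributable"
    fraction would be negative and refer to the wrong allele.
    """
    if isinstance(rr, (int, float)):
        rr = RelativeRisk(float(rr))
    if not (0.0 <= raf <= 1.0) or not math.isfinite(raf):
        raise ValueError(f"RAF must lie in [0, 1], got {raf}")
    if rr.rr_per_allele < 1.0:
        raise OrientationError(
            f"RR {rr.rr_per_allele} < 1: re-orient to the complementary allele "
            "(orient_risk_allele) before computing the PAF"
        )
    hwe = np.array([(1 - raf) ** 2, 2 * raf * (1 - raf), raf ** 2])
    mean_rr = float(hwe @ genotype_multipliers(rr, effect_model))
    return 1.0 - 1.0 / mean_rr


def orient_risk_allele(vs: VariantSummary) -> VariantSummary:
    """Return the record re-expressed for the risk (OR >= 1) allele.

    For OR < 1 the complementary allele is the risk allele: its frequency is
    1 - RAF, its OR the reciprocal, and the CI bounds swap reciprocally.
    Applying the function twice is the identity.
    """
    if vs.or_point >= 1.0:
        return vs
    ci_low = None if vs.ci_high is None else 1.0 / vs.ci_high
    ci_high = None if vs.ci_low is None else 1.0 / vs.ci_low
    return replace(vs, raf=1.0 - vs.raf, or_point=1.0 / vs.or_point,
                   ci_low=ci_low, ci_high=ci_high)


def paf_joint(betas: Sequence[float], dist: GenotypeDistribution) -> float:
    """Joint PAF of K variants by exact enumeration of the genotype support.

    ``betas`` are joint per-allele log relative risks; the baseline risk
    cancels, so only the mean relative risk over the genotype distribution
    enters.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 1 or betas.size != dist.k:
        raise ValueError(f"got {betas.size} effects for {dist.k} variants")
    if dist.k > MAX_ENUMERATION_K:
        raise ValueError(
            f"K={dist.k} exceeds the enumeration cap ({MAX_ENUMERATION_K}); "
            "use the Monte-Carlo pipeline for larger variant sets"
        )
    mean_rr = float(np.exp(dist.support @ betas) @ dist.pmf)
    return 1.0 - 1.0 / mean_rr


def paf_product_independent(pafs: Iterable[float]) -> float:
    """Combine per-variant PAFs by the independence product rule.

    ``1 - prod_k (1 - PAF_k)`` is exact when the variants are independent and
    each PAF_k uses the joint (adjusted) effect; with marginal effects and
    positively correlated variants it overestimates, and with adjusted effects
    it is the standard approximation for correlated variants.
    """
    pafs = list(pafs)
    arr = np.asarray(pafs, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one PAF")
    if np.any(arr < 0) or np.any(arr >= 1) or not np.all(np.isfinite(arr)):
        raise ValueError("each PAF must lie in [0, 1)")
    return float(1.0 - np.prod(1.0 - arr))
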