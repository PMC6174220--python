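"""Correlated binary and genotype data via a dichotomised Gaussian copula.

To draw K binary variables with given marginal probabilities p_j and a given
matrix of pairwise Pearson correlations (on the binary scale), a latent
multivariate normal vector is sampled and each coordinate is thresholded at
Phi^{-1}(1 - p_j).  The latent pairwise correlation for each pair is found by
root-finding on the bivariate-normal orthant probability so that the
dichotomised pair hits the target correlation — the classical construction
behind correlated-binary generators such as R's bindata.

Genotypes are built as the sum of two exchangeable latent allele indicators
with success probability equal to the risk-allele frequency; the two alleles
of one variant are kept independent, which enforces Hardy-Weinberg proportions
by construction while still allowing the genotype to correlate with the trait
and with other genotypes.  If the genotype-scale correlation between variants
j and k is r, every allele of j correlates with every allele of k at r/2; if
the trait-genotype correlation is c, each allele correlates with the trait at
c/sqrt(2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CorrelationTarget",
    "LatentModel",
    "feasibility_bounds",
    "solve_latent_correlation",
    "sample_binary",
    "sample_genotypes",
    "sample_trait_and_genotypes",
]

_RHO_LIM = 1.0 - 1e-9
_SOLVER_TOL = 1e-10


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def feasibility_bounds(p1: float, p2: float) -> tuple[float, float]:
    """Attainable Pearson-correlation range for two Bernoulli marginals.

    The Frechet bounds on the joint success probability,
    max(0, p1+p2-1) <= P11 <= min(p1, p2), translate directly into bounds on
    the correlation (P11 - p1 p2) / sqrt(p1 q1 p2 q2).
    """
    for p in (p1, p2):
        if not (0.0 < p < 1.0):
            raise ValueError(f"marginal probabilities must lie in (0, 1), got {p}")
    denom = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    lo = (max(0.0, p1 + p2 - 1.0) - p1 * p2) / denom
    hi = (min(p1, p2) - p1 * p2) / denom
    return lo, hi


def _orthant(t1: float, t2: float, rho: float) -> float:
    """P(Z1 > t1, Z2 > t2) for standard bivariate normal with correlation rho."""
    cdf = stats.multivariate_normal(mean=[0.0, 0.0],
                                    cov=[[1.0, rho], [rho, 1.0]]).cdf([t1, t2])
    return 1.0 - stats.norm.cdf(t1) - stats.norm.cdf(t2) + float(cdf)


def solve_pair_latent(p1: float, p2: float, target_corr: float) -> float:
    """Latent normal correlation whose dichotomised pair has the target
    binary-scale Pearson correlation.

    Deterministic in its arguments, so results are memoised; the bootstrap
    re-solves thousands of near-identical pairs.
    """
    return _solve_pair_latent_cached(float(p1), float(p2), float(target_corr))


@lru_cache(maxsize=65536)
def _solve_pair_latent_cached(p1: float, p2: float, target_corr: float) -> float:
    if target_corr == 0.0:
        return 0.0
    lo, hi = feasibility_bounds(p1, p2)
    if not (lo - 1e-12 <= target_corr <= hi + 1e-12):
        raise ValueError(
            f"target correlation {target_corr:.4f} infeasible for marginals "
            f"({p1}, {p2}); attainable range is ({lo:.4f}, {hi:.4f})"
        )
    # the Frechet bounds are attained by the co-/anti-monotone Gaussian copula
    if target_corr >= hi - 1e-12:
        return 1.0
    if target_corr <= lo + 1e-12:
        return -1.0
    t1 = stats.norm.ppf(1.0 - p1)
    t2 = stats.norm.ppf(1.0 - p2)
    denom = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    p11_target = target_corr * denom + p1 * p2

    def gap(rho: float) -> float:
        return _orthant(t1, t2, rho) - p11_target

    try:
        rho = optimize.brentq(gap, -_RHO_LIM, _RHO_LIM, xtol=_SOLVER_TOL)
    except ValueError as exc:
        raise RuntimeError(
            f"latent-correlation root finding failed for marginals ({p1}, {p2}), "
            f"target {target_corr}"
        ) from exc
    return float(rho)


@dataclass(frozen=True)
class CorrelationTarget:
    """Marginal success probabilities plus target binary-scale correlations."""

    marginal_probs: np.ndarray
    target_corr: np.ndarray

    def __init__(self, marginal_probs: Sequence[float], target_corr: np.ndarray):
        p = np.asarray(marginal_probs, dtype=float)
        r = np.asarray(target_corr, dtype=float)
        k = p.size
        if r.shape != (k, k):
            raise ValueError(f"correlation matrix must be ({k}, {k}), got {r.shape}")
        if not np.allclose(r, r.T, atol=1e-12) or not np.allclose(np.diag(r), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        for i in range(k):
            for j in range(i + 1, k):
                lo, hi = feasibility_bounds(p[i], p[j])
                if not (lo - 1e-12 <= r[i, j] <= hi + 1e-12):
                    raise ValueError(
                        f"target corr[{i},{j}]={r[i, j]:.4f} outside the Frechet-"
                        f"feasible range ({lo:.4f}, {hi:.4f}) for marginals "
                        f"({p[i]}, {p[j]})"
                    )
        object.__setattr__(self, "marginal_probs", p)
        object.__setattr__(self, "target_corr", r)

    @property
    def k(self) -> int:
        return self.marginal_probs.size


@dataclass(frozen=True)
class LatentModel:
    """Solved latent-normal correlation matrix and dichotomisation thresholds."""

    thresholds: np.ndarray
    latent_corr: np.ndarray
    marginal_probs: np.ndarray
    repaired: bool = False


def _nearest_psd(mat: np.ndarray) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clipping repair; rescaled back to unit diagonal."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() >= -1e-10:
        return mat, False
    clipped = np.clip(vals, 1e-8, None)
    fixed = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, True


def solve_latent_correlation(target: CorrelationTarget) -> LatentModel:
    """Solve every pairwise latent correlation and assemble the latent model.

    The pairwise solutions need not form a jointly positive semi-definite
    matrix; if they do not, the nearest-PSD repair (eigenvalue clipping) is
    applied and a warning emitted.
    """
    k = target.k
    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            latent[i, j] = latent[j, i] = solve_pair_latent(
                target.marginal_probs[i], target.marginal_probs[j],
                target.target_corr[i, j])
    latent, repaired = _nearest_psd(latent)
    if repaired:
        warnings.warn("pairwise latent correlation matrix was not positive "
                      "semi-definite; nearest-PSD repair applied", stacklevel=2)
    thresholds = stats.norm.ppf(1.0 - target.marginal_probs)
    return LatentModel(thresholds=thresholds, latent_corr=latent,
                       marginal_probs=target.marginal_probs, repaired=repaired)


def sample_binary(model: LatentModel, n: int, seed=None) -> np.ndarray:
    """Draw an (n, K) 0/1 matrix from the latent model; reproducible by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    # symmetric square root (eigh) rather than Cholesky: exact for singular
    # matrices such as a perfectly correlated pair
    vals, vecs = np.linalg.eigh(model.latent_corr)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n, model.latent_corr.shape[0])) @ root.T
    return (z > model.thresholds).astype(np.int8)


def _allele_level_target(y_prob: float | None, rafs: np.ndarray,
                         corr_y_x: np.ndarray | None,
                         corr_x_x: np.ndarray) -> CorrelationTarget:
    """Expand genotype-scale targets to the (Y, allele...) binary level."""
    k = rafs.size
    with_y = y_prob is not None
    dim = (1 if with_y else 0) + 2 * k
    probs = np.empty(dim)
    corr = np.eye(dim)
    off = 1 if with_y else 0
    if with_y:
        probs[0] = y_prob
    probs[off:] = np.repeat(rafs, 2)

    if with_y:
        a = np.asarray(corr_y_x, dtype=float) / math.sqrt(2.0)
        for kk in range(k):
            lo, hi = feasibility_bounds(y_prob, rafs[kk])
            if not (lo <= a[kk] <= hi):
                raise ValueError(
                    f"requested trait-genotype correlation {corr_y_x[kk]:.4f} for "
                    f"variant {kk} is outside the attainable range "
                    f"({lo * math.sqrt(2):.4f}, {hi * math.sqrt(2):.4f}); "
                    "a smaller effect (or larger sample) is needed"
                )
            corr[0, off + 2 * kk] = corr[off + 2 * kk, 0] = a[kk]
            corr[0, off + 2 * kk + 1] = corr[off + 2 * kk + 1, 0] = a[kk]
    for i in range(k):
        for j in range(i + 1, k):
            b = corr_x_x[i, j] / 2.0
            for ai in (off + 2 * i, off + 2 * i + 1):
                for aj in (off + 2 * j, off + 2 * j + 1):
                    corr[ai, aj] = corr[aj, ai] = b
    return CorrelationTarget(probs, corr)


def sample_genotypes(rafs: Sequence[float], corr_x_x: np.ndarray | None,
                     n: int, seed=None) -> np.ndarray:
    """Draw an (n, K) matrix of 0/1/2 allele counts with HWE marginals and the
    requested genotype-scale pairwise correlations."""
    rafs = np.asarray(rafs, dtype=float)
    k = rafs.size
    if corr_x_x is None:
        corr_x_x = np.eye(k)
    target = _allele_level_target(None, rafs, None, np.asarray(corr_x_x, dtype=float))
    model = solve_latent_correlation(target)
    alleles = sample_binary(model, n, seed)
    return (alleles[:, 0::2] + alleles[:, 1::2]).astype(np.int8)


def sample_trait_and_genotypes(y_prob: float, rafs: Sequence[float],
                               corr_y_x: Sequence[float],
                               corr_x_x: np.ndarray | None,
                               n: int, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw (Y, genotypes) with the requested trait-genotype and
    genotype-genotype correlations.

    Y is a single binary column with marginal ``y_prob``; genotypes are 0/1/2
    allele counts with HWE marginals at the given RAFs.
    """
    rafs = np.asarray(rafs, dtype=float)
    k = rafs.size
    corr_y_x = np.asarray(corr_y_x, dtype=float)
    if corr_y_x.shape != (k,):
        raise ValueError("corr_y_x must have one entry per variant")
    if corr_x_x is None:
        corr_x_x = np.eye(k)
    target = _allele_level_target(y_prob, rafs, corr_y_x, np.asarray(corr_x_x, dtype=float))
    model = solve_latent_correlation(target)
    draws = sample_binary(model, n, seed)
    y = draws[:, 0]
    genotypes = (draws[:, 1::2] + draws[:, 2::2]).astype(np.int8)
    return y, genotypes
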