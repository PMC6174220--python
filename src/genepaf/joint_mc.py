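"""PAF of correlated variants from GWAS summary statistics (Monte-Carlo).

Marginal per-variant summary statistics cannot be plugged into the joint PAF
formula directly: with positive LD each marginal OR absorbs a fraction of the
other alleles' effects.  The estimator here recovers joint effects without
individual-level data in five steps:

1.  Convert each variant's log-OR and standard error to a signed score
    statistic ST = beta/se, hence an implied trait-genotype correlation
    Corr(Y, X_k) = ST_k / sqrt(N_k).
2.  Simulate a large case-control-like sample of (Y, X_1..X_K) with those
    trait-genotype correlations, the LD-implied genotype-genotype
    correlations, HWE genotype marginals, and Y-marginal equal to the pooled
    case fraction; fit one multivariate logistic regression to obtain joint
    per-allele log-ORs.
3.  Estimate the population joint genotype distribution empirically from a
    second draw that uses the population RAFs and the LD structure only.
4.  Evaluate the multi-variant PAF by enumeration over that distribution.
5.  Parametric bootstrap: redraw each marginal log-OR from
    N(beta_hat, se^2), rerun steps 2-4, and set the 95% CI to the point
    estimate +/- 1.96 times the standard deviation of the bootstrap PAFs.

For a single variant the closed-form estimator (plug the OR, optionally
corrected to an RR, into the three-genotype formula) is also provided; the
Monte-Carlo path reduces to it up to simulation noise.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .core_paf import (GenotypeDistribution, VariantSummary,
                       decode_genotype_cells, encode_genotype_cells,
                       orient_risk_allele, paf_joint, paf_single)
from .corrbin import sample_genotypes, sample_trait_and_genotypes
from .gwas_summary import effect_from_summary, or_to_rr, score_stat
from .heritability import (ExpandedDesign, TraitSpec, h2_liability, h2_observed)

__all__ = [
    "JointEffects",
    "PafEstimate",
    "estimate_joint_effects",
    "population_joint_distribution",
    "paf_correlated",
    "paf_single_from_summary",
    "bootstrap_ci",
    "corr_from_ld_r2",
]

logger = logging.getLogger(__name__)

DEFAULT_MC_SAMPLE_SIZE = 100_000
DEFAULT_N_BOOT = 1_000


def corr_from_ld_r2(r2: np.ndarray, sign: float = 1.0) -> np.ndarray:
    """Genotype-scale correlation matrix from a pairwise LD r-squared matrix.

    r^2 is signless; a positive coupling (+sqrt(r^2)) is assumed by default,
    the usual situation when both reported risk alleles have OR > 1.
    """
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 < 0) or np.any(r2 > 1):
        raise ValueError("r^2 entries must lie in [0, 1]")
    corr = math.copysign(1.0, sign) * np.sqrt(r2)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass(frozen=True)
class JointEffects:
    """Joint per-allele log-ORs from the simultaneous logistic re-fit."""

    variant_ids: list[str]
    betas: np.ndarray
    intercept: float
    y_bar: float
    mc_sample_size: int


@dataclass
class PafEstimate:
    """Point estimate with bootstrap CI and the linked heritability values."""

    variant_ids: list[str]
    paf_point: float
    betas: np.ndarray
    ci_low: float | None = None
    ci_high: float | None = None
    boot_draws: np.ndarray | None = None
    h2_observed: float | None = None
    h2_liability: float | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ci_low is not None and not (self.ci_low <= self.paf_point <= self.ci_high):
            logger.warning(
                "bootstrap CI (%.4f, %.4f) does not bracket the point estimate %.4f",
                self.ci_low, self.ci_high, self.paf_point)

    def to_dict(self) -> dict:
        return {
            "variant_ids": self.variant_ids,
            "paf": self.paf_point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "betas_joint": list(map(float, np.atleast_1d(self.betas))),
            "h2_observed": self.h2_observed,
            "h2_liability": self.h2_liability,
            "settings": self.settings,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _fit_logistic_grouped(y: np.ndarray, genotypes: np.ndarray) -> np.ndarray:
    """Multivariate logistic fit, aggregated over the 3^K genotype cells.

    Returns [intercept, beta_1, ..., beta_K].  Aggregation is exact (the
    genotype support is tiny) and makes the fit cost independent of n.
    """
    codes, k = encode_genotype_cells(genotypes)
    n_cells = 3 ** k
    totals = np.bincount(codes, minlength=n_cells).astype(float)
    successes = np.bincount(codes, weights=y.astype(float), minlength=n_cells)
    observed = np.flatnonzero(totals)
    support = decode_genotype_cells(observed, k)
    successes, totals = successes[observed], totals[observed]
    exog = sm.add_constant(support.astype(float), has_constant="add")
    endog = np.column_stack([successes, totals - successes])
    try:
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"step (2): joint logistic fit failed to converge "
            f"(cells={m}, n={int(totals.sum())}): {exc}"
        ) from exc
    return np.asarray(res.params)


def _marginal_inputs(variants: Sequence[VariantSummary]):
    """Orient alleles, recover effects/ses and implied correlations."""
    oriented = [orient_risk_allele(v) for v in variants]
    effects, corrs, fractions = [], [], []
    for v in oriented:
        if v.n_total in (None, 0):
            raise ValueError(f"step (1): {v.variant_id} needs n_cases and n_controls")
        eff = effect_from_summary(v)
        st = score_stat(eff, v.n_total, y_bar=v.case_fraction)
        effects.append(eff)
        corrs.append(st.corr_yx)
        fractions.append(v.case_fraction)
    return oriented, effects, np.asarray(corrs), fractions


def estimate_joint_effects(variants: Sequence[VariantSummary], ld: np.ndarray | None,
                           mc_sample_size: int = DEFAULT_MC_SAMPLE_SIZE,
                           seed=None, y_bar: float | None = None) -> JointEffects:
    """Steps (1)-(2): joint per-allele log-ORs from marginal summary statistics.

    ``ld`` is the genotype-scale correlation matrix (use
    :func:`corr_from_ld_r2` to convert an r-squared matrix); ``y_bar`` defaults
    to the average of the studies' case fractions, the marginal under which the
    score-statistic correlations were observed.
    """
    oriented, _, corrs, fractions = _marginal_inputs(variants)
    rafs = np.array([v.raf for v in oriented])
    if y_bar is None:
        y_bar = float(np.mean(fractions))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y, genotypes = sample_trait_and_genotypes(
        y_bar, rafs, corrs, ld, mc_sample_size, rng)
    params = _fit_logistic_grouped(y, genotypes)
    return JointEffects(variant_ids=[v.variant_id for v in oriented],
                        betas=params[1:], intercept=float(params[0]),
                        y_bar=y_bar, mc_sample_size=mc_sample_size)


def population_joint_distribution(rafs: Sequence[float], ld: np.ndarray | None,
                                  mc_sample_size: int = DEFAULT_MC_SAMPLE_SIZE,
                                  seed=None,
                                  variant_ids: Sequence[str] | None = None
                                  ) -> GenotypeDistribution:
    """Step (3): empirical population genotype distribution from RAFs and LD.

    Uses population-scale RAFs (in practice the controls' frequencies stand in
    for the population when the disease is rare).
    """
    genotypes = sample_genotypes(rafs, ld, mc_sample_size, seed)
    return GenotypeDistribution.from_samples(genotypes, variant_ids)


def _corrected_betas(betas: np.ndarray, baseline_risk: float | None) -> np.ndarray:
    if baseline_risk is None:
        return betas
    return np.array([or_to_rr(math.exp(b), baseline_risk).log_rr for b in betas])


def _identity_h2(paf: float, betas: np.ndarray, dist: GenotypeDistribution,
                 trait: TraitSpec | None) -> tuple[float | None, float | None]:
    if trait is None:
        return None, None
    designs = [ExpandedDesign.linear_only(float(b)) for b in betas]
    try:
        h2 = h2_observed(paf, trait, dist, designs)
    except ValueError:
        return None, None
    return h2, h2_liability(h2, trait.prevalence)


def paf_correlated(variants: Sequence[VariantSummary], ld: np.ndarray | None,
                   trait: TraitSpec | None = None,
                   mc_sample_size: int = DEFAULT_MC_SAMPLE_SIZE,
                   n_boot: int = DEFAULT_N_BOOT, seed=None,
                   or_correction: bool = False,
                   compute_ci: bool = True) -> PafEstimate:
    """Steps (1)-(5): joint PAF of correlated variants with a bootstrap CI.

    When ``or_correction`` is set (requires ``trait.baseline_risk``), each
    joint OR is first converted to an RR via OR/(1-P0+OR*P0).  The returned
    estimate carries the linked observed- and liability-scale heritability
    when a trait prevalence is supplied.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if or_correction and (trait is None or trait.baseline_risk is None):
        raise ValueError("or_correction requires a TraitSpec with baseline_risk")
    baseline = trait.baseline_risk if (or_correction and trait is not None) else None

    oriented, effects, corrs, fractions = _marginal_inputs(variants)
    rafs = np.array([v.raf for v in oriented])
    ids = [v.variant_id for v in oriented]
    y_bar = float(np.mean(fractions))

    joint = estimate_joint_effects(oriented, ld, mc_sample_size, rng, y_bar=y_bar)
    betas = _corrected_betas(joint.betas, baseline)
    dist = population_joint_distribution(rafs, ld, mc_sample_size, rng, variant_ids=ids)
    point = paf_joint(betas, dist)

    ci_low = ci_high = None
    draws = None
    if compute_ci and n_boot >= 2:
        ci_low, ci_high, draws = bootstrap_ci(
            oriented, ld, trait=trait, n_boot=n_boot, seed=rng,
            mc_sample_size=mc_sample_size, or_correction=or_correction,
            paf_point=point)

    h2, h2l = _identity_h2(point, betas, dist, trait)
    settings = {"mc_sample_size": mc_sample_size, "n_boot": n_boot if compute_ci else 0,
                "seed": seed if isinstance(seed, int) else None,
                "or_correction": or_correction, "y_bar": y_bar}
    return PafEstimate(variant_ids=ids, paf_point=point, betas=betas,
                       ci_low=ci_low, ci_high=ci_high, boot_draws=draws,
                       h2_observed=h2, h2_liability=h2l, settings=settings)


def bootstrap_ci(variants: Sequence[VariantSummary], ld: np.ndarray | None,
                 trait: TraitSpec | None = None, n_boot: int = DEFAULT_N_BOOT,
                 seed=None, mc_sample_size: int = DEFAULT_MC_SAMPLE_SIZE,
                 or_correction: bool = False,
                 paf_point: float | None = None
                 ) -> tuple[float, float, np.ndarray]:
    """Step (5): parametric-bootstrap 95% CI for the joint PAF.

    Each replicate redraws every marginal log-OR independently from its normal
    sampling distribution, recomputes the implied score statistics, and reruns
    steps (2)-(4).  The CI is point +/- 1.96 * sd(bootstrap PAFs), truncated
    to [0, 1].
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    oriented, effects, _, fractions = _marginal_inputs(variants)
    rafs = np.array([v.raf for v in oriented])
    y_bar = float(np.mean(fractions))
    ns = np.array([v.n_total for v in oriented], dtype=float)
    ses = np.array([e.se_log_or for e in effects])
    beta_hats = np.array([e.log_or for e in effects])
    baseline = trait.baseline_risk if (or_correction and trait is not None) else None

    draws = np.empty(n_boot)
    for b in range(n_boot):
        beta_s = rng.normal(beta_hats, ses)
        corr_s = (beta_s / ses) / np.sqrt(ns)
        y, genotypes = sample_trait_and_genotypes(y_bar, rafs, corr_s, ld,
                                                  mc_sample_size, rng)
        params = _fit_logistic_grouped(y, genotypes)
        betas_b = _corrected_betas(params[1:], baseline)
        dist_b = population_joint_distribution(rafs, ld, mc_sample_size, rng)
        draws[b] = paf_joint(betas_b, dist_b)

    if paf_point is None:
        paf_point = float(np.mean(draws))
    sd = float(np.std(draws, ddof=1))
    ci_low = max(0.0, paf_point - 1.96 * sd)
    ci_high = min(1.0, paf_point + 1.96 * sd)
    return ci_low, ci_high, draws


def paf_single_from_summary(vs: VariantSummary, trait: TraitSpec | None = None,
                            n_boot: int = DEFAULT_N_BOOT, seed=None,
                            or_correction: bool = False,
                            compute_ci: bool = True) -> PafEstimate:
    """Closed-form single-variant PAF from summary statistics, with bootstrap CI.

    The OR stands in for the per-allele RR (rare disease), optionally corrected
    via OR/(1-P0+OR*P0); the bootstrap redraws the log-OR from N(beta, se^2)
    and re-evaluates the closed-form PAF — no Monte-Carlo sampling is needed
    for one variant.
    """
    v = orient_risk_allele(vs)
    baseline = trait.baseline_risk if (or_correction and trait is not None) else None
    if or_correction and baseline is None:
        raise ValueError("or_correction requires a TraitSpec with baseline_risk")

    def one_paf(log_or: float) -> float:
        rr = or_to_rr(math.exp(log_or), baseline) if baseline is not None \
            else math.exp(log_or)
        if (rr if isinstance(rr, float) else rr.rr_per_allele) < 1.0:
            return 0.0  # a bootstrap draw crossed the null; PAF floors at 0
        return paf_single(v.raf, rr, v.effect_model)

    beta_hat = math.log(v.or_point)
    point = one_paf(beta_hat)
    ci_low = ci_high = None
    draws = None
    if compute_ci and n_boot >= 2:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        se = effect_from_summary(v).se_log_or
        draws = np.array([one_paf(b) for b in rng.normal(beta_hat, se, size=n_boot)])
        sd = float(np.std(draws, ddof=1))
        ci_low = max(0.0, point - 1.96 * sd)
        ci_high = min(1.0, point + 1.96 * sd)

    beta_used = math.log(or_to_rr(v.or_point, baseline).rr_per_allele) \
        if baseline is not None else beta_hat
    dist = GenotypeDistribution.from_hwe([v.raf], [v.variant_id])
    h2, h2l = _identity_h2(point, np.array([beta_used]), dist, trait)
    settings = {"n_boot": n_boot if compute_ci else 0,
                "seed": seed if isinstance(seed, int) else None,
                "or_correction": or_correction}
    return PafEstimate(variant_ids=[v.variant_id], paf_point=point,
                       betas=np.array([beta_used]), ci_low=ci_low, ci_high=ci_high,
                       boot_draws=draws, h2_observed=h2, h2_liability=h2l,
                       settings=settings)
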