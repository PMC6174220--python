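"""Summary-statistics Monte-Carlo estimator: joint effects, joint PAF, bootstrap."""

import math

import numpy as np
import pytest

from genepaf.core_paf import VariantSummary, paf_single, paf_product_independent
from genepaf.heritability import TraitSpec
from genepaf.joint_mc import (bootstrap_ci, corr_from_ld_r2, estimate_joint_effects,
                              paf_correlated, paf_single_from_summary,
                              population_joint_distribution)


def _synthetic_variant(variant_id="v1", raf=0.3, or_point=1.25, se=None,
                       n_cases=5000, n_controls=5000):
    """Summary record whose default se is the score-statistic standard error
    1/sqrt(N ybar(1-ybar) Var(X)) — internally consistent, so the implied
    Corr(Y, X) round-trips through the simulate-and-refit pipeline."""
    n = n_cases + n_controls
    ybar = n_cases / n
    if se is None:
        se = 1.0 / math.sqrt(n * ybar * (1 - ybar) * 2 * raf * (1 - raf))
    b = math.log(or_point)
    return VariantSummary(variant_id, raf, or_point,
                          ci_low=math.exp(b - 1.96 * se),
                          ci_high=math.exp(b + 1.96 * se),
                          n_cases=n_cases, n_controls=n_controls)


class TestJointEffects:
    def test_single_variant_recovers_marginal(self):
        vs = _synthetic_variant()
        joint = estimate_joint_effects([vs], None, mc_sample_size=100_000, seed=31)
        # logistic se at this n/prevalence is ~0.01; allow 3 MC standard errors
        assert joint.betas[0] == pytest.approx(math.log(1.25), abs=0.033)

    def test_independent_pair_needs_no_adjustment(self):
        v1 = _synthetic_variant("v1", 0.3, 1.25)
        v2 = _synthetic_variant("v2", 0.4, 1.15)
        joint = estimate_joint_effects([v1, v2], np.eye(2),
                                       mc_sample_size=200_000, seed=37)
        assert joint.betas[0] == pytest.approx(math.log(1.25), abs=0.03)
        assert joint.betas[1] == pytest.approx(math.log(1.15), abs=0.03)

    def test_positive_ld_shrinks_joint_effects(self, ld_pair):
        variants, r2 = ld_pair
        joint = estimate_joint_effects(variants, corr_from_ld_r2(r2),
                                       mc_sample_size=200_000, seed=41)
        marginals = [math.log(v.or_point) for v in variants]
        assert joint.betas[0] < marginals[0]
        assert joint.betas[1] < marginals[1]

    def test_missing_study_size_rejected(self):
        vs = VariantSummary("v", 0.3, 1.2, 1.1, 1.3)
        with pytest.raises(ValueError, match="n_cases"):
            estimate_joint_effects([vs], None, seed=1)


class TestPopulationDistribution:
    def test_single_variant_hwe(self):
        dist = population_joint_distribution([0.27], None, 100_000, seed=43)
        np.testing.assert_allclose(dist.marginal(0), [0.5329, 0.3942, 0.0729],
                                   atol=0.006)

    def test_ld_zero_factorises(self):
        dist = population_joint_distribution([0.3, 0.5], np.eye(2), 100_000, seed=47)
        product = np.outer(dist.marginal(0), dist.marginal(1))
        joint = np.zeros((3, 3))
        for row, p in zip(dist.support, dist.pmf):
            joint[row[0], row[1]] = p
        assert np.abs(joint - product).sum() < 0.01  # total variation x2

    def test_positive_ld_concentrates_double_homozygotes(self):
        r = math.sqrt(0.14)
        dist = population_joint_distribution([0.36, 0.32],
                                             np.array([[1, r], [r, 1]]),
                                             200_000, seed=53)
        p22 = float(dist.pmf[(dist.support == [2, 2]).all(axis=1)].sum())
        indep = dist.marginal(0)[2] * dist.marginal(1)[2]
        assert p22 > indep


class TestPafCorrelated:
    def test_single_variant_matches_closed_form(self):
        # oracle equivalence of the Monte-Carlo path at K=1
        for raf, orp in [(0.2, 1.2), (0.4, 1.35)]:
            vs = _synthetic_variant("v", raf, orp)
            est = paf_correlated([vs], None, mc_sample_size=100_000,
                                 seed=59, compute_ci=False)
            assert est.paf_point == pytest.approx(paf_single(raf, orp), abs=0.012)

    def test_ld_zero_matches_independence_product(self):
        v1 = _synthetic_variant("v1", 0.3, 1.25)
        v2 = _synthetic_variant("v2", 0.4, 1.15)
        est = paf_correlated([v1, v2], np.eye(2), mc_sample_size=200_000,
                             seed=61, compute_ci=False)
        expected = paf_product_independent(
            [paf_single(0.3, 1.25), paf_single(0.4, 1.15)])
        assert est.paf_point == pytest.approx(expected, abs=0.015)

    def test_or_correction_reduces_paf(self):
        vs = _synthetic_variant()
        trait = TraitSpec(prevalence=0.08, baseline_risk=0.07)
        raw = paf_correlated([vs], None, trait, mc_sample_size=100_000,
                             seed=67, compute_ci=False)
        corrected = paf_correlated([vs], None, trait, mc_sample_size=100_000,
                                   seed=67, compute_ci=False, or_correction=True)
        assert corrected.paf_point < raw.paf_point

    def test_protective_allele_oriented_automatically(self):
        protective = _synthetic_variant("v", raf=0.6, or_point=1 / 1.25)
        flipped = _synthetic_variant("v", raf=0.4, or_point=1.25)
        est = paf_correlated([protective], None, mc_sample_size=100_000, seed=71,
                             compute_ci=False)
        ref = paf_correlated([flipped], None, mc_sample_size=100_000, seed=71,
                             compute_ci=False)
        assert est.paf_point == pytest.approx(ref.paf_point, abs=1e-12)
        assert est.paf_point == pytest.approx(paf_single(0.4, 1.25), abs=0.012)

    def test_estimate_serialises(self):
        vs = _synthetic_variant()
        est = paf_correlated([vs], None, TraitSpec(prevalence=0.01),
                             mc_sample_size=50_000, n_boot=10, seed=73)
        d = est.to_dict()
        assert set(d) >= {"paf", "ci_low", "ci_high", "h2_observed",
                          "h2_liability", "settings"}
        est.to_json()


class TestBootstrap:
    def test_reproducible_by_seed(self):
        vs = _synthetic_variant()
        a = bootstrap_ci([vs], None, n_boot=25, seed=79, mc_sample_size=20_000)
        b = bootstrap_ci([vs], None, n_boot=25, seed=79, mc_sample_size=20_000)
        np.testing.assert_array_equal(a[2], b[2])

    def test_ci_width_scales_with_se(self):
        narrow = _synthetic_variant(se=0.02)
        wide = _synthetic_variant(se=0.04)
        # closed-form single-variant path isolates the delta-method scaling
        est_n = paf_single_from_summary(narrow, n_boot=400, seed=83)
        est_w = paf_single_from_summary(wide, n_boot=400, seed=83)
        width_n = est_n.ci_high - est_n.ci_low
        width_w = est_w.ci_high - est_w.ci_low
        assert width_w / width_n == pytest.approx(2.0, rel=0.2)

    def test_tiny_se_tiny_ci(self):
        vs = _synthetic_variant(se=1e-5)
        est = paf_single_from_summary(vs, n_boot=100, seed=89)
        assert est.ci_high - est.ci_low < 1e-4

    def test_n_boot_validation(self):
        with pytest.raises(ValueError):
            bootstrap_ci([_synthetic_variant()], None, n_boot=1, seed=1)


class TestSingleVariantSummary:
    def test_reported_variant_point_and_ci(self, lung_variants):
        rs7086803 = lung_variants[0]
        est = paf_single_from_summary(rs7086803, n_boot=1000, seed=97)
        assert round(est.paf_point, 3) == 0.136
        # reported bootstrap CI (0.104, 0.165)
        assert est.ci_low == pytest.approx(0.104, abs=0.01)
        assert est.ci_high == pytest.approx(0.165, abs=0.01)

    def test_or_correction_applied(self):
        vs = _synthetic_variant(or_point=1.5)
        trait = TraitSpec(prevalence=0.12, baseline_risk=0.1)
        est = paf_single_from_summary(vs, trait, or_correction=True,
                                      compute_ci=False)
        rr = 1.5 / (1 - 0.1 + 1.5 * 0.1)
        assert est.paf_point == pytest.approx(paf_single(0.3, rr), abs=1e-12)
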