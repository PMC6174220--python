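"""Closed-form PAF: single variant, joint enumeration, product rule."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genepaf.core_paf import (GenotypeDistribution, OrientationError,
                              RelativeRisk, VariantSummary, orient_risk_allele,
                              paf_joint, paf_product_independent, paf_single)


def brute_force_paf(betas, rafs):
    """Independent-variant oracle: triple loop over the 3^K support."""
    total = 0.0
    for combo in itertools.product((0, 1, 2), repeat=len(betas)):
        prob = 1.0
        for g, p in zip(combo, rafs):
            prob *= [(1 - p) ** 2, 2 * p * (1 - p), p * p][g]
        total += math.exp(sum(b * g for b, g in zip(betas, combo))) * prob
    return 1.0 - 1.0 / total


class TestPafSingle:
    @pytest.mark.parametrize("raf, rr, expected_3dp", [
        (0.27, 1.28, 0.136),          # lung-cancer variant rs7086803
        (0.50, 1 / 0.85, 0.156),      # rs9387478 after re-orientation
        (0.36, 1.17, 0.112),          # rs2395185
    ])
    def test_reported_variants(self, raf, rr, expected_3dp):
        assert round(paf_single(raf, rr), 3) == expected_3dp

    def test_null_effect_gives_zero(self):
        assert paf_single(0.4, 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_moderate_effect_value(self):
        # direct evaluation: p=0.5, RR=e^0.3
        e = math.exp(0.3)
        denom = 0.25 + 0.5 * e + 0.25 * e * e
        assert paf_single(0.5, e) == pytest.approx(1 - 1 / denom, abs=1e-12)
        assert round(paf_single(0.5, e), 4) == 0.2756

    def test_protective_rr_requires_reorientation(self):
        with pytest.raises(OrientationError):
            paf_single(0.3, 0.85)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            paf_single(-0.1, 1.2)
        with pytest.raises(ValueError):
            paf_single(float("nan"), 1.2)
        with pytest.raises(ValueError):
            RelativeRisk(-1.0)

    def test_monotone_in_rr_and_raf(self):
        rafs = np.linspace(0.05, 0.95, 10)
        rrs = np.linspace(1.05, 3.0, 10)
        for raf in rafs:
            vals = [paf_single(raf, rr) for rr in rrs]
            assert np.all(np.diff(vals) > 0)
        for rr in rrs:
            vals = [paf_single(raf, rr) for raf in rafs]
            assert np.all(np.diff(vals) > 0)

    def test_dominant_recessive_orderings(self):
        # genotype multipliers (1, rr, rr^2) / (1, rr, rr) / (1, 1, rr) order
        # the mean relative risk as additive > dominant > recessive
        raf, rr = 0.3, 1.5
        add = paf_single(raf, rr, "additive")
        dom = paf_single(raf, rr, "dominant")
        rec = paf_single(raf, rr, "recessive")
        assert rec < dom < add


class TestOrientation:
    def test_protective_allele_flips(self):
        vs = VariantSummary("rs9387478", 0.50, 0.85, 0.81, 0.90)
        flipped = orient_risk_allele(vs)
        assert flipped.raf == pytest.approx(0.50)
        assert flipped.or_point == pytest.approx(1 / 0.85)
        assert flipped.ci_low == pytest.approx(1 / 0.90)
        assert flipped.ci_high == pytest.approx(1 / 0.81)
        assert round(paf_single(flipped.raf, flipped.or_point), 3) == 0.156

    def test_reciprocal_arithmetic(self):
        vs = VariantSummary("v", 0.2, 0.5, 0.4, 0.625)
        flipped = orient_risk_allele(vs)
        assert (flipped.raf, flipped.or_point) == (0.8, 2.0)
        assert flipped.ci_low == pytest.approx(1.6)
        assert flipped.ci_high == pytest.approx(2.5)

    def test_risk_allele_unchanged(self):
        vs = VariantSummary("v", 0.3, 1.2)
        assert orient_risk_allele(vs) is vs

    @given(raf=st.floats(0.01, 0.99), or_point=st.floats(0.2, 5.0))
    @settings(max_examples=60, derandomize=True)
    def test_idempotent(self, raf, or_point):
        # once oriented to the risk allele, further applications change nothing
        once = orient_risk_allele(VariantSummary("v", raf, or_point))
        twice = orient_risk_allele(once)
        assert once.or_point >= 1.0
        assert twice == once
        assert once.or_point == pytest.approx(max(or_point, 1 / or_point))


class TestGenotypeDistribution:
    def test_hwe_marginal(self):
        dist = GenotypeDistribution.from_hwe([0.27])
        np.testing.assert_allclose(dist.marginal(0),
                                   [0.73 ** 2, 2 * 0.27 * 0.73, 0.27 ** 2])

    def test_pmf_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GenotypeDistribution(["a"], [[0], [1], [2]], [0.5, 0.4, 0.2])

    def test_enumeration_cap(self):
        with pytest.raises(ValueError, match="cap"):
            GenotypeDistribution.from_hwe([0.5] * 16)

    def test_from_samples_roundtrip(self, rng):
        g = rng.binomial(2, [0.2, 0.5], size=(5000, 2))
        dist = GenotypeDistribution.from_samples(g)
        assert dist.pmf.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(dist.marginal(0),
                                   np.bincount(g[:, 0], minlength=3) / 5000)


class TestPafJoint:
    def test_against_brute_force_oracle(self):
        betas, rafs = (0.3, 0.2, 0.1), (0.1, 0.2, 0.3)
        dist = GenotypeDistribution.from_hwe(rafs)
        assert paf_joint(betas, dist) == pytest.approx(
            brute_force_paf(betas, rafs), abs=1e-12)
        assert round(paf_joint(betas, dist), 4) == 0.1955

    def test_null_effects(self):
        dist = GenotypeDistribution.from_hwe([0.1, 0.4])
        assert paf_joint([0.0, 0.0], dist) == pytest.approx(0.0, abs=1e-15)

    @given(raf=st.floats(0.01, 0.99), beta=st.floats(0.0, 1.2))
    @settings(max_examples=60, derandomize=True)
    def test_reduces_to_single(self, raf, beta):
        dist = GenotypeDistribution.from_hwe([raf])
        assert paf_joint([beta], dist) == pytest.approx(
            paf_single(raf, math.exp(beta)), abs=1e-12)

    def test_dimension_mismatch(self):
        dist = GenotypeDistribution.from_hwe([0.1, 0.2])
        with pytest.raises(ValueError, match="effects"):
            paf_joint([0.1], dist)

    def test_product_distribution_equals_product_rule(self):
        rafs, betas = (0.15, 0.42, 0.3), (0.25, 0.1, 0.4)
        dist = GenotypeDistribution.from_hwe(rafs)
        per_variant = [paf_single(p, math.exp(b)) for p, b in zip(rafs, betas)]
        assert paf_joint(betas, dist) == pytest.approx(
            paf_product_independent(per_variant), abs=1e-12)


class TestProductRule:
    def test_reported_adjusted_product(self):
        # adjusted single-variant PAFs for the correlated 6p21.3 pair
        assert paf_product_independent([0.087, 0.061]) == pytest.approx(0.1427, abs=5e-5)

    def test_single_element_identity(self):
        assert paf_product_independent([0.3]) == pytest.approx(0.3)

    def test_three_equal(self):
        assert paf_product_independent([0.1] * 3) == pytest.approx(1 - 0.9 ** 3)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            paf_product_independent([0.5, 1.0])
        with pytest.raises(ValueError):
            paf_product_independent([-0.1])
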