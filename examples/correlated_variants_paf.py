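"""Joint PAF of two LD-correlated variants from summary statistics alone.

rs2395185 and rs3817963 (6p21.3, near HLA-DRA) were reported by two different
lung-cancer GWAS and are in LD (average r^2 = 0.14).  Their marginal ORs each
absorb part of the other's effect, so the naive product rule overstates the
joint PAF; the Monte-Carlo pipeline recovers joint (adjusted) effects first.
"""

import numpy as np

from genepaf import TraitSpec, corr_from_ld_r2, paf_correlated, paf_single
from genepaf.core_paf import orient_risk_allele, paf_product_independent
from genepaf.fixtures import LUNG_CANCER_PREVALENCE, correlated_pair

variants, r2 = correlated_pair()
trait = TraitSpec(prevalence=LUNG_CANCER_PREVALENCE)

est = paf_correlated(variants, corr_from_ld_r2(r2), trait,
                     mc_sample_size=100_000, n_boot=300, seed=2)

marginal = [paf_single(v.raf, v.or_point) for v in map(orient_risk_allele, variants)]
naive = paf_product_independent(marginal)

print(f"marginal ORs         : {[v.or_point for v in variants]}")
print(f"adjusted (joint) ORs : {np.round(np.exp(est.betas), 3).tolist()}")
print(f"naive product PAF    : {naive:.3f}   (ignores the LD)")
print(f"joint PAF            : {est.paf_point:.3f}  (95% CI {est.ci_low:.3f}-{est.ci_high:.3f})")
print(f"h2 observed/liability: {est.h2_observed:.3g} / {est.h2_liability:.3g}")
print()
print("The adjusted ORs are smaller than the marginal ones because the variants")
print("are positively correlated; the joint PAF is correspondingly below the")
print("independence product of the marginal PAFs.")
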