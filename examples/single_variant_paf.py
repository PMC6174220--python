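"""Single-variant PAF with a parametric-bootstrap CI and linked heritability.

Uses the bundled lung-cancer GWAS summary statistics: rs7086803 has risk-allele
frequency 0.27 and per-allele OR 1.28 (95% CI 1.21-1.35).  Lung cancer in this
population is rare (prevalence ~0.0024), so the OR stands in for the RR.
"""

from genepaf import TraitSpec, paf_single_from_summary
from genepaf.fixtures import LUNG_CANCER_PREVALENCE, lung_gwas_variants

rs7086803 = lung_gwas_variants()[0]
trait = TraitSpec(prevalence=LUNG_CANCER_PREVALENCE)

est = paf_single_from_summary(rs7086803, trait, n_boot=1000, seed=1)

print(f"variant          : {est.variant_ids[0]}")
print(f"PAF              : {est.paf_point:.3f}  (95% CI {est.ci_low:.3f}-{est.ci_high:.3f})")
print(f"h2 (observed)    : {est.h2_observed:.3g}")
print(f"h2 (liability)   : {est.h2_liability:.3g}")
print()
print("About 14% of lung-cancer risk in this population is attributable to the")
print("risk allele, even though it explains only ~0.006% of the variance of the")
print("0/1 outcome — PAF is on the scale of sqrt(h2) times a CV ratio, so the")
print("two measures differ by orders of magnitude by construction.")
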