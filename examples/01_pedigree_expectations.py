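"""Exact pedigree IBD expectations for the bundled five-generation family.

Enumerates meiotic transmission patterns to get the probability that a
group of relatives all carry one allele copy descended from a single
ancestral copy, and the binomial risk of the control-cohort rare-variant
filter discarding a truly causal allele.
"""

from pedscreen import (
    CohortSpec,
    expected_all_share_fraction,
    hfm_pedigree,
    min_observation_probability,
    relationship_coefficients,
)

ped = hfm_pedigree()

trio = expected_all_share_fraction(ped, ["III.1", "V.2", "V.3"])
print(f"grandmother + two cousins all-share: {100 * trio.value:.1f}% "
      f"({trio.method}, {trio.n_meioses} meioses)")
# 12.5% of the autosome is expected to be shared by all three, so an IBD
# filter keeps ~1/8 of candidate variants.

quad = expected_all_share_fraction(ped, ["III.1", "III.3", "V.2", "V.3"])
print(f"four genotyped affecteds all-share:  {100 * quad.value:.4f}% "
      f"(prints as {100 * quad.value:.1f}%)")
# Adding the grandmother's first cousin shrinks the shared fraction to
# 1/64: a variant surviving this filter is very unlikely by chance.

prior = relationship_coefficients(ped, "III.1", "III.3")
print(f"first cousins Cotterman (k0,k1,k2) = "
      f"({prior.k0:.4g}, {prior.k1:.4g}, {prior.k2:.4g}), "
      f"{prior.n_meioses} meioses, kinship = {prior.kinship:.4g}")

risk = min_observation_probability(0.001, CohortSpec(n_individuals=21))
print(f"P(MAF 0.1% allele seen >=2x in 42 control chromosomes) = {risk:.3e}")
# Below 1e-3: removing cohort-recurrent alleles almost never discards a
# genuinely rare causal variant.
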