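"""Broad-sense heritability and the genetic variance explained by one locus.

Uses replicate patch-area measurements of a simulated cross: H^2 compares
the variance of segregant means with the sampling variance of those means,
and zero-centering the two allele subpopulations at the major locus
measures how much genetic variance that locus explains.
"""

from crossqtl import (
    heritability,
    locus_variance,
    simulate_cross,
    study_like_params,
)

params = study_like_params(seed=5)
truth, _, pheno = simulate_cross(params)

ypd = pheno[(pheno["condition"] == "YPD") & (pheno["day"] == 4)]
vc = heritability(ypd, min_area=5.0)

major = truth.qtl_effects[0].marker
lv = locus_variance(vc.means, truth.genotypes[major], vc)

print(f"sigma2_s (variance of segregant means): {vc.sigma2_s:7.2f} mm^4")
print(f"sigma2_w (within-strain variance):      {vc.sigma2_w:7.2f} mm^4")
print(f"sigma2_e = sigma2_w / n_bar:            {vc.sigma2_e:7.2f} mm^4  (n_bar = {vc.n_bar:.2f})")
print(f"H^2 = 1 - sigma2_e / sigma2_s:          {vc.H2:7.3f}")
print(f"variance explained by {major}: {lv.explained:.2f} mm^4 "
      f"({lv.proportion_genetic:.2f} of the genetic variance)")
# With four replicates per strain the sampling variance of a mean is small
# next to the genetic spread, so H^2 is high; the major locus accounts for
# about a quarter of the genetic variance on rich medium, the polygenic
# background for the rest.
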