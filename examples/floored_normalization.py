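"""Reconstruct a floor-censored phenotype distribution.

On harsh media, poorly growing strains pile up at a hard measurement floor,
so each allele subpopulation looks like a normal distribution with its left
tail collapsed.  The normalization fits the normal to the part of the
distribution well separated from the floor (>5 mm^2) and re-draws every
strain at its own quantile, restoring an uncensored sample.
"""

import pandas as pd

from crossqtl import quantile_normalize_floored, simulate_cross, study_like_params

params = study_like_params(seed=8)
truth, _, pheno = simulate_cross(params)

rapa = pheno[(pheno["condition"] == "rapamycin") & (pheno["day"] == 4)]
means = rapa.groupby("strain")["area"].mean()
allele = truth.genotypes[truth.qtl_effects[0].marker]

print("subpopulation means on rapamycin (mm^2):")
normalized = {}
for a in ("P1", "P2"):
    sub = means[allele == a]
    norm = quantile_normalize_floored(sub, floor_cut=5.0)
    normalized[a] = norm
    print(f"  {a}: raw {sub.mean():6.2f}  (floored fraction {(sub < 5).mean():.2f})"
          f"  normalized {norm.mean():6.2f}")

norm_all = pd.concat(normalized.values())
diff = normalized["P1"].mean() - normalized["P2"].mean()
print(f"normalized subpopulation difference: {diff:.1f} mm^2 (planted: 18.7)")
# Raw means understate the carrier penalty because censored strains cannot
# fall below the floor; the fitted-normal re-draw removes that bias while
# preserving every strain's rank.
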