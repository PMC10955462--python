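"""Chi-squared fit of observed genotype tables to model expectations.

Builds observed genotype counts for the two trimorphic populations and the
monomorphic homostyle population from survey counts plus the sequenced
haploid/diploid homostyle splits, then tests them against the recursion's
expected frequencies over the viability x generation grid with Bonferroni
correction.
"""

from slocus.crosby import PopulationState, expected_frequency_grid
from slocus.fit import fit_grid, observed_genotype_table

observed = [
    observed_genotype_table("EN4-T", (3, 4, 10), (0.40, 0.60)),
    observed_genotype_table("EN5-T", (4, 5, 10), (0.60, 0.40)),
    observed_genotype_table("EN6-M", (0, 0, 11), (0.00, 1.00)),
]
for t in observed:
    freqs = {g: round(f, 2) for g, f in t.frequencies.items()}
    print(f"{t.population}: n={t.total} observed {freqs}")

grid = expected_frequency_grid(PopulationState(0.495, 0.495, 0.01, 0.0))
results = fit_grid(observed, grid, alpha=0.05)

compatible = results[results.compatible]
print(f"\n{len(compatible)} of {len(results)} (population, v, generation) "
      "cells are compatible (Bonferroni-adjusted p >= 0.05):")
print(compatible[["population", "v", "generation", "chi2", "p_adjusted"]]
      .round(3).to_string(index=False))
# A non-significant cell means the observed genotype frequencies are
# consistent with the recursion under that viability after that many
# generations of homostyle spread.
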