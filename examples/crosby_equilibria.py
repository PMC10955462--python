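"""Genotype-frequency dynamics of the loss of distyly.

Iterates the four-genotype recursion (pin 0/0, thrum S/0, homostyle S*/0
and S*/S*) to equilibrium under equal (v=1) and reduced (v=0.65) viability
of S*/S* offspring, and prints the expected-frequency grid the observed
tables are tested against.
"""

from slocus.crosby import (
    ModelParams,
    PopulationState,
    expected_frequency_grid,
    find_equilibrium,
)

start = PopulationState(p=0.45, q=0.45, r=0.05, s=0.05)

for v in (1.0, 0.65):
    eq, converged = find_equilibrium(start, ModelParams(v=v))
    print(f"v = {v:<4}  equilibrium after {eq.generation} generations "
          f"(converged={converged}):")
    print(f"  p(0/0)={eq.p:.4f}  q(S/0)={eq.q:.4f}  "
          f"r(S*/0)={eq.r:.4f}  s(S*/S*)={eq.s:.4f}")

# With equal viability the double homostyle S*/S* fixes; with a 35% deficit
# thrums disappear but pins persist and the two homostyle genotypes
# segregate at roughly equal frequencies.

grid = expected_frequency_grid(PopulationState(0.495, 0.495, 0.01, 0.0))
print("\nExpected frequencies over the (viability x generation) grid:")
print(grid.round(3).to_string(index=False))
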