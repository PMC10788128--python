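"""Compute the four reliability indices on one dataset.

Simulates a 5,000-respondent sample from a congeneric population with
true reliability 0.731 (one factor, unequal loadings; the default
0.3...0.8 pattern hits 0.731 at k=6 without rescaling), then computes
Cronbach's alpha, omega-total, and both greatest-lower-bound variants
from its sample correlation matrix.
"""

import numpy as np

from relmc import (
    build_congeneric,
    compute_all,
    cronbach_alpha,
    draw_sample,
    sample_correlation,
)

population = build_congeneric(k=6, target_reliability=0.731)
print("population loadings:", np.round(population.loadings, 3))
print(f"population alpha:    {cronbach_alpha(population.sigma).value:.3f}")
print(f"population omega:    {population.true_reliability:.3f}")

sample = draw_sample(population, n=5000, rng=np.random.default_rng(7))
R = sample_correlation(sample)
print("\nsample estimates (n = 5000):")
for name, iv in compute_all(R).items():
    print(f"  {name:6s} {iv.value:.3f}  ({iv.status})")
print(
    "\nUnder unequal loadings alpha targets a value below the true"
    "\nreliability; the factor-based indices sit at or above it, the"
    "\nmany-factor fits (omega with m=3, glb with m=k/2) by the most —"
    "\nthey absorb sampling noise into communalities even at large n."
)
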