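"""Grid-search the rank cutoff M_cut that minimizes the penalty.

The planted cohort has 300 informative peaks per sample above 200 noise
peaks; every cutoff retaining the informative margin clusters perfectly, so
the minimizing plateau contains 300 and its midpoint is selected.
"""

import hamclust as hc
from hamclust.synthetic import CohortSpec, simulate_cohort

spec = CohortSpec(seed=0)
ranked, cohort = simulate_cohort(spec)

grid = [100, 200, 300, 400, 500, 600]
res = hc.grid_search({spec.p_G: ranked}, cohort, grid, spec.layout, method="ward")

print(res.summary.to_string(index=False))
print(f"minimum penalty: {res.min_penalty}")
print(f"minimizing plateau: {[m for m, _ in res.argmin]}")
print(f"selected (M_cut*, p_G*): {res.selected}  "
      "(plateau midpoint at the best calling threshold)")
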