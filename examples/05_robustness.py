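"""Penalty stability under random loss of reads.

Reads are simulated inside each sample's peaks, a fraction r is removed
uniformly at random, peaks are re-called with the toy pileup caller, and the
whole pipeline is re-run at fixed (M_cut, p_G).  Small losses leave the
penalty at its baseline; near-total loss destroys the cluster structure.
"""

import hamclust as hc
from hamclust.synthetic import (
    CohortSpec, simulate_cohort, simulate_reads, toy_peak_caller,
)

spec = CohortSpec(samples_per_type=2, k_info=60, k_noise=30,
                  types=("HSC", "B", "Mono"), seed=1)
ranked, cohort = simulate_cohort(spec)
reads = {s: simulate_reads(r, spec.layout, depth_per_peak=15, seed=i)
         for i, (s, r) in enumerate(ranked.items())}
caller = lambda rs, pg: toy_peak_caller(rs, spec.layout, coverage_threshold=5, p_G=pg)

table = hc.robustness_curve(
    reads, r_values=[0.0, 0.01, 0.1, 0.5, 0.95], seed=3, peak_caller=caller,
    M_cut=100, p_G=spec.p_G, cohort=cohort, layout=spec.layout, n_replicates=3,
)
print(table.groupby("r")["lambda"].agg(["mean", "min", "max"]))
print(f"(penalty bounds for this cohort: {hc.penalty_bounds(cohort)})")
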