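"""Compute the fixed-order summary-statistic vector of a dataset.

The same vector is computed for the observed panel and for every simulated
dataset in a reference table: per-group polymorphism and heterozygosity,
pairwise Hudson FST and Nei distance, and the f3/f4 admixture block.
"""

from hybridabc.sumstats import STAT_REGISTRY_VERSION, compute_summaries
from hybridabc.synthetic_data import make_pod, study_design

design = study_design("cluster", n_loci=80)
pod, truth = make_pod(1, design, rng=3)

stats = compute_summaries(pod)
print(f"statistic registry {STAT_REGISTRY_VERSION}: {stats.size} values\n")
print(stats.round(4).to_string())
print(f"\ntrue scenario {truth['scenario_id']}, r1 = {truth['params']['r1']:.2f}")
# Negative f3_HYB_* values indicate the hybrid groups mix the two parental
# gene pools; the per-group heterozygosity block carries the drift signal
# that separates recent from glacial-period event timings.
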