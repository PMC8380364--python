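"""Enterotype-like clustering of genus-level profiles.

Aggregates the OTU table to genus level, computes root-JSD distances,
clusters with PAM across k = 2..6 and reports the Calinski-Harabasz model
selection plus each cluster's dominant genus.
"""

import microlmp as m
from microlmp.enterotype import enterotype_profile

config = m.SimulationConfig.default_fixture(seed=3)
table, taxonomy, metadata, truth = m.simulate_dataset(config)

genus = m.aggregate_by_rank(m.to_relative(table), taxonomy, "genus")
dist = m.jsd_matrix(genus)                 # sqrt-JSD: a metric on profiles
result = m.select_k(dist, range(2, 7))

print("k   CH index   mean silhouette")
for k in sorted(result.ch_by_k):
    print(f"{k}   {result.ch_by_k[k]:8.1f}   {result.silhouette_by_k[k]:.3f}")
print(f"\nselected k = {result.k_selected} (CH maximum)")

dominant = enterotype_profile(genus, result.assignments)
for cluster, genus_name in dominant.items():
    n = (result.assignments == cluster).sum()
    print(f"enterotype {cluster}: {n} pigs, dominated by {genus_name}")
# The CH index peaks at the planted two-community structure; each
# cluster's dominant genus matches the component's planted driver.
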