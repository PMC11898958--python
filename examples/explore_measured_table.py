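"""Explore the packaged 18-organophosphate index table.

Computes the Pearson correlations between the three biomimetic
endpoints, clusters the compounds on the auto-scaled indices, and names
the three-group cut low/medium/high bioaccumulation potential by
ranked lipophilicity.
"""

import bioqsrr as b
from bioqsrr.explore import bioaccumulation_groups

table = b.organophosphate_table()
print(f"{len(table)} compounds loaded")

corr = b.correlation_matrix(table)
print("\nPearson correlations between endpoints:")
print(corr.round(3))
# chi_c18 vs chi_iam is strong (lipophilicity drives phospholipid
# affinity); logk_hsa correlates more weakly - albumin binding has a
# specific component.

clustering = b.hierarchical_cluster(table)  # Ward on auto-scaled columns
labels = b.cut_tree(clustering, rule="k", k=3)
groups = bioaccumulation_groups(table, clustering, labels)
print("\nBioaccumulation groups (by ranked mean CHI_C18):")
for g in ("low", "medium", "high"):
    members = sorted(groups.index[groups == g])
    print(f"  {g:6s}: {', '.join(members)}")

b.heatmap_export(table, clustering, "scratch_heatmap.svg")
print("\nheat map written to scratch_heatmap.svg (+ companion CSV)")
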