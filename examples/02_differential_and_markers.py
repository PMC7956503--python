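"""DAve/DCI differential expression and discriminant marker selection.

Continues from a simulated cohort: screens proteins by one-way ANOVA
F-ratio across the proteome groups, calls DEPs with the DAve/DCI indices,
intersects the two sets and nominates a compact 6-protein panel.
"""

from uvep import (
    align_runs,
    average_replicates,
    cluster_subjects,
    cut_tree,
    f_ratio_select,
    filter_by_frequency,
    fit_lda,
    classify_lda,
    intersect_panels,
    normalize_total_spc,
    pairwise_deps,
    select_top_markers,
)
from uvep.simulate import SimConfig, simulate_spc

run_table, truth = simulate_spc(SimConfig(seed=1))
aspc = average_replicates(
    filter_by_frequency(normalize_total_spc(align_runs(run_table)), 0.25),
    run_table.pairing(),
)
groups = cut_tree(cluster_subjects(aspc, transform="log2p1"), k=3)

records = f_ratio_select(aspc, groups.labels, f_min=5, p_max=0.01)
selected = {r.accession for r in records if r.selected}
print(f"F-ratio screen (F >= 5, p <= 0.01): {len(selected)} discriminant proteins")

deps = pairwise_deps(aspc, groups.labels, dave_threshold=0.2, dci_threshold=5)
print(f"DAve/DCI DEPs (|DAve| > 0.2, |DCI| > 5): {len(deps.proteins)} proteins "
      f"over {len(deps.comparisons)} pairwise comparisons")

panel = intersect_panels(selected, deps, aspc, groups.labels)
print(f"discriminant/DEP overlap: {len(panel.proteins)} proteins "
      f"({panel.n_lda_only} screen-only, {panel.n_dep_only} DEP-only)")

top = select_top_markers(panel, deps, k=6)
print("nominated 6-protein panel (group-balanced, ranked by max |DAve|):")
print(top.group_means.round(2))  # per-group mean aSpC of each panel protein

model = fit_lda(aspc.with_values(aspc.values.loc[sorted(selected)], "discriminants"),
                groups.labels)
assigned = classify_lda(model, aspc.with_values(aspc.values.loc[sorted(selected)], "d"))
agree = sum(assigned[s] == groups.labels[s] for s in assigned) / len(assigned)
# Mahalanobis nearest-centroid under the shrunk common covariance
print(f"LDA training agreement with clustering groups: {agree:.2f}")
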