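"""Alpha-value subject typing and respiratory-impedance linkage.

Types each subject by its alpha composition (panel-relative abundances)
against group reference centroids, then tests whether the proteome groups
differ in FOT impedance Z-scores (Kruskal–Wallis + Dunn/Holm post-hoc).
"""

from uvep import (
    align_runs,
    alpha_centroids,
    alpha_profile,
    assign_by_alpha,
    average_replicates,
    cluster_subjects,
    compare_groups_fot,
    cut_tree,
    f_ratio_select,
    filter_by_frequency,
    intersect_panels,
    normalize_total_spc,
    pairwise_deps,
    select_top_markers,
)
from uvep.simulate import SimConfig, simulate_fot, simulate_spc

cfg = SimConfig(seed=1)
run_table, truth = simulate_spc(cfg)
aspc = average_replicates(
    filter_by_frequency(normalize_total_spc(align_runs(run_table)), 0.25),
    run_table.pairing(),
)
groups = cut_tree(cluster_subjects(aspc, transform="log2p1"), k=3)

selected = {r.accession for r in f_ratio_select(aspc, groups.labels) if r.selected}
deps = pairwise_deps(aspc, groups.labels)
panel = select_top_markers(intersect_panels(selected, deps, aspc, groups.labels), deps, k=6)
print(f"marker panel: {panel.proteins}")

profiles = alpha_profile(aspc, panel)
centroids = alpha_centroids(aspc, panel, groups)
typed = assign_by_alpha(profiles, centroids)
agree = sum(typed.labels[s] == groups.labels[s] for s in groups.labels) / len(groups.labels)
# the compact panel alone re-derives the full-proteome stratification
print(f"alpha typing reproduces the proteome groups for {agree:.0%} of subjects")

fot = simulate_fot(truth, noise_sd=cfg.fot_noise_sd, seed=cfg.seed + 1)
report = compare_groups_fot(fot, groups, alpha=0.05)
print("\nFOT Z-scores across proteome groups (Kruskal–Wallis):")
cols = [c for c in report["table"].columns if c.startswith(("variable", "median", "H", "p"))]
print(report["table"][cols].round(3).to_string(index=False))
pairs = report["pairwise"]["z_rrs6"]
print("\nDunn/Holm post-hoc for z_rrs6 (adjusted p):")
for (a, b), p in pairs.items():
    print(f"  {a} vs {b}: {p:.4f}")
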