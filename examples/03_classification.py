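"""TWINSPAN classification and diagnostic species of the synthetic survey.

Expands covers into pseudospecies at the standard cut levels (0/2/5/10/20 %),
runs the divisive classification, compares the terminal groups with the
planted associations and lists a few diagnostic species by phi fidelity.
"""

from sklearn.metrics import adjusted_rand_score

from phytoind import (
    CommunityScenario,
    fidelity,
    generate_indicator_table,
    generate_releves,
    make_pseudospecies,
    synoptic_table,
    twinspan,
)

scn = CommunityScenario(seed=1)
com = generate_indicator_table(scn, seed=1)
rs, labels = generate_releves(scn, com, seed=1)

psm = make_pseudospecies(rs)
print(f"{psm.binary.shape[1]} pseudospecies from {len(rs.species)} species "
      f"at cuts {psm.cut_levels}")

tree = twinspan(psm)
groups = tree.terminal_groups()
ari = adjusted_rand_score(labels[groups.index], groups)
print(f"{tree.n_groups} terminal groups; adjusted Rand index vs planted "
      f"associations = {ari:.3f}")
print("root division eigenvalue:", round(tree.root.eigenvalue, 3),
      "indicators:", tree.root.indicators[:3])

fid = fidelity(rs, groups, equalize=True)
pct, diag = synoptic_table(rs, groups, fid)
top = diag[diag.diagnostic].sort_values("phi", ascending=False).head(5)
print("\nstrongest diagnostic species (group, phi, p):")
for sp, row in top.iterrows():
    print(f"  {sp}: group {row.best_group}, phi={row.phi:.2f}, p={row.p_value:.2g}")

# An ARI near 1 means the divisive classification rebuilt the planted
# 12-association structure almost exactly; diagnostic species with high phi
# are the faithful indicators of their group.
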