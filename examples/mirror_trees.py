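"""Mirror-tree test of correlated evolution between two protein families.

Families that co-evolve share the imprint of one species tree: their
genetic distance matrices correlate strongly. Two families are simulated
on a shared tree (the co-evolving pair) and two on independent trees
(the unrelated baseline); Pearson r over the common species plus a
label-permutation p-value separates the cases.
"""

from coatmap.evodist import correlation_significance, distance_matrix, nj_tree
from coatmap.synthetic import EvolutionScenario, generate_mirror_pair

for shared in (True, False):
    fam_a, fam_b = generate_mirror_pair(EvolutionScenario(
        n_taxa=16, n_sites=500, shared_tree=shared, seed=8))
    da, db = distance_matrix(fam_a.msa), distance_matrix(fam_b.msa)
    result = correlation_significance(da, db, n_perm=999, seed=0)
    label = "shared species tree " if shared else "independent trees  "
    print(f"{label}: r = {result.r:+.3f}   permutation p = {result.p_value:.4f}")

tree = nj_tree(distance_matrix(fam_a.msa))
print("\nNJ tree of the last family (Newick):")
print(tree.newick[:90] + "...")

# Shared-tree pairs give r near 1 with p ~ 0.001; independent trees give
# r near 0 with non-significant p - the signal used to rank how strongly
# each assembly component co-evolves with the clathrin heavy chain.
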