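"""Build a TN93 + neighbor-joining tree with bootstrap supports.

Distances follow the Tamura-Nei (1993) model, which separates the two
transition classes from transversions under unequal base frequencies;
node support is the percentage of 1000 column-resampled replicates
containing the same leaf bipartition.
"""

from barcodefish import PhyloConfig, bootstrap_tree, compute_distance_matrix
from barcodefish.io import tree_to_newick
from barcodefish.simulate import SimConfig, simulate_lineages

panel, true_tree = simulate_lineages(SimConfig(seed=7, loci=("16S",)))
seqs = panel.loci["16S"]

dm = compute_distance_matrix(seqs, model="TN93")
cross = [dm.values[i, j] for i in range(5) for j in range(5, 10)]
print(f"TN93 distance between lineages: {min(cross):.3f}-{max(cross):.3f} "
      "substitutions/site")

tree = bootstrap_tree(seqs, PhyloConfig(bootstrap_replicates=1000, seed=7))
print("\nNewick (internal-node labels are bootstrap %):")
print(tree_to_newick(tree))
print(
    "\nThe split separating the two simulated lineages should carry "
    "~100% support; shallow within-lineage nodes are weakly supported "
    "because few columns distinguish them."
)
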