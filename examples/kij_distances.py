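"""All-pairs k-independent Jaccard distances on a known phylogeny.

Eight genomes are evolved along a balanced binary tree; 1-KIJ should be
smaller within clades than between them, and neighbor joining on the
matrix should recover the true topology.
"""

from deltasketch import SketchStack, pairwise_kij, phylogeny_pangenome

leaves, true_newick = phylogeny_pangenome(n_leaves=8, genome_length=4_000,
                                          branch_rate=0.03, seed=5)
stacks = [SketchStack(g, backend="exact", label=g.labels[0])
          for g in leaves]
mat = pairwise_kij(stacks)

print("1-KIJ distance matrix (PHYLIP):")
print(mat.to_phylip())
print("per-pair k* choices (first rows):")
print(mat.details[["a", "b", "kstar_a", "kstar_b", "kstar_union",
                   "kij"]].head(3).to_string(index=False))
print(f"\ntrue topology: {true_newick}")
print("Sister leaves (e.g. L01/L02) show the smallest distances; "
      "neighbor joining on this matrix reproduces the tree exactly "
      "(see the tree-recovery test).")
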