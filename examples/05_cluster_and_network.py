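"""Cluster motifs by binding-site overlap and build a TF->TF network.

Two motifs are given heavily overlapping site sets (tree distance
1 - overlap), and a toy promoter layout turns positively changing
binding sites into a directed activation cascade.
"""

from fpk.bindetect import BindingSite
from fpk.core import GenomicInterval
from fpk.motif_clustering import build_tree, cophenetic_distance, overlap_distance_matrix
from fpk.tf_network import GeneModel, create_network


def sites(motif, coords):
    return [BindingSite(GenomicInterval("chr1", s, e), motif, 0.0) for s, e in coords]


# --- clustering: A and B share 80% of their sites, C is disjoint
A = sites("A", [(1000 * i, 1000 * i + 10) for i in range(10)])
B = sites("B", [(1000 * i + 3, 1000 * i + 13) for i in range(8)]
          + [(50_000 + 100 * i, 50_000 + 100 * i + 10) for i in range(2)])
C = sites("C", [(90_000 + 100 * i, 90_000 + 100 * i + 10) for i in range(10)])
tree = build_tree(overlap_distance_matrix({"A": A, "B": B, "C": C}), cut=0.5)
print("newick:", tree.newick)
print("tree distance A-B:", round(cophenetic_distance(tree, "A", "B"), 3))
print("flat clusters at cut 0.5:", tree.clusters)
# distance 0.2 = 80% site overlap; A and B co-cluster below the 0.5 cut.

# --- network: S binds promoters of T1/T2 with rising strength; T1 binds U1
def fc_site(motif, pos, fc):
    s = BindingSite(GenomicInterval("chr1", pos, pos + 10), motif, 0.0)
    s.log2fc[("c1", "c2")] = fc
    s.bound = {"c2": True}
    return s

genes = [
    GeneModel("gene_T1", "chr1", 50_000, 55_000, "+", ("T1",)),
    GeneModel("gene_T2", "chr1", 150_000, 155_000, "+", ("T2",)),
    GeneModel("gene_U1", "chr1", 250_000, 255_000, "+", ("U1",)),
]
net = create_network(
    [fc_site("S", 49_000, 1.2), fc_site("S", 149_000, 0.4), fc_site("T1", 249_000, 0.8)],
    genes, source_motif="S", cond_pair=("c1", "c2"),
)
print("\nnetwork levels:", net.levels)
for e in net.edges:
    print(f"  {e['source']} -> {e['target']} (mean log2FC {e['mean_log2fc']:+.2f})")
# Levels are breadth-first distances from the source TF; only sites with
# log2FC > 0 (binding gaining strength) create edges.
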