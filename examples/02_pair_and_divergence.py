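"""Pair alleles through synteny blocks and quantify their divergence.

Builds a small genome, filters synteny blocks by the three retention
rules, pairs genes by reciprocal-best CDS identity, and computes NG86
Ka/Ks and 4DTv per locus.
"""

from asekit.divergence import divergence_table
from asekit.pairing import cds_similarity, filter_synteny_blocks, pair_alleles
from asekit.simulate import SimulationConfig, generate_haplotype_pair

config = SimulationConfig(n_chromosome_pairs=2, n_loci_per_chromosome=50, seed=7)
genes_a, genes_b, cds_a, cds_b, blocks, truth = generate_haplotype_pair(config)

kept = filter_synteny_blocks(blocks, truth.homolog_map)
anchors = [a for b in kept for a in b.anchor_pairs]
similarity = cds_similarity(anchors, cds_a, cds_b)
pairs, unique_a, unique_b = pair_alleles(kept, genes_a, genes_b, similarity)
print(f"{len(pairs)} allele pairs; {len(unique_a)} HA-unique, "
      f"{len(unique_b)} HB-unique genes")

table = divergence_table(pairs, cds_a, cds_b)
print(f"mean CDS identity : {table['identity'].mean():.4f}")
print(f"median Ka/Ks      : {table['ka_ks'].median():.3f}")
print(f"mean 4DTv         : {table['four_dtv'].mean():.4f}")
# Identity sits near the 0.9635 generator target; median Ka/Ks < 1
# reflects the purifying constraint applied when mutating allele CDS.
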