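"""Compare histone-mark occupancy between haplotypes and quantify
DNA methylation by context.

Computes RPKM-style H3K36me3 occupancy per gene on each haplotype,
summarizes dominant-minus-recessive differences per ASEG class, and
reports genome-wide weighted methylation levels.
"""

from asekit import ase, asymmetry
from asekit.core import AllelePair
from asekit.io import sample_metadata
from asekit.simulate import (
    SimulationConfig, generate_haplotype_pair, simulate_expression,
    simulate_marks, simulate_methylation,
)

config = SimulationConfig(n_chromosome_pairs=2, n_loci_per_chromosome=100, seed=7)
genes_a, genes_b, _, _, _, truth = generate_haplotype_pair(config)
counts, lengths = simulate_expression(config, truth)
tracks, _ = simulate_marks(config, truth, genes_a, genes_b)

tpm = ase.normalize(counts, lengths)
meta = sample_metadata(list(counts.columns))
pairs = [AllelePair(k, *truth.allele_map[k]) for k in sorted(truth.allele_map)]
calls = []
for tissue in config.tissues:
    calls += ase.classify_allelic_bias(pairs, tpm, meta, tissue)
dominance, _ = ase.aggregate_asegs(calls)

# gene body only (flank 0): the ASE-coupled enrichment acts on the body
occ_a = asymmetry.occupancy_table(
    {"H3K36me3": tracks["HA"]["H3K36me3"]}, genes_a, flank_bp=0
)
occ_b = asymmetry.occupancy_table(
    {"H3K36me3": tracks["HB"]["H3K36me3"]}, genes_b, flank_bp=0
)
summary = asymmetry.asymmetry_summary(occ_a, occ_b, pairs, dominance)
print(summary[["dominance", "mark", "n_loci", "median_diff",
               "p_vs_balanced"]].to_string(index=False))

meth = simulate_methylation(config, truth)["HA"]
for ctx in ("CG", "CHG", "CHH"):
    level = asymmetry.weighted_methylation_level(meth, context=ctx)
    print(f"weighted m{ctx} level: {level:.4f}")
# The dominant allele of biased loci carries elevated H3K36me3 (positive
# median difference, small rank-sum P); the balanced class sits near 0.
# Methylation levels echo the CG/CHG/CHH generator targets.
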