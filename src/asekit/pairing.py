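"""Allelic gene pairing from synteny blocks between the two haplotypes.

Blocks pass three filters before any gene is paired: (i) the two regions
must lie on a designated homologous chromosome pair, (ii) neither region may
be more than three times as long as the other, and (iii) the aligned
anchors must cover at least half of each region. Both boundaries are
inclusive (ratio exactly 3 and coverage exactly 0.5 are retained). Within
the retained blocks, genes are paired by reciprocal best similarity so that
each locus carries exactly one gene per haplotype.
"""

from __future__ import annotations

from .core import AllelePair, GeneModel, InputError, SyntenyBlock

MAX_LENGTH_RATIO = 3.0
MIN_COVERAGE = 0.5


def default_homolog_map(chroms_a: list[str], chroms_b: list[str]) -> dict[str, str]:
    """Pair chromosomes by identical index (HA_chr_i <-> HB_chr_i)."""
    if len(chroms_a) != len(chroms_b):
        raise InputError("haplotypes have different chromosome counts")
    return dict(zip(sorted(chroms_a), sorted(chroms_b)))


def filter_synteny_blocks(
    blocks: list[SyntenyBlock], homolog_map: dict[str, str]
) -> list[SyntenyBlock]:
    """Retain blocks satisfying the homology, length-ratio and coverage rules."""
    kept = []
    for b in blocks:
        if b.chrom_a not in homolog_map:
            raise InputError(f"block {b.block_id}: {b.chrom_a} not in homolog map")
        if b.chrom_b not in set(homolog_map.values()):
            raise InputError(f"block {b.block_id}: {b.chrom_b} not in homolog map")
        if homolog_map[b.chrom_a] != b.chrom_b:
            continue
        la, lb = b.length_a, b.length_b
        if max(la, lb) > MAX_LENGTH_RATIO * min(la, lb):
            continue
        if b.coverage_a < MIN_COVERAGE or b.coverage_b < MIN_COVERAGE:
            continue
        kept.append(b)
    return kept


def pair_alleles(
    filtered_blocks: list[SyntenyBlock],
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    similarity: dict[tuple[str, str], float],
) -> tuple[list[AllelePair], list[str], list[str]]:
    """Reciprocal-best pairing of anchor genes within retained blocks.

    Returns ``(pairs, unique_a, unique_b)`` where the unique lists contain
    genes of each haplotype matched in no retained block. Ties are broken
    deterministically by (score descending, partner id ascending).
    """
    ids_a = [g.gene_id for g in genes_a]
    ids_b = [g.gene_id for g in genes_b]
    if set(ids_a) & set(ids_b):
        raise InputError("duplicate gene ids across haplotypes")
    if len(set(ids_a)) != len(ids_a) or len(set(ids_b)) != len(ids_b):
        raise InputError("duplicate gene ids within a haplotype")

    # candidate edges: anchor pairs of retained blocks with a similarity score
    edges: dict[tuple[str, str], tuple[float, str]] = {}
    for b in filtered_blocks:
        for ga, gb in b.anchor_pairs:
            if (ga, gb) not in similarity:
                continue
            score = similarity[(ga, gb)]
            if (ga, gb) not in edges or score > edges[(ga, gb)][0]:
                edges[(ga, gb)] = (score, b.block_id)

    best_for_a: dict[str, tuple[float, str]] = {}
    best_for_b: dict[str, tuple[float, str]] = {}
    for (ga, gb), (score, _blk) in edges.items():
        cur = best_for_a.get(ga)
        if cur is None or score > cur[0] or (score == cur[0] and gb < cur[1]):
            best_for_a[ga] = (score, gb)
        cur = best_for_b.get(gb)
        if cur is None or score > cur[0] or (score == cur[0] and ga < cur[1]):
            best_for_b[gb] = (score, ga)

    pairs: list[AllelePair] = []
    paired_a: set[str] = set()
    paired_b: set[str] = set()
    for ga in sorted(best_for_a):
        score, gb = best_for_a[ga]
        if best_for_b.get(gb, (None, None))[1] != ga:
            continue
        pairs.append(
            AllelePair(
                locus_id=f"L{len(pairs) + 1:06d}",
                gene_a=ga,
                gene_b=gb,
                source_block=edges[(ga, gb)][1],
                identity=score,
            )
        )
        paired_a.add(ga)
        paired_b.add(gb)

    unique_a = [g for g in ids_a if g not in paired_a]
    unique_b = [g for g in ids_b if g not in paired_b]
    return pairs, unique_a, unique_b


def cds_similarity(
    candidate_pairs: list[tuple[str, str]],
    cds_a: dict[str, str],
    cds_b: dict[str, str],
) -> dict[tuple[str, str], float]:
    """Global CDS alignment identity for each candidate gene pair."""
    from .divergence import align_codon_pair, pair_identity

    scores = {}
    for ga, gb in candidate_pairs:
        aln = align_codon_pair(cds_a[ga], cds_b[gb])
        scores[(ga, gb)] = pair_identity(aln)
    return scores
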