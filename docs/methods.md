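# Methods

`asekit` analyses allele-specific expression (ASE) and its epigenomic
correlates in a haplotype-resolved diploid genome: two phased assemblies
(HA and HB), one gene model per haplotype at each allelic locus. This note
documents the models, the parameters that matter, the synthetic-data
generator the test suite runs against, and the design choices made where
the procedure was genuinely open.

## Allelic gene pairing

Collinearity blocks between the haplotypes (MCScanX-style input) are
filtered by three rules before any pairing: (i) the two regions must lie on
a designated homologous chromosome pair (the homolog map defaults to
identical chromosome indices, HA_chr*i* ↔ HB_chr*i*); (ii) neither region
may exceed three times the length of its counterpart; (iii) the aligned
anchors must cover at least 50% of each region. Both thresholds are read
inclusively (ratio exactly 3 and coverage exactly 0.5 are retained).
Coverage is computed per region as aligned anchor span over region span;
the precise meaning of "the entire area" is not standardised across tools,
so this reading is a package decision and both regions must pass.

Within retained blocks, genes are paired to their closest counterpart on
the opposite haplotype by global CDS alignment identity, with a
**reciprocal-best** requirement so that every locus carries exactly one
gene per haplotype. How ties among multiple candidates inside a block
should be broken is not dictated by the pairing literature; we break them
deterministically by (score descending, partner id ascending). Genes
matched in no retained block are reported haplotype-unique.

## Sequence divergence

Allelic CDS pairs are aligned at the protein level (Needleman–Wunsch,
match +1, mismatch 0, gap −1) and back-threaded to codons; gapped columns
are excluded from all site counts. Divergence statistics per pair:

* **Identity** — matching nucleotides over ungapped columns.
* **Ka/Ks (NG86)** — Nei–Gojobori counting: each codon position
  contributes the fraction of its three possible mutations that are
  synonymous to S (mutations creating stop codons count as
  nonsynonymous); multi-difference codons are averaged over all shortest
  mutational pathways, excluding pathways through stop codons (all
  pathways are used if none is stop-free). Proportions pN, pS are
  Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 flags the
  estimate undefined. NG86 was chosen as the concrete estimator because it
  is the canonical counting method with an exactly enumerable oracle; a
  maximum-likelihood estimator (CODEML-style) is out of scope.
* **4DTv** — among third positions where both codons belong to the same
  fourfold-degenerate family (identical first two bases), the fraction
  differing by a transversion.

The implementation is verified against a brute-force pathway-enumeration
oracle to 1e-12 (relative) in the test suite.

## ASE classification

Counts are TPM-normalized (FPKM available for positional profiling). Per
tissue, a locus is testable when mean TPM(HA) + mean TPM(HB) ≥ 1;
otherwise it is `not_expressed`. For testable loci, log2FC =
log2((mA + c)/(mB + c)) with pseudocount c = 0.1 TPM, and significance is
a two-sided Welch t-test on log2(TPM + 1) across replicates (the
underlying study does not name its test; Welch on logs is a conservative,
swappable default). Categories: P ≥ 0.05 → `no_bias`; otherwise by
|log2FC|: ≤ 1 `smaller`, (1, 3) `larger`, ≥ 3 `largest` (fold changes 2
and 8; the boundary values join the smaller and largest categories
respectively). No multiple-testing correction is applied, matching the raw
P < 0.05 convention of the emulated analysis.

Across tissues, a locus is an ASEG (class `HA_gt_HB` or `HA_lt_HB`) when
at least one tissue is `larger`/`largest` (FC > 2, P < 0.05) and all such
tissues agree on the direction; conflicts or no qualifying tissue give
`HA_eq_HB`. This "≥ 1 qualifying tissue, direction-consistent" reading
reproduces the additive identity |ASEG| = |HA>HB| + |HA<HB|. The
consistency fraction counts loci whose every testable tissue carries the
same biased category and direction.

## Chromatin states

Binned read counts (200-bp bins) are binarized per mark by an upper-tail
Poisson test: a bin is "present" iff P(X ≥ count; λ) < 1e-4, with λ the
control count (floored at one read) scaled by the mark/control library
ratio, or the mark's global mean without a control. The threshold mirrors
the default of the standard segmentation tool and is configurable.

The state model is a K-state HMM with independent Bernoulli emissions per
mark, fitted by Baum–Welch EM: emissions initialized from K-means cluster
means of the binary mark vectors, transitions at 0.9 self-transition,
scaled linear-space forward–backward, stop at log-likelihood gain < tol or
max_iter. EM is restarted from a few seeds (default 3) and the best final
likelihood kept — a single K-means initialization occasionally lands in a
merged-state optimum. Chromosomes are independent sequences sharing one
parameter set. Decoding is per-bin maximum posterior (not Viterbi),
matching per-bin state semantics; ties break to the lowest state index.
`model_selection_sweep` reports log-likelihood and BIC over K = 10..20
but deliberately does not pick K: the choice is left to the user, as the
selection criterion in the emulated analysis was manual.

State–feature fold enrichment is FE = (overlap/state bp) / (feature
bp/genome bp), with merged feature intervals and NaN for empty states.

## Haplotype mark asymmetry and methylation

Occupancy is RPKM-style: reads over gene body ± flank (default 1 kb,
configurable; the exact window of the emulated analysis is unstated) per
kb per million mapped reads, partial bins weighted by overlap. Asymmetry
summaries report, per ASEG class and mark, the median dominant-minus-
recessive difference, a two-sided Wilcoxon rank-sum P against the
balanced class (tie-degenerate comparisons return P = 1), and the
coefficient of variation of occupancies within the class. DNA methylation
is quantified but plays no role in ASEG classification, mirroring the
emulated finding that expression asymmetry tracks histone marks rather
than methylation.

The weighted methylation level of a region is Σ methylated reads / Σ
coverage over covered cytosines of the requested context (CG/CHG/CHH);
zero-coverage sites are excluded and a region with none is flagged NaN.

## Positional profiles

Metagene profiles rescale each gene body to 20 bins and add 1-kb flanks in
fixed 50-bp bins (20 per kb, matching body-bin granularity), oriented
5′→3′; per-bin signal is per-kb per-million, flanks truncated at
chromosome ends average over covered width, and genes shorter than 20 bp
are skipped with a warning. FPKM strata use right-closed bins {0}, (0,1],
(1,10], (10,20], (20,∞) — the bin notation "0–1, 1–10" is ambiguous and
right-closed was fixed as the package convention. Exon-position signals
cover the first three exons in transcript order, the union of annotated
5′UTR and first CDS segment, and TSS ± 1 kb.

## Metabolome

VIP scores come from a two-class PLS-DA (NIPALS PLS via scikit-learn) on
autoscaled intensities against a standardized group indicator, with
VIP_j = sqrt(p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a), so Σ VIP² equals
the number of metabolites. PLS-DA replaces OPLS-DA deliberately: the
orthogonal filtering step changes neither the thresholding logic nor the
VIP normalization identity, and it keeps the estimator dependency-free.
Two components by default; zero-variance metabolites are excluded with a
flag; zero intensities are imputed to half the metabolite's minimum
positive value (standard metabolomics convention), flagged. A metabolite
is a DAM when VIP ≥ 1, |log2FC| ≥ 1 and two-sided Welch P < 0.05 on log2
intensities.

## Co-expression modules

Unsigned network: adjacency |Pearson r|^β between gene expression
profiles, β the smallest candidate whose scale-free topology fit exceeds
0.85 (fit index −sign(slope)·R² of the log10 p(k) ~ log10 k regression
over equal-width connectivity bins; equal-frequency bins would flatten
p(k) by construction). TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 −
a_ij). Modules are average-linkage clusters of 1 − TOM under a static cut
(default: the 0.8 quantile of merge heights — high enough to isolate
tight clusters, low enough that the diffuse top of the tree does not glue
everything together; a static cut deliberately replaces the dynamic
hybrid cut and leaves fringe genes grey). Clusters below 40 genes go to
"grey"; modules whose eigengenes are closer than 0.15 in correlation
distance are merged iteratively. Eigengenes are first principal components
of standardized module expression, signed to correlate positively with the
module mean profile. Module–trait association is a Pearson correlation
with a t-distribution P on n − 2 df.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions the suite runs under.

* **Genome** — `n_chromosome_pairs` homologous chromosome pairs, one gene
  slot every 3 kb; a fraction `allelic_fraction` (default 0.8367) of loci
  carries one gene per haplotype, the rest are haplotype-unique,
  alternating sides. Genes have a fixed 3-exon architecture
  (300/300/300 bp exons, 200-bp introns, 99-bp 5′UTR → an 801-bp CDS),
  which keeps exon-position logic exercised without an annotation
  simulator. Synteny blocks span whole chromosome pairs with the allelic
  pairs as anchors.
* **CDS divergence** — the HB allele is the HA CDS with point mutations
  until exactly round((1 − identity)·L) sites differ (identity target
  0.9635 by default); proposals are transitions with probability 2/3
  (ts:tv = 2), mutations creating stops are rejected, and amino-acid-
  changing proposals are accepted only with probability 0.3, a mild
  purifying constraint that keeps median Ka/Ks below 1.
* **Expression** — negative-binomial counts (gamma–Poisson; variance
  μ + φμ², φ = 0.05) at base mean 200 over 9 tissues × 3 replicates, with
  a per-locus, per-tissue lognormal scale (σ = 0.5). Each allelic locus
  carries one planted category for all tissues, allocated by largest
  remainder over fractions 0.90/0.03/0.04/0.03
  (no_bias/smaller/larger/largest), with a coin-flip direction; the
  HA:HB mean ratio is 1, 2^U(0,1], U(2,8) or U(8,12) respectively.
  Planting per locus (rather than per locus × tissue) makes the
  across-tissue aggregation rule and recovery rates well-defined.
* **ChIP tracks** — per 200-bp bin, a Poisson background (λ = 1) plus a
  Poisson signal component (λ = 30) wherever a hidden chromatin-state
  chain emits the mark. The default truth model has four archetype states
  (active-promoter, transcribed-body, repressed, quiescent) with
  emissions 0.85/0.05 and a quiescent-heavy stationary distribution
  (70%), so binarization behaves like real ChIP data (few-percent signal
  bins at high enrichment). Gene-body bins of the dominant allele of
  `larger`/`largest` loci additionally multiply the background of
  H3K36me3/H3K4me3/H3K27ac by 8. The sampled state paths are recorded as
  ground truth. Replicate-level ChIP variability is not modelled — the
  emulated study does not report it — so noise levels here are generator
  parameters, not claims about any real dataset.
* **Methylation** — cytosines every 30 bp, contexts drawn 1:1:2
  (CG:CHG:CHH); per-site levels are Beta draws with context means
  0.8107/0.5423/0.1037 (concentration 8), coverage 1 + Poisson(19), 2% of
  sites left at zero coverage to exercise the exclusion path; methylated
  counts are binomial.
* **Metabolome** — 683 metabolites, log-normal intensities (log2 base
  ~N(17, 2)), 200 planted up and 150 down by a ±3 log2-unit shift between
  leaf and root groups, replicate noise SD 0.3. Planting all 683 as DAMs
  (the emulated report's counts sum to its detected total) would leave no
  nulls and make the VIP ≥ 1 filter reject half the true effects by the
  Σ VIP² identity; the generator therefore keeps a null fraction.
* **Seeding** — one master seed; each data type uses a fixed child stream
  (`SeedSequence(seed, spawn_key=(k,))`), so any part can be regenerated
  independently and identical configurations produce byte-identical files.

What the generator does **not** emulate: read-level artifacts (FASTQ,
alignment, duplicates), sequencing error, co-expression structure across
loci (module detection is exercised on explicitly planted blocks), gene
architecture variation, and replicate-level ChIP variability. Passing
tests therefore demonstrate correctness of the statistical machinery
under known truth, not performance on real sequencing data.

## Numerical choices and degenerate inputs

Emission probabilities are clipped to [1e-4, 1 − 1e-4] to keep Bernoulli
log-likelihoods finite; forward–backward uses per-bin scaling. Zero-
variance t-tests fall back to P = 1 (equal means) or 0. Rank-sum
comparisons of identical samples return P = 1. CDS lengths not divisible
by 3 are trimmed with a warning; internal stops in both sequences are an
error. TPM requires positive library sizes and gene lengths. Problem
sizes in the tests and the acceptance script (hundreds of loci, 5×10⁴
HMM bins, ~10⁵ cytosines) were chosen as the smallest scales at which the
sampling tolerances above are comfortably stable.
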