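"""Synthetic haplotype-resolved multi-omics data with known ground truth.

The generator emulates the pipeline's real-world inputs at desk scale: a
pair of phased haplotype assemblies (HA/HB) with one gene per haplotype at
each allelic locus plus haplotype-unique genes, allelic CDS pairs diverged
to a target identity (96.35% by default) under a mild purifying-selection
constraint, RNA-seq counts across nine tissues with planted allelic-bias
categories, binned ChIP tracks whose active marks follow both a hidden
chromatin-state chain and the dominant allele of biased loci,
Bismark-style cytosine reports with plant-like context methylation levels
(CG 81%, CHG 54%, CHH 10%), and a two-group metabolite intensity table
with planted fold changes.

One master seed determines everything; each data type draws from its own
fixed child stream so the parts can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatin import ChromatinStateModel
from .core import BinnedTrack, ConfigurationError, GeneModel, SyntenyBlock
from .divergence import CODON_TO_AA, STOP_CODONS
from . import io as aio

DEFAULT_MARKS = [
    "H3K4me2",
    "H3K4me3",
    "H3K9me2",
    "H3K27me2",
    "H3K27me3",
    "H3K36me2",
    "H3K36me3",
    "H3K9ac",
    "H3K27ac",
]

ASE_COUPLED_MARKS = ("H3K36me3", "H3K4me3", "H3K27ac")

DEFAULT_TISSUES = [
    "flower_bud",
    "flower",
    "stem",
    "leaf",
    "seed",
    "fibrous_root",
    "tuberous_root",
    "mature_leaf",
    "mature_root",
]

BIAS_CATEGORIES = ("no_bias", "smaller", "larger", "largest")

#: context-wise mean methylation targets (leaf values of the emulated system)
METHYLATION_MEANS = {"CG": 0.8107, "CHG": 0.5423, "CHH": 0.1037}
_BETA_CONCENTRATION = 8.0


def _default_beta_params() -> dict[str, tuple[float, float]]:
    return {
        ctx: (m * _BETA_CONCENTRATION, (1.0 - m) * _BETA_CONCENTRATION)
        for ctx, m in METHYLATION_MEANS.items()
    }


def _default_bias_fractions() -> dict[str, float]:
    return {"no_bias": 0.90, "smaller": 0.03, "larger": 0.04, "largest": 0.03}


SENSE_CODONS = sorted(set(CODON_TO_AA) - STOP_CODONS)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator; defaults are the study
    conditions the pipeline is tested under."""

    n_chromosome_pairs: int = 2
    n_loci_per_chromosome: int = 50
    allelic_fraction: float = 0.8367
    target_cds_identity: float = 0.9635
    bias_fractions: dict[str, float] = field(default_factory=_default_bias_fractions)
    n_tissues: int = 9
    n_replicates: int = 3
    base_mean: float = 200.0
    nb_dispersion: float = 0.05
    tissue_sigma: float = 0.5
    mark_names: list[str] = field(default_factory=lambda: list(DEFAULT_MARKS))
    hmm_truth: ChromatinStateModel | None = None
    bin_width: int = 200
    lambda_background: float = 1.0
    ase_enrichment: float = 8.0
    state_signal_lambda: float = 30.0
    methylation_beta_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_beta_params
    )
    methylation_site_spacing: int = 30
    methylation_coverage_mean: float = 20.0
    zero_coverage_fraction: float = 0.02
    n_metabolites: int = 683
    n_up_metabolites: int = 200
    n_down_metabolites: int = 150
    metabolite_effect: float = 3.0
    metabolite_noise_sd: float = 0.3
    nonsynonymous_retention: float = 0.3
    transition_fraction: float = 2.0 / 3.0  # ts:tv ratio of 2
    exon_lengths: tuple[int, ...] = (300, 300, 300)
    intron_lengths: tuple[int, ...] = (200, 200)
    utr5_length: int = 99
    gene_spacing: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosome_pairs < 1 or self.n_loci_per_chromosome < 1:
            raise ConfigurationError("chromosome and locus counts must be positive")
        if not 0.0 <= self.allelic_fraction <= 1.0:
            raise ConfigurationError("allelic_fraction must lie in [0, 1]")
        if not 0.0 <= self.target_cds_identity <= 1.0:
            raise ConfigurationError("target_cds_identity must lie in [0, 1]")
        if set(self.bias_fractions) != set(BIAS_CATEGORIES):
            raise ConfigurationError(
                f"bias_fractions must have keys {BIAS_CATEGORIES}"
            )
        if abs(sum(self.bias_fractions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("bias_fractions must sum to 1")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.n_replicates < 2:
            raise ConfigurationError("need at least 2 replicates")
        if set(self.methylation_beta_params) != {"CG", "CHG", "CHH"}:
            raise ConfigurationError(
                "methylation_beta_params must have keys CG, CHG, CHH"
            )
        if self.metabolite_effect < 0:
            raise ConfigurationError("metabolite_effect must be >= 0")
        if self.n_up_metabolites + self.n_down_metabolites > self.n_metabolites:
            raise ConfigurationError("more planted DAMs than metabolites")
        cds_len = sum(self.exon_lengths) - self.utr5_length
        if cds_len < 3 or cds_len % 3:
            raise ConfigurationError(
                "exon/UTR lengths must leave a CDS of positive length % 3 == 0"
            )
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ConfigurationError("need one intron fewer than exons")

    @property
    def n_loci(self) -> int:
        return self.n_chromosome_pairs * self.n_loci_per_chromosome

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths) - self.utr5_length

    @property
    def gene_length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    @property
    def tissues(self) -> list[str]:
        if self.n_tissues <= len(DEFAULT_TISSUES):
            return DEFAULT_TISSUES[: self.n_tissues]
        return DEFAULT_TISSUES + [
            f"tissue{i}" for i in range(len(DEFAULT_TISSUES), self.n_tissues)
        ]


_STREAMS = {"genome": 0, "expression": 1, "marks": 2, "methylation": 3,
            "metabolome": 4}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream stages must recover."""

    allele_map: dict[str, tuple[str, str]]
    unique_genes: dict[str, list[str]]
    bias: dict[str, tuple[str, str]]  # locus -> (category, direction)
    chrom_lengths: dict[str, dict[str, int]]  # haplotype -> chrom -> bp
    homolog_map: dict[str, str]
    state_paths: dict[str, list[int]] = field(default_factory=dict)
    planted_dams: dict[str, str] = field(default_factory=dict)

    def category_fractions(self) -> dict[str, float]:
        n = len(self.bias)
        out = {c: 0 for c in BIAS_CATEGORIES}
        for cat, _ in self.bias.values():
            out[cat] += 1
        return {c: v / n for c, v in out.items()}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "allele_map": {k: list(v) for k, v in self.allele_map.items()},
            "unique_genes": self.unique_genes,
            "bias": {k: list(v) for k, v in self.bias.items()},
            "chrom_lengths": self.chrom_lengths,
            "homolog_map": self.homolog_map,
            "state_paths": self.state_paths,
            "planted_dams": self.planted_dams,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            allele_map={k: tuple(v) for k, v in d["allele_map"].items()},
            unique_genes=d["unique_genes"],
            bias={k: tuple(v) for k, v in d["bias"].items()},
            chrom_lengths=d["chrom_lengths"],
            homolog_map=d["homolog_map"],
            state_paths=d["state_paths"],
            planted_dams=d["planted_dams"],
        )


# ---------------------------------------------------------------------------
# Gene models, CDS and synteny


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    codons = ["ATG"] + [
        SENSE_CODONS[i]
        for i in rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    ]
    return "".join(codons)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


def _mutate_cds(
    cds: str, config: SimulationConfig, rng: np.random.Generator
) -> str:
    """Point-mutate a CDS to the target identity under purifying retention.

    Exactly ``round((1 - identity) * L)`` sites end up different. Proposed
    changes are transitions with probability 2/3; a change that alters the
    amino acid (or creates a stop) is accepted only with probability
    ``nonsynonymous_retention``, which keeps Ka/Ks below 1.
    """
    seq = list(cds)
    L = len(seq)
    n_target = int(round((1.0 - config.target_cds_identity) * L))
    mutated: set[int] = set()
    guard = 0
    while len(mutated) < n_target and guard < 200 * L:
        guard += 1
        pos = int(rng.integers(0, L))
        if pos in mutated:
            continue
        base = seq[pos]
        if rng.random() < config.transition_fraction:
            new = _TRANSITION[base]
        else:
            new = _TRANSVERSIONS[base][int(rng.integers(0, 2))]
        cstart = 3 * (pos // 3)
        codon = "".join(seq[cstart : cstart + 3])
        mutant = codon[: pos - cstart] + new + codon[pos - cstart + 1 :]
        if mutant in STOP_CODONS:
            continue
        if CODON_TO_AA[mutant] != CODON_TO_AA[codon]:
            if rng.random() >= config.nonsynonymous_retention:
                continue
        seq[pos] = new
        mutated.add(pos)
    return "".join(seq)


def _build_gene(
    gene_id: str, haplotype: str, chrom: str, start: int, strand: str,
    config: SimulationConfig,
) -> GeneModel:
    exons = []
    pos = start
    for i, elen in enumerate(config.exon_lengths):
        exons.append((pos, pos + elen))
        pos += elen
        if i < len(config.intron_lengths):
            pos += config.intron_lengths[i]
    end = exons[-1][1]
    if strand == "+":
        # 5' UTR occupies the head of the first exon
        cds = [(exons[0][0] + config.utr5_length, exons[0][1])] + exons[1:]
    else:
        cds = exons[:-1] + [(exons[-1][0], exons[-1][1] - config.utr5_length)]
    return GeneModel(
        gene_id=gene_id,
        haplotype=haplotype,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        exons=exons,
        cds=cds,
    )


def _plant_bias(
    loci: list[str], fractions: dict[str, float], rng: np.random.Generator
) -> dict[str, tuple[str, str]]:
    """Largest-remainder allocation of bias categories over loci."""
    n = len(loci)
    cats = list(BIAS_CATEGORIES)
    raw = np.array([fractions[c] * n for c in cats])
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - np.floor(raw)))[: n - counts.sum()]:
        counts[i] += 1
    order = rng.permutation(n)
    bias: dict[str, tuple[str, str]] = {}
    cursor = 0
    for cat, cnt in zip(cats, counts):
        for idx in order[cursor : cursor + cnt]:
            if cat == "no_bias":
                direction = "none"
            else:
                direction = "HA" if rng.random() < 0.5 else "HB"
            bias[loci[idx]] = (cat, direction)
        cursor += cnt
    return bias


def generate_haplotype_pair(
    config: SimulationConfig,
) -> tuple[
    list[GeneModel], list[GeneModel], dict[str, str], dict[str, str],
    list[SyntenyBlock], GroundTruth,
]:
    """Gene models, CDS and synteny for both haplotypes, plus ground truth."""
    rng = _rng(config, "genome")
    P, L = config.n_chromosome_pairs, config.n_loci_per_chromosome
    total = P * L
    n_allelic = int(round(config.allelic_fraction * total))
    allelic_mask = np.zeros(total, dtype=bool)
    allelic_mask[rng.permutation(total)[:n_allelic]] = True

    clen = 1000 + L * config.gene_spacing + 1000
    clen += (-clen) % config.bin_width  # pad to a whole number of bins

    genes_a: list[GeneModel] = []
    genes_b: list[GeneModel] = []
    cds_a: dict[str, str] = {}
    cds_b: dict[str, str] = {}
    blocks: list[SyntenyBlock] = []
    allele_map: dict[str, tuple[str, str]] = {}
    unique_genes = {"HA": [], "HB": []}
    homolog_map = {}
    n_codons = config.cds_length // 3
    unique_counter = 0

    for c in range(1, P + 1):
        chrom_a, chrom_b = f"HA_chr{c}", f"HB_chr{c}"
        homolog_map[chrom_a] = chrom_b
        anchors = []
        for j in range(L):
            flat = (c - 1) * L + j
            start = 1000 + j * config.gene_spacing
            strand = "+" if rng.random() < 0.5 else "-"
            ga_id = f"SnA{c:02d}g{j + 1:04d}"
            gb_id = f"SnB{c:02d}g{j + 1:04d}"
            seq = _random_cds(n_codons, rng)
            if allelic_mask[flat]:
                locus_id = f"locus_{c}_{j + 1}"
                genes_a.append(_build_gene(ga_id, "HA", chrom_a, start, strand, config))
                genes_b.append(_build_gene(gb_id, "HB", chrom_b, start, strand, config))
                cds_a[ga_id] = seq
                cds_b[gb_id] = _mutate_cds(seq, config, rng)
                allele_map[locus_id] = (ga_id, gb_id)
                anchors.append((ga_id, gb_id))
            else:
                # haplotype-unique gene, alternating sides
                if unique_counter % 2 == 0:
                    genes_a.append(
                        _build_gene(ga_id, "HA", chrom_a, start, strand, config)
                    )
                    cds_a[ga_id] = seq
                    unique_genes["HA"].append(ga_id)
                else:
                    genes_b.append(
                        _build_gene(gb_id, "HB", chrom_b, start, strand, config)
                    )
                    cds_b[gb_id] = seq
                    unique_genes["HB"].append(gb_id)
                unique_counter += 1
        blocks.append(
            SyntenyBlock(
                block_id=f"blk{c}",
                chrom_a=chrom_a, start_a=0, end_a=clen,
                chrom_b=chrom_b, start_b=0, end_b=clen,
                orientation="same",
                anchor_pairs=anchors,
                coverage_a=1.0,
                coverage_b=1.0,
            )
        )

    bias = _plant_bias(sorted(allele_map), config.bias_fractions, rng)
    truth = GroundTruth(
        allele_map=allele_map,
        unique_genes=unique_genes,
        bias=bias,
        chrom_lengths={
            "HA": {f"HA_chr{c}": clen for c in range(1, P + 1)},
            "HB": {f"HB_chr{c}": clen for c in range(1, P + 1)},
        },
        homolog_map=homolog_map,
    )
    return genes_a, genes_b, cds_a, cds_b, blocks, truth


# ---------------------------------------------------------------------------
# Expression


def _nb_counts(
    mean: float, dispersion: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Negative binomial via gamma-Poisson; variance = mu + dispersion mu^2."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion, size=size)
    return rng.poisson(lam)


def _fold_change(category: str, rng: np.random.Generator) -> float:
    if category == "no_bias":
        return 1.0
    if category == "smaller":
        return float(2.0 ** rng.uniform(np.nextafter(0.0, 1.0), 1.0))
    if category == "larger":
        return float(rng.uniform(2.0, 8.0))
    return float(rng.uniform(8.0, 12.0))


def simulate_expression(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.Series]:
    """Raw count matrix (genes x tissue_replicate samples) and gene lengths."""
    rng = _rng(config, "expression")
    tissues = config.tissues
    R = config.n_replicates
    samples = [f"{t}_{r + 1}" for t in tissues for r in range(R)]
    rows: dict[str, np.ndarray] = {}

    for locus_id in sorted(truth.allele_map):
        ga, gb = truth.allele_map[locus_id]
        category, direction = truth.bias[locus_id]
        fc = _fold_change(category, rng)
        boost = np.sqrt(fc)
        mean_a = config.base_mean * (boost if direction != "HB" else 1.0 / boost)
        mean_b = config.base_mean * (boost if direction == "HB" else 1.0 / boost)
        if category == "no_bias":
            mean_a = mean_b = config.base_mean
        va, vb = [], []
        for _t in tissues:
            mu_scale = float(
                np.exp(rng.normal(0.0, config.tissue_sigma)
                       - config.tissue_sigma ** 2 / 2.0)
            )
            va.append(_nb_counts(mean_a * mu_scale, config.nb_dispersion, R, rng))
            vb.append(_nb_counts(mean_b * mu_scale, config.nb_dispersion, R, rng))
        rows[ga] = np.concatenate(va)
        rows[gb] = np.concatenate(vb)

    for hap in ("HA", "HB"):
        for gid in truth.unique_genes[hap]:
            vals = []
            for _t in tissues:
                mu_scale = float(
                    np.exp(rng.normal(0.0, config.tissue_sigma)
                           - config.tissue_sigma ** 2 / 2.0)
                )
                vals.append(
                    _nb_counts(config.base_mean * mu_scale,
                               config.nb_dispersion, R, rng)
                )
            rows[gid] = np.concatenate(vals)

    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    counts = counts.sort_index()
    lengths = pd.Series(
        float(sum(config.exon_lengths)), index=counts.index, name="length"
    )
    return counts, lengths


# ---------------------------------------------------------------------------
# ChIP tracks


def default_chromatin_truth(mark_names: list[str], K: int = 4) -> ChromatinStateModel:
    """A well-separated K-state generator model over the given marks.

    States emulate an active-promoter/transcribed state, a transcribed
    gene-body state, a repressed heterochromatic state and a quiescent
    state (extra states interpolate between active and quiescent).
    """
    M = len(mark_names)
    active = {"H3K4me3", "H3K9ac", "H3K27ac", "H3K4me2"}
    body = {"H3K36me3", "H3K36me2"}
    repressed = {"H3K9me2", "H3K27me2", "H3K27me3"}
    archetypes = [active, body, repressed, set()]
    weights = [0.08, 0.08, 0.14, 0.70]  # quiescent state dominates the genome
    emission = np.full((K, M), 0.05)
    pi = np.empty(K)
    for k in range(K):
        marks_on = archetypes[k % len(archetypes)]
        pi[k] = weights[k % len(weights)]
        for m, name in enumerate(mark_names):
            if name in marks_on:
                emission[k, m] = 0.85
    pi /= pi.sum()
    # rows mix 0.9 self-transition with the stationary distribution, so the
    # chain's stationary state frequencies equal pi exactly
    transition = 0.9 * np.eye(K) + 0.1 * pi[None, :] if K > 1 else np.ones((1, 1))
    transition /= transition.sum(axis=1, keepdims=True)
    initial = pi
    return ChromatinStateModel(
        K=K, mark_names=list(mark_names), emission=emission,
        transition=transition, initial=initial,
    )


def simulate_marks(
    config: SimulationConfig,
    truth: GroundTruth,
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
) -> tuple[dict[str, dict[str, BinnedTrack]], dict[str, BinnedTrack]]:
    """Binned ChIP count tracks per haplotype and mark, plus input controls.

    Every bin draws a Poisson background; bins under a hidden chromatin
    state that emits a mark add a Poisson signal component, and gene-body
    bins of the dominant allele of a biased locus multiply the background
    of the ASE-coupled active marks by ``ase_enrichment``. The sampled
    state path per chromosome is recorded in ``truth.state_paths``.
    """
    if config.bin_width != 200:
        raise ConfigurationError("mark simulation is defined for 200-bp bins")
    rng = _rng(config, "marks")
    model = config.hmm_truth or default_chromatin_truth(config.mark_names)
    if list(model.mark_names) != list(config.mark_names):
        raise ConfigurationError("hmm_truth marks differ from config.mark_names")
    w = config.bin_width
    genes_by_hap = {"HA": genes_a, "HB": genes_b}

    # which (hap, chrom, bin range) get the ASE multiplier, per coupled mark
    boosted: dict[str, list[tuple[str, int, int]]] = {"HA": [], "HB": []}
    gene_index = {g.gene_id: g for g in genes_a + genes_b}
    for locus_id, (category, direction) in truth.bias.items():
        if category not in ("larger", "largest"):
            continue
        ga, gb = truth.allele_map[locus_id]
        gene = gene_index[ga if direction == "HA" else gb]
        boosted[gene.haplotype].append(
            (gene.chrom, gene.start // w, (gene.end + w - 1) // w)
        )

    tracks: dict[str, dict[str, BinnedTrack]] = {}
    controls: dict[str, BinnedTrack] = {}
    for hap in ("HA", "HB"):
        chrom_lens = truth.chrom_lengths[hap]
        mark_counts: dict[str, dict[str, np.ndarray]] = {
            m: {} for m in config.mark_names
        }
        control_counts: dict[str, np.ndarray] = {}
        for chrom, clen in sorted(chrom_lens.items()):
            n_bins = clen // w
            path = np.empty(n_bins, dtype=np.int64)
            path[0] = rng.choice(model.K, p=model.initial)
            for t in range(1, n_bins):
                path[t] = rng.choice(model.K, p=model.transition[path[t - 1]])
            truth.state_paths[f"{hap}:{chrom}"] = path.tolist()
            factor = {
                m: np.ones(n_bins) for m in ASE_COUPLED_MARKS
                if m in config.mark_names
            }
            for bchrom, b0, b1 in boosted[hap]:
                if bchrom == chrom:
                    for m in factor:
                        factor[m][b0:b1] = config.ase_enrichment
            for mi, mark in enumerate(config.mark_names):
                present = rng.random(n_bins) < model.emission[path, mi]
                lam = config.lambda_background * factor.get(mark, np.ones(n_bins))
                counts = rng.poisson(lam) + np.where(
                    present, rng.poisson(config.state_signal_lambda, n_bins), 0
                )
                mark_counts[mark][chrom] = counts.astype(np.int64)
            control_counts[chrom] = rng.poisson(
                config.lambda_background, n_bins
            ).astype(np.int64)
        tracks[hap] = {
            m: BinnedTrack(counts=mark_counts[m], bin_width=w)
            for m in config.mark_names
        }
        controls[hap] = BinnedTrack(counts=control_counts, bin_width=w)
    return tracks, controls


# ---------------------------------------------------------------------------
# Methylation


_TRINUCLEOTIDE = {"CG": "CGG", "CHG": "CAG", "CHH": "CAT"}
_CONTEXT_PROBS = {"CG": 0.25, "CHG": 0.25, "CHH": 0.5}


def simulate_methylation(
    config: SimulationConfig, truth: GroundTruth
) -> dict[str, pd.DataFrame]:
    """Bismark-style cytosine reports per haplotype.

    Per-site methylation probabilities are Beta draws per context;
    methylated counts are binomial at a shifted-negative-binomial coverage
    of at least one read, except for a configurable fraction of
    zero-coverage sites (which region-level summaries must exclude).
    """
    rng = _rng(config, "methylation")
    reports = {}
    contexts = list(_CONTEXT_PROBS)
    probs = np.array([_CONTEXT_PROBS[c] for c in contexts])
    for hap in ("HA", "HB"):
        frames = []
        for chrom, clen in sorted(truth.chrom_lengths[hap].items()):
            pos = np.arange(
                config.methylation_site_spacing, clen,
                config.methylation_site_spacing, dtype=np.int64,
            )
            n = len(pos)
            ctx = rng.choice(contexts, size=n, p=probs)
            p_site = np.empty(n)
            for c in contexts:
                a, b = config.methylation_beta_params[c]
                mask = ctx == c
                if a <= 0 or b <= 0:
                    # point-mass limits for degenerate Beta parameters
                    p_site[mask] = 1.0 if b <= 0 < a else 0.0
                else:
                    p_site[mask] = rng.beta(a, b, size=int(mask.sum()))
            coverage = 1 + rng.poisson(
                max(config.methylation_coverage_mean - 1.0, 0.0), size=n
            )
            coverage[rng.random(n) < config.zero_coverage_fraction] = 0
            meth = rng.binomial(coverage, p_site)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,  # 1-based report positions
                        "strand": np.where(np.arange(n) % 2 == 0, "+", "-"),
                        "count_methylated": meth,
                        "count_unmethylated": coverage - meth,
                        "context": ctx,
                        "trinucleotide": [_TRINUCLEOTIDE[c] for c in ctx],
                    }
                )
            )
        reports[hap] = pd.concat(frames, ignore_index=True)
    return reports


# ---------------------------------------------------------------------------
# Metabolome


def simulate_metabolome(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group (leaf/root) metabolite intensities with planted fold changes.

    Planted "up" metabolites are shifted +effect in log2 space in leaf
    relative to root, "down" metabolites -effect, nulls unshifted; the
    planted status map is recorded in ``truth.planted_dams`` when a truth
    object is supplied.
    """
    rng = _rng(config, "metabolome")
    n = config.n_metabolites
    names = [f"M{i + 1:04d}" for i in range(n)]
    status = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    status[order[: config.n_up_metabolites]] = "up"
    status[
        order[config.n_up_metabolites : config.n_up_metabolites
              + config.n_down_metabolites]
    ] = "down"

    base = rng.normal(17.0, 2.0, size=n)
    shift = np.where(status == "up", config.metabolite_effect / 2.0,
                     np.where(status == "down", -config.metabolite_effect / 2.0, 0.0))
    R = 3
    samples = [f"leaf_{r + 1}" for r in range(R)] + [
        f"root_{r + 1}" for r in range(R)
    ]
    data = np.empty((n, 2 * R))
    for r in range(R):
        data[:, r] = base + shift + rng.normal(0, config.metabolite_noise_sd, n)
        data[:, R + r] = base - shift + rng.normal(0, config.metabolite_noise_sd, n)
    intensities = pd.DataFrame(2.0 ** data, index=names, columns=samples)
    groups = pd.Series(
        ["leaf"] * R + ["root"] * R, index=samples, name="group"
    )
    if truth is not None:
        truth.planted_dams = dict(zip(names, status))
    return intensities, groups


# ---------------------------------------------------------------------------
# One-call driver


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input under ``outdir``; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes_a, genes_b, cds_a, cds_b, blocks, truth = generate_haplotype_pair(config)
    counts, lengths = simulate_expression(config, truth)
    tracks, controls = simulate_marks(config, truth, genes_a, genes_b)
    meth = simulate_methylation(config, truth)
    intensities, groups = simulate_metabolome(config, truth)

    paths: dict[str, Path] = {}

    def _p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    aio.write_gff3(genes_a, _p("genes_HA.gff3"))
    aio.write_gff3(genes_b, _p("genes_HB.gff3"))
    aio.write_fasta(cds_a, _p("cds_HA.fasta"))
    aio.write_fasta(cds_b, _p("cds_HB.fasta"))
    aio.write_synteny(blocks, _p("synteny.tsv"))
    aio.write_counts(counts, _p("counts.tsv"))
    lengths.to_csv(_p("gene_lengths.tsv"), sep="\t", index_label="gene_id")
    for hap in ("HA", "HB"):
        for mark, track in tracks[hap].items():
            aio.write_bedgraph(track, _p(f"chip_{hap}_{mark}.bedgraph"))
        aio.write_bedgraph(controls[hap], _p(f"chip_{hap}_input.bedgraph"))
        aio.write_cytosine_report(meth[hap], _p(f"methylation_{hap}.tsv"))
    aio.write_metabolite_table(intensities, groups, _p("metabolites.tsv"))
    truth.to_json(_p("ground_truth.json"))
    return paths
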