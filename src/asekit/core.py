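"""Shared domain containers for the haplotype-resolved ASE/epigenome pipeline.

Coordinates are 0-based, half-open throughout the package; the GFF3 and
cytosine-report readers/writers in :mod:`asekit.io` convert to and from the
1-based inclusive conventions of those formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Interval = tuple[int, int]

HAPLOTYPES = ("HA", "HB")


class ConfigurationError(ValueError):
    """Raised when a simulation or analysis is configured inconsistently."""


class InputError(ValueError):
    """Raised when input data violate a documented contract."""


def _check_intervals(name: str, ivs: list[Interval]) -> None:
    prev_end = -1
    for s, e in ivs:
        if s >= e:
            raise InputError(f"{name} interval ({s}, {e}) is empty or reversed")
        if s < prev_end:
            raise InputError(f"{name} intervals overlap or are unsorted")
        prev_end = e


@dataclass
class GeneModel:
    """A gene on one haplotype; the coordinate anchor for signal extraction.

    ``exons`` and ``cds`` are sorted in genomic order (ascending start) and
    non-overlapping; for minus-strand genes the 5'-most exon is therefore the
    *last* element. Use :meth:`exons_5to3` for transcript order.
    """

    gene_id: str
    haplotype: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.haplotype not in HAPLOTYPES:
            raise InputError(f"haplotype must be one of {HAPLOTYPES}")
        if self.strand not in ("+", "-"):
            raise InputError("strand must be '+' or '-'")
        if not self.start < self.end:
            raise InputError(f"gene {self.gene_id}: start must be < end")
        _check_intervals(f"gene {self.gene_id} exons", self.exons)
        _check_intervals(f"gene {self.gene_id} cds", self.cds)
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise InputError(
                    f"gene {self.gene_id}: CDS ({cs}, {ce}) not inside an exon"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    def exons_5to3(self) -> list[Interval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def cds_5to3(self) -> list[Interval]:
        return self.cds if self.strand == "+" else list(reversed(self.cds))

    def utr5(self) -> list[Interval]:
        """Exonic intervals upstream (5') of the first coding base."""
        if not self.cds:
            return []
        out: list[Interval] = []
        if self.strand == "+":
            cds_start = self.cds[0][0]
            for s, e in self.exons:
                if e <= cds_start:
                    out.append((s, e))
                elif s < cds_start:
                    out.append((s, cds_start))
        else:
            cds_end = self.cds[-1][1]
            for s, e in self.exons:
                if s >= cds_end:
                    out.append((s, e))
                elif e > cds_end:
                    out.append((cds_end, e))
        return out


@dataclass
class SyntenyBlock:
    """A collinear region pair between the two haplotype assemblies."""

    block_id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    orientation: str = "same"
    anchor_pairs: list[tuple[str, str]] = field(default_factory=list)
    coverage_a: float = 1.0
    coverage_b: float = 1.0

    def __post_init__(self) -> None:
        if self.orientation not in ("same", "inverted"):
            raise InputError("orientation must be 'same' or 'inverted'")
        for cov in (self.coverage_a, self.coverage_b):
            if not 0.0 <= cov <= 1.0:
                raise InputError("aligned coverage must lie in [0, 1]")

    @property
    def length_a(self) -> int:
        return self.end_a - self.start_a

    @property
    def length_b(self) -> int:
        return self.end_b - self.start_b


@dataclass
class AllelePair:
    """One locus: the HA gene and its HB counterpart."""

    locus_id: str
    gene_a: str
    gene_b: str
    source_block: str = ""
    identity: float | None = None


@dataclass
class BinnedTrack:
    """Fixed-width per-chromosome read counts for one mark or input control."""

    counts: dict[str, np.ndarray]
    bin_width: int = 200
    library_size: int | None = None

    def __post_init__(self) -> None:
        for chrom, arr in self.counts.items():
            arr = np.asarray(arr)
            if arr.ndim != 1:
                raise InputError(f"{chrom}: counts must be a 1-D vector")
            if np.any(arr < 0):
                raise InputError(f"{chrom}: counts must be non-negative")
            self.counts[chrom] = arr
        if self.library_size is None:
            self.library_size = int(sum(int(a.sum()) for a in self.counts.values()))

    def n_bins(self, chrom: str) -> int:
        return len(self.counts[chrom])

    def chrom_length(self, chrom: str) -> int:
        return self.n_bins(chrom) * self.bin_width

    def same_grid(self, other: "BinnedTrack") -> bool:
        if self.bin_width != other.bin_width:
            return False
        if set(self.counts) != set(other.counts):
            return False
        return all(len(self.counts[c]) == len(other.counts[c]) for c in self.counts)


@dataclass
class BiasCall:
    """Per-locus, per-tissue allelic bias classification."""

    locus_id: str
    tissue: str
    log2fc: float
    p_value: float
    category: str
    direction: str

    CATEGORIES = ("not_expressed", "no_bias", "smaller", "larger", "largest")

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise InputError(f"unknown bias category {self.category!r}")
        if (self.direction == "none") != (
            self.category in ("not_expressed", "no_bias")
        ):
            raise InputError(
                "direction must be 'none' exactly for untested/unbiased calls"
            )


@dataclass
class DominanceCall:
    """Across-tissue haplotype dominance class for one locus."""

    locus_id: str
    dominance: str
    supporting_tissues: list[str] = field(default_factory=list)

    CLASSES = ("HA_gt_HB", "HA_lt_HB", "HA_eq_HB")

    def __post_init__(self) -> None:
        if self.dominance not in self.CLASSES:
            raise InputError(f"unknown dominance class {self.dominance!r}")

    @property
    def is_aseg(self) -> bool:
        return self.dominance != "HA_eq_HB"
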