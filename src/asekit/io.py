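"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are plain TSV. GFF3 is written 1-based inclusive,
bedGraph 0-based half-open, and the cytosine report 1-based, matching the
conventions of the upstream tools these files emulate (MAKER-style gene
annotation, bedtools/deeptools binned coverage, Bismark cytosine reports).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import BinnedTrack, GeneModel, InputError, SyntenyBlock

# ---------------------------------------------------------------------------
# GFF3


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};haplotype={g.haplotype}"
            fh.write(
                f"{g.chrom}\tasekit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tasekit\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tasekit\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\tasekit\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna_id}.cds;Parent={mrna_id}\n"
                )


def _parse_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/exon/CDS features into :class:`GeneModel` objects."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise InputError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            attrs = _parse_attributes(attrs)
            start0, end0 = int(start) - 1, int(end)
            if ftype == "gene":
                gid = attrs["ID"]
                genes[gid] = {
                    "gene_id": gid,
                    "haplotype": attrs.get("haplotype", "HA"),
                    "chrom": chrom,
                    "start": start0,
                    "end": end0,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                }
                order.append(gid)
            elif ftype == "mRNA":
                gid = attrs["Parent"]
                genes[gid]["mrna"] = attrs["ID"]
            elif ftype in ("exon", "CDS"):
                parent = attrs["Parent"]
                gid = parent.rsplit(".t1", 1)[0]
                if gid not in genes:
                    raise InputError(f"{ftype} with unknown parent {parent}")
                key = "exons" if ftype == "exon" else "cds"
                genes[gid][key].append((start0, end0))
    models = []
    for gid in order:
        d = genes[gid]
        d.pop("mrna", None)
        d["exons"] = sorted(d["exons"])
        d["cds"] = sorted(d["cds"])
        models.append(GeneModel(**d))
    return models


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# bedGraph (fixed-width binned tracks)


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    w = track.bin_width
    with Path(path).open("w") as fh:
        for chrom in sorted(track.counts):
            arr = track.counts[chrom]
            for i, v in enumerate(arr):
                fh.write(f"{chrom}\t{i * w}\t{(i + 1) * w}\t{int(v)}\n")


def read_bedgraph(
    path: str | Path, bin_width: int = 200, library_size: int | None = None
) -> BinnedTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "count"]
    )
    counts: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        widths = sub["end"].to_numpy() - sub["start"].to_numpy()
        if np.any(widths != bin_width):
            raise InputError(f"{chrom}: bedGraph bins are not {bin_width} bp wide")
        idx = sub["start"].to_numpy() // bin_width
        arr = np.zeros(int(idx.max()) + 1, dtype=np.int64)
        arr[idx] = sub["count"].to_numpy()
        counts[str(chrom)] = arr
    return BinnedTrack(counts=counts, bin_width=bin_width, library_size=library_size)


# ---------------------------------------------------------------------------
# Count matrices and generic tables


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def sample_metadata(columns: list[str]) -> pd.DataFrame:
    """Decompose ``tissue_replicate`` sample ids into a metadata table."""
    rows = []
    for col in columns:
        tissue, _, rep = col.rpartition("_")
        if not tissue:
            raise InputError(f"sample id {col!r} is not of the form tissue_rep")
        rows.append({"sample": col, "tissue": tissue, "replicate": rep})
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# Cytosine report (Bismark-style)

CYTOSINE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]


def write_cytosine_report(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", header=False, index=False,
                   columns=CYTOSINE_COLUMNS)


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=CYTOSINE_COLUMNS)


# ---------------------------------------------------------------------------
# Synteny blocks


def write_synteny(blocks: list[SyntenyBlock], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "block_id\tchrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\t"
            "orientation\tcoverage_a\tcoverage_b\tanchors\n"
        )
        for b in blocks:
            anchors = ";".join(f"{ga}:{gb}" for ga, gb in b.anchor_pairs)
            fh.write(
                f"{b.block_id}\t{b.chrom_a}\t{b.start_a}\t{b.end_a}\t"
                f"{b.chrom_b}\t{b.start_b}\t{b.end_b}\t{b.orientation}\t"
                f"{b.coverage_a:.6g}\t{b.coverage_b:.6g}\t{anchors}\n"
            )


def read_synteny(path: str | Path) -> list[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    blocks = []
    for row in df.itertuples(index=False):
        anchors = [
            tuple(pair.split(":", 1)) for pair in str(row.anchors).split(";") if pair
        ]
        blocks.append(
            SyntenyBlock(
                block_id=str(row.block_id),
                chrom_a=str(row.chrom_a),
                start_a=int(row.start_a),
                end_a=int(row.end_a),
                chrom_b=str(row.chrom_b),
                start_b=int(row.start_b),
                end_b=int(row.end_b),
                orientation=str(row.orientation),
                anchor_pairs=anchors,
                coverage_a=float(row.coverage_a),
                coverage_b=float(row.coverage_b),
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# Metabolite tables


def write_metabolite_table(
    intensities: pd.DataFrame, groups: pd.Series, path: str | Path
) -> None:
    path = Path(path)
    intensities.to_csv(path, sep="\t", index_label="metabolite")
    groups.rename("group").to_csv(
        path.with_suffix(".groups.tsv"), sep="\t", index_label="sample"
    )


def read_metabolite_table(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    path = Path(path)
    intensities = pd.read_csv(path, sep="\t", index_col="metabolite")
    groups = pd.read_csv(
        path.with_suffix(".groups.tsv"), sep="\t", index_col="sample"
    )["group"]
    return intensities, groups


# ---------------------------------------------------------------------------
# Chromatin-state model JSON / segmentation BED


def write_state_model(model, path: str | Path) -> None:
    payload = {
        "K": model.K,
        "mark_names": list(model.mark_names),
        "emission": np.asarray(model.emission).tolist(),
        "transition": np.asarray(model.transition).tolist(),
        "initial": np.asarray(model.initial).tolist(),
        "log_likelihood_trace": [float(x) for x in model.log_likelihood_trace],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_state_model(path: str | Path):
    from .chromatin import ChromatinStateModel

    d = json.loads(Path(path).read_text())
    return ChromatinStateModel(
        K=d["K"],
        mark_names=list(d["mark_names"]),
        emission=np.asarray(d["emission"]),
        transition=np.asarray(d["transition"]),
        initial=np.asarray(d["initial"]),
        log_likelihood_trace=list(d["log_likelihood_trace"]),
    )


def write_segmentation_bed(seg, path: str | Path, bin_width: int = 200) -> None:
    with Path(path).open("w") as fh:
        for chrom in sorted(seg.labels):
            labels = seg.labels[chrom]
            # merge runs of identical states into single BED records
            run_start = 0
            for i in range(1, len(labels) + 1):
                if i == len(labels) or labels[i] != labels[run_start]:
                    fh.write(
                        f"{chrom}\t{run_start * bin_width}\t{i * bin_width}\t"
                        f"S{labels[run_start] + 1}\n"
                    )
                    run_start = i
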