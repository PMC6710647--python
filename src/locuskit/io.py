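"""Readers and writers for the plain-text formats locuskit exchanges.

Writers emit deterministic, byte-stable output: FASTA wrapped at 60
columns, GFF3 with a version header and 1-based inclusive coordinates, a
minimal VCF v4.2 subset (CHROM POS ID REF ALT QUAL FILTER INFO), and TSV
tables for digital-PCR partition counts. Reading VCF goes through pysam;
FASTA through Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dpcr import DpcrAssay
from .errors import InputError
from .scan import VariantTable

FASTA_WRAP = 60


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(seqrecs)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(path: str | Path, locus) -> None:
    """Annotation of a :class:`~locuskit.synthetic.SyntheticLocus` as GFF3."""
    lines = ["##gff-version 3", f"##sequence-region {locus.contig} 1 {locus.genome_length}"]
    for f in locus.features:
        attrs = f"ID={f.gene_id};family={f.family};uniqueness=" + (
            "unique" if f.family == "unique" else "repetitive"
        )
        lines.append(
            "\t".join(
                [
                    locus.contig,
                    "locuskit",
                    "gene",
                    str(f.start),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_vcf(path: str | Path, table: VariantTable) -> None:
    header = [
        "##fileformat=VCFv4.2",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    rows = [
        f"{r.contig}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t."
        for r in table.records.itertuples()
    ]
    Path(path).write_text("\n".join(header + rows) + "\n")


def read_vcf(path: str | Path, source_label: str = "") -> VariantTable:
    import pysam

    recs = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                recs.append((rec.chrom, rec.pos, rec.ref, alt))
    return VariantTable(
        pd.DataFrame(recs, columns=list(VariantTable.COLUMNS)),
        source_label=source_label or str(path),
    )


def write_dpcr_tsv(path: str | Path, assays: Sequence[DpcrAssay]) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_label": a.sample_label,
                "replicate_id": a.replicate_id,
                "chambers": a.chambers,
                "positives_target": a.positives_target,
                "positives_ref": a.positives_ref,
            }
            for a in assays
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_dpcr_tsv(path: str | Path) -> list[DpcrAssay]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_label", "replicate_id", "chambers", "positives_target", "positives_ref"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"dPCR table missing columns: {sorted(missing)}")
    return [
        DpcrAssay(
            chambers=int(r.chambers),
            positives_target=int(r.positives_target),
            positives_ref=int(r.positives_ref),
            replicate_id=str(r.replicate_id),
            sample_label=str(r.sample_label),
        )
        for r in df.itertuples()
    ]


def write_truth_json(path: str | Path, locus) -> None:
    """Machine-readable planted truth for a synthetic locus."""
    payload = {
        "contig": locus.contig,
        "genome_length": locus.genome_length,
        "features": [
            {
                "gene_id": f.gene_id,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "family": f.family,
            }
            for f in locus.features
        ],
        "truth_sites": {
            f"{a}|{b}": list(sites) for (a, b), sites in locus.truth_sites.items()
        },
        "events": [
            {
                "donor": e.donor_gene_id,
                "acceptor": e.acceptor_gene_id,
                "junction": e.crossover_junction,
                "deleted_interval": list(e.deleted_interval),
                "chimera_id": e.chimera_id,
            }
            for e in locus.events
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """BED (0-based half-open) → 1-based inclusive labelled regions."""
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise InputError("BED regions need 4 columns: chrom start end name")
        _, start, end, name = parts[:4]
        regions.append((name, int(start) + 1, int(end)))
    return regions


def write_regions_bed(path: str | Path, regions, contig: str = "locus") -> None:
    lines = [f"{contig}\t{s - 1}\t{e}\t{lab}" for lab, s, e in regions]
    Path(path).write_text("\n".join(lines) + "\n")
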