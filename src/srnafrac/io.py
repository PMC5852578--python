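"""File products: FASTQ reads, per-category FASTA references, BED clusters,
collapsed FASTA and TSV tables."""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import CATEGORY_ORDER, ReferenceSet


def write_fastq(reads: pd.DataFrame, path: str) -> None:
    """Write reads (read_id, sequence) as FASTQ with uniform quality 'I'."""
    records = (
        SeqRecord(
            Seq(row.sequence), id=row.read_id, description="",
            letter_annotations={"phred_quality": [40] * len(row.sequence)},
        )
        for row in reads.itertuples()
    )
    SeqIO.write(records, path, "fastq")


def read_fastq(path: str) -> pd.DataFrame:
    rows = [
        {"read_id": rec.id, "sequence": str(rec.seq)}
        for rec in SeqIO.parse(path, "fastq")
    ]
    return pd.DataFrame(rows, columns=["read_id", "sequence"])


def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items())
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    """3+1-column BED (contig, start, end, name), 0-based half-open."""
    intervals[["contig", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = ["contig", "start", "end", "name"][: df.shape[1]]
    return df


def write_reference_set(ref: ReferenceSet, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    for cat in CATEGORY_ORDER:
        write_fasta(ref.categories[cat], os.path.join(outdir, f"{cat}.fasta"))
    write_fasta(ref.genome, os.path.join(outdir, "genome.fasta"))
    write_fasta(ref.repeat_families, os.path.join(outdir, "repeat_families.fasta"))
    write_bed(ref.pirna_clusters, os.path.join(outdir, "pirna_clusters.bed"))
    ref.mature_mirnas.to_csv(os.path.join(outdir, "mature_mirnas.tsv"),
                             sep="\t", index=False)


def load_reference_set(refdir: str) -> ReferenceSet:
    categories = {
        cat: read_fasta(os.path.join(refdir, f"{cat}.fasta"))
        for cat in CATEGORY_ORDER
    }
    ref = ReferenceSet(
        categories=categories,
        mature_mirnas=pd.read_csv(os.path.join(refdir, "mature_mirnas.tsv"), sep="\t"),
        pirna_clusters=read_bed(os.path.join(refdir, "pirna_clusters.bed")),
        genome=read_fasta(os.path.join(refdir, "genome.fasta")),
        repeat_families=read_fasta(os.path.join(refdir, "repeat_families.fasta")),
        trnas_cca=categories["tRNA"],
    )
    ref.validate()
    return ref


def write_collapsed_fasta(records: pd.DataFrame, sample: str, path: str) -> None:
    """Collapsed per-sample FASTA with ``>seq{i}_x{count}`` headers."""
    with open(path, "w") as fh:
        i = 0
        for seq, count in records[sample].items():
            if count > 0:
                i += 1
                fh.write(f">seq{i}_x{count}\n{seq}\n")


def read_collapsed_fasta(path: str, sample: str) -> pd.DataFrame:
    rows = {}
    for rec in SeqIO.parse(path, "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        rows[str(rec.seq)] = count
    df = pd.DataFrame({sample: rows}, dtype=int)
    df.index.name = "sequence"
    return df
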