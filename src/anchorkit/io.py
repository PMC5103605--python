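"""Thin readers/writers for the plain-text formats the pipeline exchanges."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sim import ReadPair


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_paired_fastq_gz(pairs: Sequence[ReadPair], prefix: str | Path) -> tuple[Path, Path]:
    """Write mates to ``<prefix>_R1.fastq.gz`` / ``<prefix>_R2.fastq.gz``."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq.gz")
    p2 = prefix.with_name(prefix.name + "_R2.fastq.gz")
    with gzip.open(p1, "wt") as f1, gzip.open(p2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")
    return p1, p2


def read_paired_fastq_gz(r1: str | Path, r2: str | Path) -> list[ReadPair]:
    def _parse(path):
        with gzip.open(str(path), "rt") as fh:
            return [(r.id, str(r.seq), "".join(chr(q + 33) for q in r.letter_annotations["phred_quality"]))
                    for r in SeqIO.parse(fh, "fastq")]

    recs1, recs2 = _parse(r1), _parse(r2)
    if len(recs1) != len(recs2):
        raise ValueError("mate files have different read counts")
    pairs = []
    for (id1, s1, q1), (_id2, s2, q2) in zip(recs1, recs2):
        pairs.append(ReadPair(id1.rsplit("/", 1)[0], s1, q1, s2, q2))
    return pairs


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    """0-based half-open intervals, BED3."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
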