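"""Alignment masking, trimming, concatenation, and summary statistics.

Per-locus alignments are screened residue by residue: a site is "good" when
it agrees with more than half of the other non-gap residues in its column,
sliding 20-column windows with fewer than 14 good sites are masked, and
columns left with fewer than 30 unmasked bases are removed.  Surviving loci
are concatenated into a supermatrix partitioned by locus.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

GAP_CHARS = "-."
MISSING_FASTA = "N"
MISSING_PHYLIP = "?"


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows plus a per-residue visibility mask."""

    locus: str
    taxa: list[str]
    rows: list[str]
    mask: np.ndarray | None = None  # True = masked

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in number")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows must be equal length")
        if self.mask is None:
            self.mask = np.zeros((len(self.rows), self.length), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (len(self.rows), self.length):
            raise ValueError("mask shape must equal alignment shape")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def align_locus_external(
    records: list[tuple[str, str]],
    locus: str = "locus",
    aligner: str = "mafft",
    flags: tuple[str, ...] = ("--genafpair", "--maxiterate", "1000"),
    log: list[str] | None = None,
) -> MultipleAlignment:
    """Align a cluster with an external aligner (MAFFT by default).

    Pre-aligned input (all rows equal length) passes through unchanged.  The
    tool and exact flags used are appended to ``log`` for provenance.
    """
    lengths = {len(s) for _, s in records}
    if len(lengths) == 1:
        if log is not None:
            log.append(f"{locus}: pre-aligned input passed through")
        return MultipleAlignment(locus, [n for n, _ in records], [s for _, s in records])
    exe = shutil.which(aligner)
    if exe is None:
        raise RuntimeError(f"{aligner} not on PATH and input is not aligned")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fa"
        fin.write_text("".join(f">{n}\n{s}\n" for n, s in records))
        cmd = [exe, *flags, "--quiet", str(fin)]
        out = subprocess.run(cmd, capture_output=True, text=True, check=True).stdout
    if log is not None:
        log.append(f"{locus}: {aligner} {' '.join(flags)}")
    taxa, rows, cur = [], [], []
    for line in out.splitlines():
        if line.startswith(">"):
            if cur:
                rows.append("".join(cur))
                cur = []
            taxa.append(line[1:].split()[0])
        else:
            cur.append(line.strip())
    if cur:
        rows.append("".join(cur))
    return MultipleAlignment(locus, taxa, [r.upper() for r in rows])


def compute_good_sites(aln: MultipleAlignment, threshold: float = 0.5) -> np.ndarray:
    """Per-residue goodness: agrees with > ``threshold`` of other residues.

    A gap is never good.  A residue with no other non-gap residue in its
    column is good by convention (a single-row alignment is all good).
    """
    if len(aln.rows) == 1:
        warnings.warn("single-sequence alignment: all sites good", stacklevel=2)
    n, L = len(aln.rows), aln.length
    good = np.zeros((n, L), dtype=bool)
    arr = np.array([list(r.upper()) for r in aln.rows])
    for c in range(L):
        col = arr[:, c]
        is_base = ~np.isin(col, list(GAP_CHARS))
        n_base = int(is_base.sum())
        if n_base == 0:
            continue
        vals, counts = np.unique(col[is_base], return_counts=True)
        count_of = dict(zip(vals, counts))
        for i in range(n):
            if not is_base[i]:
                continue
            others = n_base - 1
            if others == 0:
                good[i, c] = True
            else:
                matches = count_of[col[i]] - 1
                good[i, c] = matches > threshold * others
    return good


def mask_low_quality_windows(
    good: np.ndarray, window: int = 20, min_good: int = 14
) -> np.ndarray:
    """Mask, per row, every sliding window with fewer than ``min_good`` good sites.

    Windows slide one column at a time; the mask is the union over windows.  A
    window with exactly ``min_good`` good sites stays unmasked.  Alignments
    shorter than ``window`` are judged as a single truncated window with a
    pro-rated threshold ``ceil(min_good / window * length)``.
    """
    good = np.asarray(good, dtype=bool)
    n, L = good.shape
    mask = np.zeros((n, L), dtype=bool)
    if L < window:
        thr = int(np.ceil(min_good / window * L))
        for i in range(n):
            if good[i].sum() < thr:
                mask[i, :] = True
        return mask
    counts = np.lib.stride_tricks.sliding_window_view(good, window, axis=1).sum(axis=2)
    for i in range(n):
        bad_starts = np.nonzero(counts[i] < min_good)[0]
        for s in bad_starts:
            mask[i, s : s + window] = True
    return mask


@dataclass
class TrimmedAlignment:
    locus: str
    taxa: list[str]
    rows: list[str]  # masked residues already replaced by the missing symbol
    kept_columns: list[int]  # original column indices retained


def remove_sparse_columns(
    aln: MultipleAlignment,
    mask: np.ndarray | None = None,
    min_unmasked: int = 30,
    missing: str = MISSING_PHYLIP,
) -> TrimmedAlignment:
    """Drop columns with fewer than ``min_unmasked`` unmasked, non-gap residues.

    A column with 29 unmasked bases is removed; one with 30 is kept.  Masked
    residues in surviving columns are written as the missing symbol.
    """
    if mask is None:
        mask = aln.mask
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(aln.rows), aln.length):
        raise ValueError("mask shape must equal alignment shape")
    arr = np.array([list(r.upper()) for r in aln.rows])
    is_base = ~np.isin(arr, list(GAP_CHARS))
    unmasked_bases = (is_base & ~mask).sum(axis=0)
    keep = np.nonzero(unmasked_bases >= min_unmasked)[0]
    out_rows = []
    for i in range(len(aln.rows)):
        chars = []
        for c in keep:
            ch = arr[i, c]
            if mask[i, c] and ch not in GAP_CHARS:
                ch = missing
            chars.append(ch)
        out_rows.append("".join(chars))
    return TrimmedAlignment(aln.locus, list(aln.taxa), out_rows, [int(c) for c in keep])


def mask_and_trim(
    aln: MultipleAlignment,
    similarity_threshold: float = 0.5,
    window: int = 20,
    min_good: int = 14,
    min_unmasked: int = 30,
    missing: str = MISSING_PHYLIP,
) -> tuple[TrimmedAlignment, np.ndarray]:
    """Full per-locus cleaning: good sites -> window mask -> sparse-column trim."""
    good = compute_good_sites(aln, similarity_threshold)
    mask = mask_low_quality_windows(good, window, min_good)
    return remove_sparse_columns(aln, mask, min_unmasked, missing), mask


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]]  # (locus, start, end), 1-based inclusive

    def __post_init__(self) -> None:
        L = self.length
        if any(len(r) != L for r in self.rows):
            raise ValueError("row lengths differ")
        pos = 1
        for locus, start, end in self.partitions:
            if start != pos or end < start:
                raise ValueError("partitions must tile the matrix without overlap")
            pos = end + 1
        if self.partitions and pos != L + 1:
            raise ValueError("partitions do not cover the matrix")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def concatenate_loci(
    trimmed: list[TrimmedAlignment],
    taxon_universe: list[str] | None = None,
    missing: str = MISSING_PHYLIP,
) -> Supermatrix:
    """Concatenate loci (lexicographic order) into a partitioned supermatrix.

    Taxa absent from a locus are padded with the missing symbol across that
    partition.
    """
    if taxon_universe is None:
        taxon_universe = sorted({t for a in trimmed for t in a.taxa})
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxon_universe}
    pos = 1
    for aln in sorted(trimmed, key=lambda a: a.locus):
        if len(set(aln.taxa)) != len(aln.taxa):
            raise ValueError(f"{aln.locus}: duplicate taxon")
        L = len(aln.rows[0]) if aln.rows else 0
        row_of = dict(zip(aln.taxa, aln.rows))
        for t in taxon_universe:
            chunks[t].append(row_of.get(t, missing * L))
        if L:
            parts.append((aln.locus, pos, pos + L - 1))
            pos += L
    return Supermatrix(
        taxa=list(taxon_universe),
        rows=["".join(chunks[t]) for t in taxon_universe],
        partitions=parts,
    )


@dataclass
class AlignmentStats:
    n_loci: int
    total_bp: int
    mean_locus_length: float
    min_locus_length: int
    max_locus_length: int
    informative_sites: int
    percent_missing: float


def count_informative_sites(rows: list[str], missing: str = MISSING_PHYLIP) -> int:
    """Columns with >= 2 states each present in >= 2 taxa (gaps/missing excluded)."""
    arr = np.array([list(r.upper()) for r in rows])
    excluded = list(GAP_CHARS + missing + "N?")
    n_inf = 0
    for c in range(arr.shape[1]):
        col = arr[:, c]
        col = col[~np.isin(col, excluded)]
        if col.size < 4:
            continue
        _vals, counts = np.unique(col, return_counts=True)
        if (counts >= 2).sum() >= 2:
            n_inf += 1
    return int(n_inf)


def compute_alignment_stats(sm: Supermatrix, missing: str = MISSING_PHYLIP) -> AlignmentStats:
    lengths = [end - start + 1 for _l, start, end in sm.partitions]
    arr = np.array([list(r.upper()) for r in sm.rows])
    absent = np.isin(arr, list(GAP_CHARS + missing + "N?"))
    pct = 100.0 * absent.sum() / arr.size if arr.size else 0.0
    return AlignmentStats(
        n_loci=len(sm.partitions),
        total_bp=sm.length,
        mean_locus_length=float(np.mean(lengths)) if lengths else 0.0,
        min_locus_length=min(lengths) if lengths else 0,
        max_locus_length=max(lengths) if lengths else 0,
        informative_sites=count_informative_sites(sm.rows, missing),
        percent_missing=float(pct),
    )


def write_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP: name, whitespace, full row."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.length}\n")
        width = max(len(t) for t in sm.taxa) + 2
        for t, r in zip(sm.taxa, sm.rows):
            fh.write(f"{t:<{width}}{r}\n")


def read_phylip(path: str | Path, partitions: list[tuple[str, int, int]] | None = None) -> Supermatrix:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n, L = (int(x) for x in lines[0].split())
    taxa, rows = [], []
    for ln in lines[1 : n + 1]:
        name, seq = ln.split(None, 1)
        taxa.append(name)
        rows.append(seq.strip())
    if any(len(r) != L for r in rows):
        raise ValueError("row length disagrees with header")
    return Supermatrix(taxa=taxa, rows=rows, partitions=partitions or [("all", 1, L)])


def write_partition_file(sm: Supermatrix, path: str | Path) -> None:
    """RAxML-style partition file: ``DNA, locus = start-end``."""
    with open(path, "w") as fh:
        for locus, start, end in sm.partitions:
            fh.write(f"DNA, {locus} = {start}-{end}\n")


def read_partition_file(path: str | Path) -> list[tuple[str, int, int]]:
    parts = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        _dtype, rest = ln.split(",", 1)
        name, rng = rest.split("=")
        start, end = rng.strip().split("-")
        parts.append((name.strip(), int(start), int(end)))
    return parts
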