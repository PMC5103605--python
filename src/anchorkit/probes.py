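"""Target-capture probe design.

Given candidate locus alignments and reference genomes, this module builds a
spaced-k-mer reference index, scans genomes for homologous regions, filters
loci by per-species copy number, tallies high-copy 15-mer hits onto alignment
columns so repeat-rich regions can be masked, and tiles fixed-length capture
probes across the unmasked target at a chosen tiling density.

Coordinates are 0-based half-open throughout; hit sequences are reported on
the locus-forward strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp

DNA = frozenset("ACGT")


@dataclass(frozen=True)
class SpacedKmerPattern:
    """Positions sampled within a window to form a key.

    The default is the contiguous weight-20 pattern (window 20, all positions
    sampled); spaced patterns trade specificity for substitution tolerance.
    """

    window_length: int = 20
    sampled_positions: tuple[int, ...] = tuple(range(20))

    def __post_init__(self) -> None:
        if len(self.sampled_positions) > self.window_length:
            raise ValueError("pattern weight exceeds window length")
        if any(p < 0 or p >= self.window_length for p in self.sampled_positions):
            raise ValueError("sampled position outside window")

    @property
    def weight(self) -> int:
        return len(self.sampled_positions)

    def key(self, window: str) -> str:
        return "".join(window[p] for p in self.sampled_positions)


@dataclass
class KmerIndex:
    pattern: SpacedKmerPattern
    postings: dict[str, list[tuple[str, int, str]]]  # key -> [(locus, column, strand)]
    locus_keys: dict[str, set[str]]  # locus -> distinct keys (both strands)
    locus_lengths: dict[str, int]  # alignment length per locus


def _ungapped_windows(gapped: str, window: int):
    """Yield (alignment column of window start, window string) over ungapped bases."""
    cols = [i for i, c in enumerate(gapped) if c not in "-."]
    seq = "".join(gapped[i] for i in cols).upper()
    for i in range(len(seq) - window + 1):
        yield cols[i], seq[i : i + window]


def build_spaced_kmer_index(
    locus_alignments: dict[str, list[tuple[str, str]]],
    pattern: SpacedKmerPattern | None = None,
) -> KmerIndex:
    """Index every sequence window of every locus alignment, both strands.

    Windows containing non-ACGT symbols are skipped.  Sequences shorter than
    the window are skipped with a warning.
    """
    if not locus_alignments:
        raise ValueError("no locus alignments given")
    pattern = pattern or SpacedKmerPattern()
    postings: dict[str, list[tuple[str, int, str]]] = {}
    locus_keys: dict[str, set[str]] = {}
    locus_lengths: dict[str, int] = {}
    for locus, rows in locus_alignments.items():
        keys = locus_keys.setdefault(locus, set())
        locus_lengths[locus] = max((len(s) for _, s in rows), default=0)
        for seq_id, gapped in rows:
            n_bases = sum(c not in "-." for c in gapped)
            if n_bases < pattern.window_length:
                warnings.warn(
                    f"{locus}/{seq_id}: shorter than window, skipped", stacklevel=2
                )
                continue
            for col, window in _ungapped_windows(gapped, pattern.window_length):
                if not set(window) <= DNA:
                    continue
                for strand, w in (("+", window), ("-", revcomp(window))):
                    key = pattern.key(w)
                    postings.setdefault(key, []).append((locus, col, strand))
                    if strand == "+":
                        # one strand's worth of keys: a scan of either strand
                        # of an exact copy then recovers fraction ~1.0
                        keys.add(key)
    return KmerIndex(pattern, postings, locus_keys, locus_lengths)


@dataclass
class HomologHit:
    """One homologous genomic region for one locus in one species."""

    locus: str
    species: str
    contig: str
    start: int
    end: int
    strand: str
    matched_keys: int
    key_fraction: float
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if len(self.sequence) > 3000:
            raise ValueError("extracted sequence exceeds the 3000 bp cap")


def scan_genome_for_homologs(
    genome: dict[str, str],
    index: KmerIndex,
    min_key_fraction: float = 0.2,
    species: str = "",
    merge_gap: int = 100,
    max_extract: int = 3000,
) -> list[HomologHit]:
    """Call homologous regions by spaced-key density.

    Matching key positions on a contig are grouped per locus, runs separated
    by more than ``merge_gap`` bp are split, and a region is reported when its
    distinct matched keys cover at least ``min_key_fraction`` of the locus's
    key set.  Each hit's sequence is extracted with flanks, capped at
    ``max_extract`` bp total, and reported on the locus-forward strand.
    """
    window = index.pattern.window_length
    contiguous = index.pattern.sampled_positions == tuple(range(window))
    hits: list[HomologHit] = []
    for contig, seq in genome.items():
        seq = seq.upper()
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_dna = (
            (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
        )
        run = np.concatenate([[0], np.cumsum(is_dna)])
        # locus -> list of (genome pos, key, strand)
        matches: dict[str, list[tuple[int, str, str]]] = {}
        postings_get = index.postings.get
        for i in range(len(seq) - window + 1):
            if run[i + window] - run[i] != window:
                continue
            w = seq[i : i + window]
            key = w if contiguous else index.pattern.key(w)
            posted = postings_get(key)
            if not posted:
                continue
            for locus in {p[0] for p in posted}:
                strands = {s for lo, _c, s in posted if lo == locus}
                strand = "+" if "+" in strands else "-"
                matches.setdefault(locus, []).append((i, key, strand))
        for locus, mlist in matches.items():
            mlist.sort()
            runs: list[list[tuple[int, str, str]]] = [[mlist[0]]]
            for m in mlist[1:]:
                if m[0] - runs[-1][-1][0] <= merge_gap + window:
                    runs[-1].append(m)
                else:
                    runs.append([m])
            total_keys = len(index.locus_keys[locus])
            for run in runs:
                distinct = {k for _p, k, _s in run}
                frac = len(distinct) / total_keys if total_keys else 0.0
                if frac < min_key_fraction:
                    continue
                span_start, span_end = run[0][0], run[-1][0] + window
                flank = max(0, (max_extract - (span_end - span_start)) // 2)
                start = max(0, span_start - flank)
                end = min(len(seq), span_end + flank)
                if end - start > max_extract:
                    end = start + max_extract
                n_minus = sum(1 for _p, _k, s in run if s == "-")
                strand = "-" if n_minus * 2 > len(run) else "+"
                extracted = seq[start:end]
                if strand == "-":
                    extracted = revcomp(extracted)
                hits.append(
                    HomologHit(
                        locus=locus,
                        species=species,
                        contig=contig,
                        start=start,
                        end=end,
                        strand=strand,
                        matched_keys=len(distinct),
                        key_fraction=frac,
                        sequence=extracted,
                    )
                )
    hits.sort(key=lambda h: (h.locus, h.contig, h.start))
    return hits


def filter_loci_by_copy_number(
    hits: list[HomologHit],
    species: list[str] | None = None,
    max_copies: int = 4,
) -> set[str]:
    """Loci where every species has at least one and at most ``max_copies`` hits.

    A species with five or more homologous regions at a locus disqualifies the
    locus; so does a species with none.
    """
    if species is None:
        species = sorted({h.species for h in hits})
    counts: dict[str, dict[str, int]] = {}
    for h in hits:
        counts.setdefault(h.locus, {}).setdefault(h.species, 0)
        counts[h.locus][h.species] += 1
    retained = set()
    for locus, per_sp in counts.items():
        if all(1 <= per_sp.get(sp, 0) <= max_copies for sp in species):
            retained.add(locus)
    return retained


@dataclass
class RepeatKmerDB:
    """Observed k-mers plus all single-substitution neighbors.

    ``positions`` maps every db k-mer to the alignment columns of the observed
    occurrences it derives from, so genome matches can be tallied back onto
    alignment coordinates.
    """

    k: int
    kmers: frozenset[str]
    positions: dict[str, list[tuple[str, tuple[int, ...]]]]


def _neighbors_1sub(kmer: str):
    for i, c in enumerate(kmer):
        for b in "ACGT":
            if b != c:
                yield kmer[:i] + b + kmer[i + 1 :]


def build_repeat_kmer_db(
    species_rows: dict[str, str], k: int = 15
) -> RepeatKmerDB:
    """Build the high-copy screening database for one species.

    ``species_rows`` maps locus id to that species' (gapped) row in the
    trimmed locus alignment.  The db contains every observed k-mer plus every
    k-mer one substitution away; neighbors inherit the columns of the observed
    k-mer they derive from.  Neighbors of neighbors are not included.
    """
    positions: dict[str, list[tuple[str, tuple[int, ...]]]] = {}
    observed: dict[str, list[tuple[str, tuple[int, ...]]]] = {}
    for locus, gapped in species_rows.items():
        cols = [i for i, c in enumerate(gapped) if c not in "-."]
        seq = "".join(gapped[i] for i in cols).upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if not set(w) <= DNA:
                continue
            occ = (locus, tuple(cols[i : i + k]))
            observed.setdefault(w, []).append(occ)
    for w, occs in observed.items():
        positions.setdefault(w, []).extend(occs)
        for nb in _neighbors_1sub(w):
            if nb not in observed:
                positions.setdefault(nb, []).extend(occs)
            else:
                positions.setdefault(nb, [])
                for occ in occs:
                    if occ not in positions[nb]:
                        positions[nb].append(occ)
    return RepeatKmerDB(k=k, kmers=frozenset(positions), positions=positions)


@dataclass
class RepeatMaskProfile:
    """Per-alignment-column repeat-hit counts for one species."""

    species: str
    counts: dict[str, np.ndarray]  # locus -> int counts per alignment column


def tally_repeat_hits(
    genome: dict[str, str],
    db: RepeatKmerDB,
    locus_lengths: dict[str, int],
    species: str = "",
) -> RepeatMaskProfile:
    """Scan the genome for db k-mers and tally matches onto alignment columns.

    Every genome position whose forward k-mer is in the db increments the
    counts at all alignment columns covered by that k-mer's occurrences.
    """
    counts = {
        locus: np.zeros(length, dtype=np.int64)
        for locus, length in locus_lengths.items()
    }
    k = db.k
    for seq in genome.values():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            occs = db.positions.get(seq[i : i + k])
            if not occs:
                continue
            for locus, cols in occs:
                counts[locus][list(cols)] += 1
    return RepeatMaskProfile(species=species, counts=counts)


def mask_high_copy_regions(
    alignment: list[tuple[str, str]],
    profiles: list[RepeatMaskProfile],
    locus: str,
    threshold: int = 100_000,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Soft-mask columns whose count strictly exceeds ``threshold`` in any species.

    A count exactly equal to the threshold is not masked.  Returns the
    alignment with masked columns lower-cased plus the boolean column mask.
    """
    length = max(len(s) for _, s in alignment)
    mask = np.zeros(length, dtype=bool)
    for prof in profiles:
        c = prof.counts.get(locus)
        if c is None:
            continue
        if len(c) != length:
            raise ValueError(f"profile length {len(c)} != alignment length {length}")
        mask |= c > threshold
    out = []
    for name, seq in alignment:
        chars = [c.lower() if mask[i] else c for i, c in enumerate(seq)]
        out.append((name, "".join(chars)))
    return out, mask


@dataclass
class ProbeSet:
    locus: str
    probe_length: int = 120
    density: float = 5.5
    probes: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        starts = [s for s, _ in self.probes]
        if starts != sorted(set(starts)):
            raise ValueError("probe starts must be strictly increasing")
        for _s, p in self.probes:
            if len(p) != self.probe_length:
                raise ValueError("probe of wrong length")


def tile_probes(
    region: str,
    probe_len: int = 120,
    density: float = 5.5,
    mask: np.ndarray | None = None,
    locus: str = "region",
) -> ProbeSet:
    """Tile ``probe_len``-bp probes uniformly at ``density``-fold redundancy.

    Start offsets are ``round(i * probe_len / density)`` with the final probe
    pinned to end at the region boundary.  Probes overlapping a masked column
    (lowercase, or True in ``mask``) or a non-ACGT symbol are dropped, so
    every emitted probe is ``probe_len`` unmasked bases.
    """
    length = len(region)
    if mask is None:
        mask = np.zeros(length, dtype=bool)
    mask = np.asarray(mask, dtype=bool) | np.array(
        [c.islower() or c.upper() not in DNA for c in region]
    )
    if length < probe_len:
        warnings.warn(f"{locus}: region shorter than probe length", stacklevel=2)
        return ProbeSet(locus=locus, probe_length=probe_len, density=density)
    step = probe_len / density
    starts: list[int] = []
    i = 0
    while True:
        s = round(i * step)
        if s > length - probe_len:
            break
        starts.append(s)
        i += 1
    last = length - probe_len
    if not starts or starts[-1] != last:
        starts.append(last)
    probes = []
    for s in sorted(set(starts)):
        if not mask[s : s + probe_len].any():
            probes.append((s, region[s : s + probe_len].upper()))
    return ProbeSet(locus=locus, probe_length=probe_len, density=density, probes=probes)
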