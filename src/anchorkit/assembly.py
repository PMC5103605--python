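"""Read merging and copy-aware, reference-guided assembly.

Overlapping mates are merged into a single longer read (overlap bases resolved
toward the higher-quality call).  Reads are then recruited to a locus
reference by exact seed k-mers, placed at their best ungapped offset, and
clustered by pairwise identity so that gene copies differing by more than the
split divergence assemble into separate contigs.  Weakly supported contigs
(few supporting reads, a signature of index hopping) are filtered out.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._seq import revcomp
from .sim import ReadPair

_BASE_CODE = {b: i for i, b in enumerate("ACGTN")}
_ABSENT = 255


@dataclass
class Read:
    read_id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError("sequence and quality lengths differ")


@dataclass
class Contig:
    """Assembled consensus of one gene copy in one sample."""

    locus: str
    sample: str
    sequence: str
    supporting_read_count: int
    mean_depth: float
    ref_start: int = 0  # offset of the consensus on the recruiting reference

    def __post_init__(self) -> None:
        if self.supporting_read_count < 1:
            raise ValueError("a contig needs at least one supporting read")
        if not set(self.sequence) <= set("ACGTN"):
            raise ValueError("consensus must be over ACGTN")


def merge_overlapping_pair(
    pair: ReadPair, min_overlap: int = 20, max_mismatch_rate: float = 0.05
) -> Read | None:
    """Merge mates sharing an ungapped 3' overlap; None when they do not.

    The reverse mate is reverse-complemented and slid against the forward
    mate; among overlaps of at least ``min_overlap`` bases with mismatch rate
    at most ``max_mismatch_rate`` the one with the most matching bases wins.
    Overlap disagreements are resolved toward the higher-quality base and the
    merged quality is the maximum of the two.
    """
    r1, q1 = pair.seq1, pair.qual1
    r2 = revcomp(pair.seq2)
    q2 = pair.qual2[::-1]
    best = None  # (matches, overlap)
    for o in range(min_overlap, min(len(r1), len(r2)) + 1):
        a, b = r1[-o:], r2[:o]
        mm = sum(x != y for x, y in zip(a, b))
        if mm / o <= max_mismatch_rate:
            score = (o - mm, o)
            if best is None or score > best[:2]:
                best = (o - mm, o)
    if best is None:
        return None
    o = best[1]
    mid_seq, mid_qual = [], []
    for i in range(o):
        x, y = r1[len(r1) - o + i], r2[i]
        qx, qy = q1[len(r1) - o + i], q2[i]
        if x == y:
            mid_seq.append(x)
        else:
            mid_seq.append(x if qx >= qy else y)
        mid_qual.append(max(qx, qy))
    seq = r1[:-o] + "".join(mid_seq) + r2[o:]
    qual = q1[:-o] + "".join(mid_qual) + q2[o:]
    return Read(pair.read_id, seq, qual)


def merge_pairs(
    pairs: list[ReadPair], min_overlap: int = 20, max_mismatch_rate: float = 0.05
) -> tuple[list[Read], dict[str, int]]:
    """Merge every overlapping pair; non-overlapping mates are kept separate."""
    reads: list[Read] = []
    n_merged = 0
    for p in pairs:
        m = merge_overlapping_pair(p, min_overlap, max_mismatch_rate)
        if m is not None:
            reads.append(m)
            n_merged += 1
        else:
            reads.append(Read(p.read_id + "/1", p.seq1, p.qual1))
            reads.append(Read(p.read_id + "/2", revcomp(p.seq2), p.qual2[::-1]))
    report = {"pairs_in": len(pairs), "pairs_merged": n_merged, "reads_out": len(reads)}
    return reads, report


def _place_read(seq: str, ref_kmers: dict[str, list[int]], k: int) -> tuple[int, str] | None:
    """Best ungapped offset of the read on the reference via seed k-mer votes."""
    best = None  # (votes, offset, oriented seq)
    for oriented in (seq, revcomp(seq)):
        votes: Counter[int] = Counter()
        for j in range(len(oriented) - k + 1):
            for p in ref_kmers.get(oriented[j : j + k], ()):
                votes[p - j] += 1
        if votes:
            offset, n = votes.most_common(1)[0]
            if best is None or n > best[0]:
                best = (n, offset, oriented)
    if best is None:
        return None
    return best[1], best[2]


def assemble_locus(
    reads: list[Read],
    reference: str,
    locus: str = "locus",
    sample: str = "sample",
    split_divergence: float = 0.05,
    min_identity_to_ref: float = 0.6,
    seed_k: int = 20,
    min_pair_overlap: int = 20,
) -> list[Contig]:
    """Recruit, place, cluster, and call consensus contigs for one locus.

    Placed reads are phased at variant columns (columns where a minor allele
    is well supported): reads agreeing at the variant sites they share join
    one haplotype cluster.  Phased clusters whose consensus sequences differ
    by at most ``split_divergence`` over their shared span are then merged,
    so gene copies diverging by more than ``split_divergence`` assemble into
    separate contigs while closer copies collapse into one.  Each cluster's
    consensus takes the majority base per column, with ties called N.
    """
    if not reads:
        return []
    ref = reference.upper()
    ref_kmers: dict[str, list[int]] = {}
    for i in range(len(ref) - seed_k + 1):
        ref_kmers.setdefault(ref[i : i + seed_k], []).append(i)

    placed: list[tuple[int, str]] = []
    for r in reads:
        hit = _place_read(r.seq.upper(), ref_kmers, seed_k)
        if hit is None:
            continue
        offset, oriented = hit
        # identity to the reference over the aligned span
        s = max(0, offset)
        e = min(len(ref), offset + len(oriented))
        if e - s >= min_pair_overlap:
            a = ref[s:e]
            b = oriented[s - offset : e - offset]
            ident = sum(x == y for x, y in zip(a, b)) / (e - s)
            if ident < min_identity_to_ref:
                continue
        placed.append((offset, oriented))
    if not placed:
        return []

    lo = min(off for off, _ in placed)
    hi = max(off + len(s) for off, s in placed)
    width = hi - lo
    mat = np.full((len(placed), width), _ABSENT, dtype=np.uint8)
    for idx, (off, s) in enumerate(placed):
        codes = np.frombuffer(s.encode(), dtype=np.uint8)
        mapped = np.full(len(s), _BASE_CODE["N"], dtype=np.uint8)
        for b, c in _BASE_CODE.items():
            mapped[codes == ord(b)] = c
        mat[idx, off - lo : off - lo + len(s)] = mapped

    present = (mat != _ABSENT) & (mat < 4)  # N is never counted

    # variant columns: a well-supported minor allele marks divergent copies
    base_counts = np.zeros((4, width), dtype=np.int32)
    for b in range(4):
        base_counts[b] = ((mat == b) & present).sum(axis=0)
    col_cov = base_counts.sum(axis=0)
    sorted_counts = np.sort(base_counts, axis=0)
    minor = sorted_counts[-2]
    with np.errstate(invalid="ignore", divide="ignore"):
        vcols = np.nonzero(
            (minor >= 2) & (col_cov > 0) & (minor / np.maximum(col_cov, 1) >= 0.2)
        )[0]

    n_reads = len(placed)
    assigned = np.full(n_reads, -1)
    min_phase_sites = 5
    if vcols.size:
        matv = mat[:, vcols]
        presv = present[:, vcols]
        n_v = presv.sum(axis=1)
        core = [i for i in np.argsort(-n_v, kind="stable") if n_v[i] >= min_phase_sites]
        # seeded phasing: grow haplotype clusters by agreement with the
        # cluster's variant-column consensus (>= 90% over >= 5 shared sites)
        vcounts: list[np.ndarray] = []  # per cluster: (4, n_vcols) allele counts
        for seed_i in core:
            if assigned[seed_i] >= 0:
                continue
            cid = len(vcounts)
            vc = np.zeros((4, vcols.size), dtype=np.int32)
            cols = np.nonzero(presv[seed_i])[0]
            vc[matv[seed_i, cols], cols] += 1
            vcounts.append(vc)
            assigned[seed_i] = cid
            grew = True
            while grew:
                grew = False
                for i in core:
                    if assigned[i] >= 0:
                        continue
                    shared = presv[i] & (vc.sum(axis=0) > 0)
                    n_shared = int(shared.sum())
                    # the read must anchor at least half its own variant
                    # sites inside the cluster profile, so a cluster cannot
                    # grow blindly past its copy's territory
                    if n_shared < max(min_phase_sites, 0.5 * n_v[i]):
                        continue
                    allele = vc.argmax(axis=0)
                    unique = (vc == vc.max(axis=0)[None, :]).sum(axis=0) == 1
                    agree = int((shared & unique & (matv[i] == allele)).sum())
                    if agree >= 0.9 * n_shared:
                        cols = np.nonzero(presv[i])[0]
                        vc[matv[i, cols], cols] += 1
                        assigned[i] = cid
                        grew = True
        # remaining reads (too few variant sites) join by overall identity
        roots = sorted(set(int(a) for a in assigned if a >= 0))
        if roots:
            cons_counts = [np.zeros((4, width), dtype=np.int32) for _ in roots]
            for i in range(n_reads):
                if assigned[i] >= 0:
                    cols = np.nonzero(present[i])[0]
                    cons_counts[int(assigned[i])][mat[i, cols], cols] += 1
            for i in range(n_reads):
                if assigned[i] >= 0:
                    continue
                best = None
                for cid, cc in enumerate(cons_counts):
                    covered = cc.sum(axis=0) > 0
                    both = present[i] & covered
                    ov = int(both.sum())
                    if ov < min_pair_overlap:
                        continue
                    cons = cc.argmax(axis=0)
                    unique = (cc == cc.max(axis=0)[None, :]).sum(axis=0) == 1
                    ident = float((both & unique & (mat[i] == cons)).sum()) / ov
                    if best is None or ident > best[0]:
                        best = (ident, cid)
                assigned[i] = best[1] if best is not None else len(cons_counts)
    # no variant columns (or stragglers with nothing to compare): one cluster
    next_cid = int(assigned.max()) + 1 if n_reads else 0
    solo = assigned < 0
    if solo.any():
        assigned[solo] = next_cid

    clusters = {}
    for i in range(n_reads):
        clusters.setdefault(int(assigned[i]), []).append(i)

    # merge haplotype clusters whose consensuses stay within split_divergence
    def cluster_consensus_counts(members: list[int]) -> np.ndarray:
        cc = np.zeros((4, width), dtype=np.int32)
        for i in members:
            cols = np.nonzero(present[i])[0]
            cc[mat[i, cols], cols] += 1
        return cc

    roots = sorted(clusters)
    counts_of = {r: cluster_consensus_counts(clusters[r]) for r in roots}
    merged = True
    while merged and len(roots) > 1:
        merged = False
        for ai in range(len(roots) - 1):
            for bi in range(ai + 1, len(roots)):
                ra, rb = roots[ai], roots[bi]
                ca, cb = counts_of[ra], counts_of[rb]
                cov_a, cov_b = ca.sum(axis=0) > 0, cb.sum(axis=0) > 0
                both = cov_a & cov_b
                span = int(both.sum())
                if span >= 50:
                    mm = (ca.argmax(axis=0) != cb.argmax(axis=0)) & both
                    div = float(mm.sum()) / span
                    if div > split_divergence:
                        continue
                # small shared span or low divergence: same copy
                clusters[ra].extend(clusters.pop(rb))
                counts_of[ra] = counts_of[ra] + counts_of.pop(rb)
                roots.pop(bi)
                merged = True
                break
            if merged:
                break

    contigs = []
    for _cid, members in sorted(clusters.items()):
        members = sorted(members)
        sub = mat[members]
        cov = (sub != _ABSENT).sum(axis=0)
        covered = np.nonzero(cov > 0)[0]
        if covered.size == 0:
            continue
        span = slice(int(covered[0]), int(covered[-1]) + 1)
        cons = []
        for col in range(span.start, span.stop):
            col_bases = sub[:, col]
            col_bases = col_bases[col_bases != _ABSENT]
            if col_bases.size == 0:
                cons.append("N")
                continue
            counts = np.bincount(col_bases, minlength=5)[:4]  # N never wins
            top = counts.max()
            if top == 0 or (counts == top).sum() > 1:
                cons.append("N")
            else:
                cons.append("ACGT"[int(counts.argmax())])
        seq = "".join(cons)
        contigs.append(
            Contig(
                locus=locus,
                sample=sample,
                sequence=seq,
                supporting_read_count=len(members),
                mean_depth=float(cov[span].mean()),
                ref_start=lo + span.start,
            )
        )
    contigs.sort(key=lambda c: -c.supporting_read_count)
    return contigs


def filter_contigs(contigs: list[Contig], min_reads: int = 50) -> list[Contig]:
    """Keep contigs supported by at least ``min_reads`` reads.

    A contig derived from 49 reads is dropped; one from 50 is kept.  The low
    default guards against cross-sample index-hopping artifacts.
    """
    return [c for c in contigs if c.supporting_read_count >= min_reads]
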