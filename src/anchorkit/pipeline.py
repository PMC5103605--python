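"""End-to-end synthetic enrichment experiment with planted truth.

Wires the whole toolkit together on generated data: candidate loci from
three reference species, genome scans and the copy-number filter (with
high-copy loci planted in one reference), per-sample read simulation,
merging and copy-aware assembly, orthology clustering with the occupancy
filter (with planted low-occupancy loci), reference-coordinate alignment,
masking/trimming, and supermatrix statistics.

The defaults are the study conditions of the synthetic experiment: 12 loci
by 20 taxa, 3 loci carrying extra gene copies in one reference species (so
the copy-number filter must drop them) and 2 loci enriched in only half the
samples (so the occupancy filter must drop them), leaving 7 loci in the
supermatrix.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from . import alignments, assembly, orthology, probes, sim
from ._seq import random_seq


@dataclass
class PipelineResult:
    n_loci_simulated: int
    loci_after_copy_filter: list[str]
    loci_after_occupancy: list[str]
    expected_retained: list[str]
    supermatrix: alignments.Supermatrix
    stats: alignments.AlignmentStats
    contig_counts: dict[str, int] = field(default_factory=dict)


def _diverge(seq: str, p: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hit = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hit:
        out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def run_synthetic_pipeline(
    seed: int = 0,
    n_taxa: int = 20,
    n_loci: int = 12,
    n_high_copy: int = 3,
    n_sparse: int = 2,
    locus_length: int = 800,
    coverage: float = 40.0,
    substitution_rate: float = 0.02,
    extra_copies: int = 5,
    min_key_fraction: float = 0.2,
    max_copies: int = 4,
    min_reads: int = 50,
    min_taxa_fraction: float = 0.72,
    min_unmasked: int = 15,
) -> PipelineResult:
    """Design -> assemble -> orthologs -> trim -> concat -> stats on planted data.

    High-copy loci get ``extra_copies`` additional diverged copies planted in
    the first reference species' genome, so they fail the "<= 4 homologs per
    species" rule.  Sparse loci are sequenced in only half the samples, so
    they fail the occupancy rule.  ``min_unmasked`` is scaled to the taxon
    count (the printed default of 30 assumes >170 taxa).
    """
    rng = np.random.default_rng(seed)
    tree = sim.simulate_species_tree(n_taxa, seed)
    taxa = sorted(
        (lf.taxon.label for lf in tree.leaf_node_iter()),
        key=lambda t: int(t[1:]),
    )
    ref_species = taxa[:3]
    locus_ids = [f"L{i:03d}" for i in range(n_loci)]
    high_copy = set(locus_ids[:n_high_copy])
    sparse = set(locus_ids[n_high_copy : n_high_copy + n_sparse])
    expected = [l for l in locus_ids if l not in high_copy and l not in sparse]

    # per-locus homolog sequences for every taxon
    locus_seqs: dict[str, dict[str, str]] = {}
    for li, locus in enumerate(locus_ids):
        cfg = sim.SimulationConfig(
            seed=seed,
            n_taxa=n_taxa,
            locus_length=locus_length,
            substitution_rate=substitution_rate,
            coverage=coverage,
        )
        seqs, _truth = sim.evolve_locus(tree, cfg, locus_id=locus, seed=seed * 997 + li)
        locus_seqs[locus] = {taxon: copies[0] for taxon, copies in seqs.items()}

    # candidate alignments: the three reference species' rows (ungapped)
    candidates = {
        locus: [(sp, locus_seqs[locus][sp]) for sp in ref_species]
        for locus in locus_ids
    }
    # reference genomes, with extra copies of the high-copy loci in species 1
    genomes: dict[str, dict[str, str]] = {}
    for sp in ref_species:
        parts = [random_seq(300, rng)]
        for locus in locus_ids:
            parts += [locus_seqs[locus][sp], random_seq(300, rng)]
            if sp == ref_species[0] and locus in high_copy:
                for _c in range(extra_copies):
                    parts += [
                        _diverge(locus_seqs[locus][sp], 0.03, rng),
                        random_seq(300, rng),
                    ]
        genomes[sp] = {"chr1": "".join(parts)}

    index = probes.build_spaced_kmer_index(candidates)
    hits = []
    for sp in ref_species:
        hits += probes.scan_genome_for_homologs(
            genomes[sp], index, min_key_fraction=min_key_fraction, species=sp
        )
    retained_design = sorted(
        probes.filter_loci_by_copy_number(hits, ref_species, max_copies=max_copies)
    )

    # sequencing and assembly, per retained locus and sample
    contigs_by_locus: dict[str, list[assembly.Contig]] = {}
    contig_counts: dict[str, int] = {}
    for locus in retained_design:
        samples = taxa if locus not in sparse else taxa[: n_taxa // 2]
        reference = locus_seqs[locus][ref_species[0]]
        kept: list[assembly.Contig] = []
        for si, taxon in enumerate(samples):
            cfg = sim.SimulationConfig(
                seed=seed, locus_length=locus_length, coverage=coverage
            )
            pairs = sim.simulate_reads(
                locus_seqs[locus][taxon], cfg, read_prefix=f"{locus}|{taxon}",
                seed=(seed * 7919 + zlib.crc32(f"{locus}|{taxon}".encode())) % 2**31,
            )
            reads, _rep = assembly.merge_pairs(pairs)
            cs = assembly.assemble_locus(reads, reference, locus=locus, sample=taxon)
            kept += assembly.filter_contigs(cs, min_reads=min_reads)
        contigs_by_locus[locus] = kept
        contig_counts[locus] = len(kept)

    # orthology + occupancy filter
    retained_loci: list[str] = []
    cluster_rows: dict[str, list[tuple[str, str, int]]] = {}
    for locus in retained_design:
        recs = [
            (f"{locus}|{c.sample}", c.sample, c.sequence)
            for c in contigs_by_locus[locus]
        ]
        offsets = {f"{locus}|{c.sample}": c.ref_start for c in contigs_by_locus[locus]}
        if len(recs) < 2:
            continue
        dm = orthology.build_distance_matrix(recs)
        clusters = orthology.cluster_orthologs(dm, locus)
        kept = orthology.filter_clusters_by_occupancy(
            clusters, min_taxa_fraction, n_species_universe=n_taxa
        )
        if not kept:
            continue
        best = max(kept, key=lambda c: len(c.species))
        seq_of = {rid: s for rid, _sp, s in recs}
        retained_loci.append(locus)
        cluster_rows[locus] = [
            (rid.split("|")[1], seq_of[rid], offsets[rid]) for rid in best.members
        ]

    # reference-coordinate alignment (assembly is ungapped), then trim
    trimmed = []
    for locus in retained_loci:
        rows = cluster_rows[locus]
        width = max(off + len(s) for _t, s, off in rows)
        taxa_l = [t for t, _s, _o in rows]
        gapped = ["-" * off + s + "-" * (width - off - len(s)) for _t, s, off in rows]
        aln = alignments.MultipleAlignment(locus, taxa_l, gapped)
        tr, _mask = alignments.mask_and_trim(aln, min_unmasked=min_unmasked)
        trimmed.append(tr)

    sm = alignments.concatenate_loci(trimmed, taxon_universe=taxa)
    st = alignments.compute_alignment_stats(sm)
    return PipelineResult(
        n_loci_simulated=n_loci,
        loci_after_copy_filter=retained_design,
        loci_after_occupancy=retained_loci,
        expected_retained=expected,
        supermatrix=sm,
        stats=st,
        contig_counts=contig_counts,
    )
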