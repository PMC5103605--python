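"""Alignment masking, trimming, concatenation, and statistics."""

from __future__ import annotations

import numpy as np
import pytest

from anchorkit import alignments, sim
from anchorkit._seq import random_seq


def uniform_alignment(n, L, char="A"):
    taxa = [f"t{i}" for i in range(n)]
    return alignments.MultipleAlignment("L", taxa, [char * L for _ in taxa])


class TestGoodSites:
    def test_identical_column_all_good(self):
        aln = uniform_alignment(10, 5)
        assert alignments.compute_good_sites(aln).all()

    def test_six_four_split_derived_counts(self):
        rows = ["A"] * 6 + ["C"] * 4
        aln = alignments.MultipleAlignment("L", [f"t{i}" for i in range(10)], rows)
        good = alignments.compute_good_sites(aln)
        # A rows: 5/9 > 0.5 good; C rows: 3/9 not good
        assert good[:6, 0].all() and not good[6:, 0].any()

    def test_gap_never_good(self):
        rows = ["A", "A", "-"]
        aln = alignments.MultipleAlignment("L", ["a", "b", "c"], rows)
        good = alignments.compute_good_sites(aln)
        assert good[0, 0] and good[1, 0] and not good[2, 0]

    def test_single_sequence_all_good_with_warning(self):
        aln = alignments.MultipleAlignment("L", ["a"], ["ACGT"])
        with pytest.warns(UserWarning):
            good = alignments.compute_good_sites(aln)
        assert good.all()


class TestWindowMask:
    def test_all_good_no_mask(self):
        good = np.ones((4, 60), bool)
        assert not alignments.mask_low_quality_windows(good).any()

    def test_boundary_13_vs_14_good_sites(self):
        good13 = np.ones((1, 60), bool)
        good13[0, :7] = False  # first window has 13 good sites
        m = alignments.mask_low_quality_windows(good13)
        assert m[0, :20].all()
        good14 = np.ones((1, 60), bool)
        good14[0, :6] = False  # 14 good sites
        assert not alignments.mask_low_quality_windows(good14)[0].any()

    def test_short_alignment_prorated(self):
        good = np.ones((1, 10), bool)
        good[0, :5] = False  # 5/10 good < ceil(14/20*10)=7
        assert alignments.mask_low_quality_windows(good)[0].all()
        good2 = np.ones((1, 10), bool)
        good2[0, :3] = False  # 7/10 good
        assert not alignments.mask_low_quality_windows(good2)[0].any()

    def test_planted_shuffled_segment_masked(self):
        n_ok_seg = n_ok_clean = 0
        for seed in range(10):
            tree = sim.simulate_species_tree(35, seed)
            cfg = sim.SimulationConfig(seed=seed, locus_length=300, substitution_rate=0.02)
            seqs, _ = sim.evolve_locus(tree, cfg, seed=seed)
            taxa = sorted(seqs)
            rows = [seqs[t][0] for t in taxa]
            rows[3], seg = sim.inject_shuffled_segment(rows[3], 100, 40, seed)
            aln = alignments.MultipleAlignment("L", taxa, rows)
            good = alignments.compute_good_sites(aln)
            mask = alignments.mask_low_quality_windows(good)
            seg_cols = np.arange(*seg)
            clean = np.ones(300, bool)
            clean[seg_cols] = False
            n_ok_seg += mask[3, seg_cols].mean() >= 0.95
            n_ok_clean += (1 - mask[:, clean].mean()) >= 0.95
        assert n_ok_seg >= 9 and n_ok_clean >= 9


class TestSparseColumns:
    def test_boundary_29_30_unmasked_bases(self):
        aln = uniform_alignment(40, 3)
        mask = np.zeros((40, 3), bool)
        mask[:11, 0] = True  # 29 unmasked
        mask[:10, 1] = True  # 30 unmasked
        tr = alignments.remove_sparse_columns(aln, mask)
        assert tr.kept_columns == [1, 2]

    def test_no_mask_no_gaps_unchanged(self):
        aln = uniform_alignment(30, 10)
        tr = alignments.remove_sparse_columns(aln, np.zeros((30, 10), bool))
        assert tr.rows == aln.rows

    def test_masked_residues_become_missing(self):
        aln = uniform_alignment(35, 4)
        mask = np.zeros((35, 4), bool)
        mask[0, 2] = True
        tr = alignments.remove_sparse_columns(aln, mask)
        assert tr.rows[0][2] == "?"

    def test_gaps_excluded_from_unmasked_count(self):
        rows = ["A" * 4] * 29 + ["-AAA"]
        aln = alignments.MultipleAlignment("L", [f"t{i}" for i in range(30)], rows)
        tr = alignments.remove_sparse_columns(aln, np.zeros((30, 4), bool))
        assert tr.kept_columns == [1, 2, 3]  # col 0 has 29 bases only

    def test_matches_brute_force_recount(self, rng):
        for trial in range(10):
            n, L = 34, 25
            rows = ["".join(rng.choice(list("ACGT-"), size=L)) for _ in range(n)]
            aln = alignments.MultipleAlignment("L", [f"t{i}" for i in range(n)], rows)
            mask = rng.random((n, L)) < 0.2
            tr = alignments.remove_sparse_columns(aln, mask, min_unmasked=20)
            want = [
                c for c in range(L)
                if sum(
                    rows[i][c] not in "-." and not mask[i, c] for i in range(n)
                ) >= 20
            ]
            assert tr.kept_columns == want

    def test_monotone_in_min_unmasked(self, rng):
        n, L = 40, 30
        rows = ["".join(rng.choice(list("ACGT-"), size=L)) for _ in range(n)]
        aln = alignments.MultipleAlignment("L", [f"t{i}" for i in range(n)], rows)
        mask = rng.random((n, L)) < 0.3
        kept = [
            len(alignments.remove_sparse_columns(aln, mask, min_unmasked=k).kept_columns)
            for k in (10, 20, 30)
        ]
        assert kept[0] >= kept[1] >= kept[2]

    def test_mask_and_trim_idempotent(self):
        aln = uniform_alignment(40, 60)
        tr1, _ = alignments.mask_and_trim(aln)
        aln2 = alignments.MultipleAlignment("L", tr1.taxa, tr1.rows)
        tr2, _ = alignments.mask_and_trim(aln2)
        assert tr2.rows == tr1.rows


class TestConcatenation:
    def test_partition_arithmetic(self):
        t1 = alignments.TrimmedAlignment("a", ["x", "y"], ["A" * 100, "C" * 100], [])
        t2 = alignments.TrimmedAlignment("b", ["x", "y"], ["G" * 200, "T" * 200], [])
        sm = alignments.concatenate_loci([t1, t2])
        assert sm.length == 300
        assert sm.partitions == [("a", 1, 100), ("b", 101, 300)]

    def test_absent_taxon_padded_with_missing(self):
        t1 = alignments.TrimmedAlignment("a", ["x"], ["A" * 100], [])
        t2 = alignments.TrimmedAlignment("b", ["x", "y"], ["G" * 200, "T" * 200], [])
        sm = alignments.concatenate_loci([t1, t2])
        row_y = sm.rows[sm.taxa.index("y")]
        assert row_y[:100] == "?" * 100

    def test_single_locus_identity(self):
        t1 = alignments.TrimmedAlignment("a", ["x", "y"], ["ACGT", "ACGA"], [])
        sm = alignments.concatenate_loci([t1])
        assert sm.rows == t1.rows and sm.partitions == [("a", 1, 4)]

    def test_duplicate_taxon_rejected(self):
        t1 = alignments.TrimmedAlignment("a", ["x", "x"], ["AC", "GT"], [])
        with pytest.raises(ValueError, match="duplicate"):
            alignments.concatenate_loci([t1])

    def test_deterministic_locus_order(self):
        ts = [
            alignments.TrimmedAlignment(l, ["x"], ["A" * 10], [])
            for l in ("b", "a", "c")
        ]
        sm = alignments.concatenate_loci(ts)
        assert [p[0] for p in sm.partitions] == ["a", "b", "c"]


class TestStats:
    def test_invariant_alignment_no_informative_sites(self):
        sm = alignments.concatenate_loci(
            [alignments.TrimmedAlignment("a", ["x", "y", "z", "w"], ["ACGT"] * 4, [])]
        )
        assert alignments.compute_alignment_stats(sm).informative_sites == 0

    def test_hand_built_toy_counts(self):
        # 4 taxa x 8 columns; columns 0 and 1 informative; 6 missing cells
        rows = [
            "AAC?ACGT",
            "AACGAC?T",
            "CGC?ACGT",
            "CG???CGT",
            # col0: A,A,C,C informative; col1: A,A,G,G informative
            # col2: C,C,C not informative; six '?' cells in total
        ]
        sm = alignments.Supermatrix(["a", "b", "c", "d"], rows, [("L", 1, 8)])
        st = alignments.compute_alignment_stats(sm)
        assert st.informative_sites == 2
        assert st.percent_missing == pytest.approx(100 * 6 / 32)

    def test_mean_locus_length(self):
        t1 = alignments.TrimmedAlignment("a", ["x"], ["A" * 120], [])
        t2 = alignments.TrimmedAlignment("b", ["x"], ["A" * 60], [])
        st = alignments.compute_alignment_stats(alignments.concatenate_loci([t1, t2]))
        assert st.mean_locus_length == pytest.approx(90.0)
        assert (st.min_locus_length, st.max_locus_length) == (60, 120)


class TestExternalAligner:
    def test_prealigned_passthrough(self):
        recs = [("a", "ACGT-A"), ("b", "ACGTTA")]
        log = []
        aln = alignments.align_locus_external(recs, log=log)
        assert aln.rows == ["ACGT-A", "ACGTTA"]
        assert "pre-aligned" in log[0]

    def test_identical_sequences_align_without_gaps(self, rng):
        s = random_seq(60, rng)
        recs = [("a", s), ("b", s), ("c", s + "ACGT")]
        log = []
        aln = alignments.align_locus_external(recs, log=log)
        assert "-" not in aln.rows[0][: len(s)]
        assert "mafft" in log[0] and "--genafpair" in log[0]

    def test_missing_aligner_errors(self):
        with pytest.raises(RuntimeError):
            alignments.align_locus_external(
                [("a", "ACGT"), ("b", "ACG")], aligner="no-such-aligner-xyz"
            )


class TestRoundTrip:
    def test_phylip_partition_round_trip_stats_identical(self, tmp_path, rng):
        loci = []
        for li in range(3):
            L = int(rng.integers(40, 80))
            rows = ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(6)]
            loci.append(
                alignments.TrimmedAlignment(f"L{li}", [f"t{i}" for i in range(6)], rows, [])
            )
        sm = alignments.concatenate_loci(loci)
        st = alignments.compute_alignment_stats(sm)
        phy, part = tmp_path / "sm.phy", tmp_path / "sm.part"
        alignments.write_phylip(sm, phy)
        alignments.write_partition_file(sm, part)
        back = alignments.read_phylip(phy, alignments.read_partition_file(part))
        assert back.rows == sm.rows and back.partitions == sm.partitions
        assert alignments.compute_alignment_stats(back) == st
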