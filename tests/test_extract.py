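"""Repertoire extraction and UMI error correction."""

from trarep import (
    Allele,
    Molecule,
    SimConfig,
    build_v_dictionary,
    parse_reads,
    simulate_recombination,
    umi_correct_stage1,
    umi_correct_stage2,
)
from trarep.synthdata import molecule_cdna, simulate_reads


def mol(umi, cdr3, reads, v="V1", j="J1"):
    return Molecule(umi=umi, v_id=v, j_id=j, cdr3=cdr3, reads=reads)


class TestParseReads:
    def test_error_free_identity(self, small_locus):
        cfg = SimConfig(n_v=10, n_j=8, n_cells=200, seq_error_sub=0.0,
                        seq_error_ins=0.0, seed=31)
        asm = simulate_recombination(small_locus, cfg)
        reads, truth = simulate_reads(asm, small_locus, cfg)
        mols, stats = parse_reads(reads, small_locus.segments, min_reads=1,
                                  umi_len=cfg.umi_len)
        true_mols = truth.drop_duplicates("molecule_id")
        true_keys = set(zip(true_mols.umi, true_mols.v_id, true_mols.cdr3,
                            true_mols.j_id))
        assert {m.key for m in mols} == true_keys
        assert stats.unmatched_v == 0 and stats.unmatched_j == 0

    def test_min_reads_threshold_drops_singletons(self, small_locus):
        cfg = SimConfig(n_v=10, n_j=8, n_cells=30, seq_error_sub=0.0,
                        seq_error_ins=0.0, reads_per_molecule_mean=0.01,
                        seed=32)
        asm = simulate_recombination(small_locus, cfg)
        reads, _ = simulate_reads(asm, small_locus, cfg)  # all singletons
        mols1, _ = parse_reads(reads, small_locus.segments, min_reads=1,
                               umi_len=cfg.umi_len)
        mols2, stats2 = parse_reads(reads, small_locus.segments, min_reads=2,
                                    umi_len=cfg.umi_len)
        assert len(mols1) > 0
        assert len(mols2) == 0
        assert stats2.below_threshold == len(mols1)

    def test_unknown_v_counted_not_fatal(self, small_locus):
        cfg = SimConfig(n_v=10, n_j=8, n_cells=20, seq_error_sub=0.0,
                        seq_error_ins=0.0, seed=33)
        asm = simulate_recombination(small_locus, cfg)
        reads, _ = simulate_reads(asm, small_locus, cfg)
        # withhold the V dictionary entries actually used
        used = {a.v_id for a in asm}
        segs = [s for s in small_locus.segments if s.id not in used]
        mols, stats = parse_reads(reads, segs, min_reads=1,
                                  umi_len=cfg.umi_len)
        assert stats.unmatched_v > 0
        assert len(mols) == 0

    def test_nonselectable_allele_flagged(self, small_locus):
        cfg = SimConfig(n_v=10, n_j=8, n_cells=200, seq_error_sub=0.0,
                        seq_error_ins=0.0, nonselectable_fraction=0.5,
                        seed=34)
        asm = simulate_recombination(small_locus, cfg)
        reads, truth = simulate_reads(asm, small_locus, cfg)
        mols, _ = parse_reads(reads, small_locus.segments, min_reads=1,
                              umi_len=cfg.umi_len)
        truth_allele = dict(zip(truth.umi, truth.allele))
        assert any(m.allele is Allele.NON_SELECTABLE for m in mols)
        for m in mols:
            assert m.allele.value == truth_allele[m.umi]


class TestStage1:
    def test_neighbour_pair_collapses_to_top_reads(self):
        a = mol("AAAAAAAAAAAA", "ACGTACGT", 10)
        b = mol("AAAAAAAAAAAT", "ACGTACGT", 1)
        out = umi_correct_stage1([a, b])
        assert len(out) == 1
        assert out[0].umi == a.umi
        assert out[0].reads == 11

    def test_distant_umis_untouched(self):
        a = mol("AAAAAAAAAAAA", "ACGTACGT", 5)
        b = mol("AAAAAAAAGGGG", "ACGTACGT", 3)
        out = umi_correct_stage1([a, b])
        assert len(out) == 2

    def test_chain_component_single_survivor(self):
        """A-B and B-C adjacent, A-C not: one survivor per component,
        chosen by max reads (brute-force component check)."""
        a = mol("AAAAAAAAAAAA", "ACGTACGT", 5)
        b = mol("AAAAAAAAAAAT", "ACGTACGT", 9)
        c = mol("AAAAAAAAAATT", "ACGTACGT", 2)
        assert sum(x != y for x, y in zip(a.umi, c.umi)) == 2  # not adjacent
        out = umi_correct_stage1([a, b, c])
        assert len(out) == 1
        assert out[0].umi == b.umi and out[0].reads == 16

    def test_read_tie_breaks_to_lexicographic_umi(self):
        a = mol("AAAAAAAAAAAC", "ACGTACGT", 5)
        b = mol("AAAAAAAAAAAA", "ACGTACGT", 5)
        out = umi_correct_stage1([a, b])
        assert out[0].umi == b.umi

    def test_different_cdr3_lengths_never_merge(self):
        a = mol("AAAAAAAAAAAA", "ACGTACGT", 5)
        b = mol("AAAAAAAAAAAT", "ACGTACG", 5)
        assert len(umi_correct_stage1([a, b])) == 2

    def test_reads_conserved(self, small_locus):
        cfg = SimConfig(n_v=10, n_j=8, n_cells=500, seq_error_sub=0.004,
                        seed=35)
        asm = simulate_recombination(small_locus, cfg)
        reads, _ = simulate_reads(asm, small_locus, cfg)
        mols, _ = parse_reads(reads, small_locus.segments, min_reads=1,
                              umi_len=cfg.umi_len)
        out = umi_correct_stage1(mols)
        assert sum(m.reads for m in out) == sum(m.reads for m in mols)
        assert len(out) <= len(mols)

    def test_idempotent(self, small_locus):
        cfg = SimConfig(n_v=10, n_j=8, n_cells=500, seq_error_sub=0.004,
                        seed=36)
        asm = simulate_recombination(small_locus, cfg)
        reads, _ = simulate_reads(asm, small_locus, cfg)
        mols, _ = parse_reads(reads, small_locus.segments, min_reads=1,
                              umi_len=cfg.umi_len)
        once = umi_correct_stage1(mols)
        twice = umi_correct_stage1(once)
        assert [m.key for m in twice] == [m.key for m in once]


class TestStage2:
    def test_close_cdr3s_conflict_most_read_wins(self):
        a = mol("AAAAAAAAAAAA", "ACGTACGTA", 5)
        b = mol("AAAAAAAAAAAA", "ACGTACGTT", 2)  # Levenshtein 1
        out = umi_correct_stage2([a, b])
        assert len(out) == 1 and out[0].cdr3 == a.cdr3

    def test_distant_cdr3s_both_survive(self):
        a = mol("AAAAAAAAAAAA", "ACGTACGTA", 5)
        b = mol("AAAAAAAAAAAA", "TTTTGGGGCCC", 2)  # Levenshtein 7+
        assert len(umi_correct_stage2([a, b])) == 2

    def test_unique_umis_pass_through(self):
        ms = [mol(f"AAAAAAAAAAA{c}", "ACGTACGT", 3) for c in "ACGT"]
        out = umi_correct_stage2(ms)
        assert sorted(m.key for m in out) == sorted(m.key for m in ms)

    def test_idempotent(self):
        ms = [mol("AAAAAAAAAAAA", "ACGTACGTA", 5),
              mol("AAAAAAAAAAAA", "ACGTACGTT", 2),
              mol("AAAAAAAAAAAA", "TTTTGGGGCCC", 4)]
        once = umi_correct_stage2(ms)
        assert [m.key for m in umi_correct_stage2(once)] == \
            [m.key for m in once]


class TestBuildVDictionary:
    def test_recovers_germline_termini(self, small_locus):
        cfg = SimConfig(n_v=10, n_j=8, n_cells=400, seq_error_sub=0.0,
                        seq_error_ins=0.0, seed=37)
        asm = simulate_recombination(small_locus, cfg)
        in_frame = [a for a in asm if a.in_frame]
        cdnas = [molecule_cdna(a, small_locus) for a in in_frame]
        germ = {s.id: s.seq[:s.frame_anchor + 3]
                for s in small_locus.v_segments}
        df = build_v_dictionary(cdnas, germ)
        mapped = set(df["germline_id"].dropna())
        used = {a.v_id for a in in_frame}
        assert mapped == used
        assert (df["distance"].dropna() == 0).all()
        for seq, gid in zip(df["expressed_v"], df["germline_id"]):
            if gid is not None:
                assert seq == germ[gid][-180:]

    def test_short_orf_rejected(self):
        # 50-codon stop-free fragment with plausible signatures cannot pass
        cdna = ("TGT" * 10 + "TTCGGAGCAGGAACAAAGCTG" + "TGCCTGAGCACCGAT"
                + "TTC" * 5)
        assert build_v_dictionary([cdna]).empty

    def test_distant_expressed_v_left_unmapped(self, small_locus):
        cfg = SimConfig(n_v=10, n_j=8, n_cells=50, seq_error_sub=0.0,
                        seq_error_ins=0.0, seed=38)
        asm = simulate_recombination(small_locus, cfg)
        in_frame = [a for a in asm if a.in_frame]
        cdnas = [molecule_cdna(a, small_locus) for a in in_frame]
        # germline with 6 substitutions inside the compared 180-nt window:
        # beyond the 5-nt mapping tolerance
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}

        def break_entry(v):
            # 10 substitutions scattered through the compared window, so
            # no alignment shift can absorb them below the 5-nt tolerance
            head, window = v[:-60], list(v[-60:])
            for i in range(0, 60, 6):
                window[i] = flip[window[i]]
            return head + "".join(window)

        germ = {s.id: break_entry(s.seq[:s.frame_anchor + 3])
                for s in small_locus.v_segments}
        df = build_v_dictionary(cdnas, germ)
        assert df["germline_id"].isna().all()
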