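"""Junction provenance annotation against hand-built and brute-force oracles."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trarep import (
    JoinClass,
    annotate_junction,
    annotate_repertoire,
    default_patterns,
    match_pattern,
    repertoire_summary,
    simulate_recombination,
)
from trarep.model import Clonotype
from trarep.synthdata import SimConfig, V_TERMINUS, generate_germline, revcomp


def brute_force_decomposition(cdr3, v_germ, j_germ):
    """Enumerate all (v_keep, j_keep) germline attributions and pick the
    maximal one (ties toward larger v_keep)."""
    n = len(cdr3)
    best = None
    for a in range(min(n, len(v_germ)) + 1):
        if cdr3[:a] != v_germ[:a]:
            continue
        for b in range(min(n, len(j_germ)) + 1):
            if b and cdr3[n - b:] != j_germ[len(j_germ) - b:]:
                continue
            key = (a + b, a)
            if best is None or key > best[0]:
                best = (key, a, b)
    _, a, b = best
    return a, b, max(0, a + b - n), max(0, n - a - b)


class TestAnnotateJunction:
    def test_worked_microhomology_example(self):
        """TG overlap: labels VVVVVVVAA..., mh 2, v_trim 5, pattern 1."""
        j_germ = "TGCCAGCAAGTAGTTCGCCT"[:20]
        cdr3 = "TGTGCTCTG" + j_germ[2:]
        ann = annotate_junction(cdr3, V_TERMINUS, j_germ)
        assert ann.labels.startswith("VVVVVVVAA")
        assert ann.mh_len == 2
        assert ann.v_trim == 5 and ann.j_trim == 0
        assert ann.join_class is JoinClass.MH
        pid = match_pattern(ann, cdr3, V_TERMINUS, j_germ)
        assert pid == 1

    def test_blunt_join(self):
        v, j = "ACGT", "GGAA"
        ann = annotate_junction(v + j, v, j)
        assert ann.join_class is JoinClass.BLUNT
        assert ann.mh_len == 0 and ann.n_len == 0
        assert ann.labels == "VVVVJJJJ"

    def test_non_templated_gap(self):
        v, j = "ACGT", "GGAA"
        ann = annotate_junction(v + "TTT" + j, v, j)
        assert ann.n_len == 3
        assert ann.join_class is JoinClass.N_INS
        assert not ann.tdt_free

    def test_p_nucleotides_flagged(self):
        v, j = "ACCAGTC", "GGAATTG"
        cdr3 = v + revcomp(v[-2:]) + j
        ann = annotate_junction(cdr3, v, j)
        assert ann.p_len == 2
        assert ann.join_class is JoinClass.P
        assert ann.tdt_free

    def test_no_v_match_is_legal(self):
        ann = annotate_junction("TTTT", "CCCC", "GGGG")
        assert ann.v_match == 0 and ann.j_match == 0
        assert set(ann.labels) == {"N"}

    def test_labels_partition_cdr3(self, small_assemblies, lookups):
        v_lookup, j_lookup = lookups
        for a in small_assemblies[:500]:
            ann = annotate_junction(a.cdr3, v_lookup[a.v_id],
                                    j_lookup[a.j_id])
            assert len(ann.labels) == len(a.cdr3)
            assert ann.labels.count("A") == ann.mh_len
            assert ann.labels.count("N") == ann.n_len
            assert ann.mh_len <= min(ann.v_match, ann.j_match)

    def test_reconstruction_from_labels(self, small_assemblies, lookups):
        """Untrimmed V prefix + insert + untrimmed J suffix == CDR3."""
        v_lookup, j_lookup = lookups
        for a in small_assemblies[:500]:
            v_germ, j_germ = v_lookup[a.v_id], j_lookup[a.j_id]
            ann = annotate_junction(a.cdr3, v_germ, j_germ)
            n = len(a.cdr3)
            gap = ann.n_len
            j_only = n - ann.v_match - gap     # J labels beyond the overlap
            rebuilt = (v_germ[:ann.v_match]
                       + a.cdr3[ann.v_match:ann.v_match + gap]
                       + j_germ[len(j_germ) - j_only:] if j_only else
                       v_germ[:ann.v_match]
                       + a.cdr3[ann.v_match:ann.v_match + gap])
            assert rebuilt == a.cdr3

    def test_exhaustive_oracle_equivalence_two_letters(self):
        """All short junctions over {A, C} agree with the brute-force
        maximal-attribution enumerator."""
        alphabet = "AC"
        germs = ["".join(p) for p in itertools.product(alphabet, repeat=3)]
        for v_germ in germs:
            for j_germ in germs:
                for n in range(1, 7):
                    for cdr3 in map("".join,
                                    itertools.product(alphabet, repeat=n)):
                        a, b, mh, gap = brute_force_decomposition(
                            cdr3, v_germ, j_germ)
                        ann = annotate_junction(cdr3, v_germ, j_germ)
                        assert (ann.v_match, ann.j_match) == (a, b)
                        assert (ann.mh_len, ann.n_len) == (mh, gap)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text("AC", min_size=1, max_size=12),
           st.text("AC", min_size=1, max_size=8),
           st.text("AC", min_size=1, max_size=8))
    def test_oracle_equivalence_property(self, cdr3, v_germ, j_germ):
        a, b, mh, gap = brute_force_decomposition(cdr3, v_germ, j_germ)
        ann = annotate_junction(cdr3, v_germ, j_germ)
        assert (ann.v_match, ann.j_match, ann.mh_len, ann.n_len) == \
            (a, b, mh, gap)


class TestMatchPattern:
    def test_blunt_join_has_no_pattern(self):
        v, j = "ACGT", "GGAA"
        ann = annotate_junction(v + j, v, j)
        assert match_pattern(ann, v + j, v, j) is None

    def test_degenerate_patterns_take_lowest_id(self):
        """Single-C patterns on the default templates produce identical
        junctions; the lowest pattern id wins and multi_fit is set."""
        j_germ = "TGCC" + "AGCAAGTAGTTCGCCT"
        pats = {p.id: p for p in default_patterns()}
        from trarep.synthdata import _mh_product
        cdr3_p3 = _mh_product(V_TERMINUS, j_germ, pats[3])[0]
        cdr3_p2 = _mh_product(V_TERMINUS, j_germ, pats[2])[0]
        assert cdr3_p2 == cdr3_p3
        ann = annotate_junction(cdr3_p3, V_TERMINUS, j_germ)
        assert match_pattern(ann, cdr3_p3, V_TERMINUS, j_germ) == 2
        assert ann.multi_fit


class TestRepertoireSummary:
    def _annotate(self, cfg):
        locus = generate_germline(cfg)
        asm = simulate_recombination(locus, cfg)
        v_lookup = {s.id: s.v_terminus for s in locus.v_segments}
        j_lookup = {s.id: s.j_cdr3_part for s in locus.j_segments}
        cts = [Clonotype(v_id=a.v_id, j_id=a.j_id, cdr3=a.cdr3,
                         molecule_count=a.clone_size, read_count=a.clone_size)
               for a in asm]
        return asm, annotate_repertoire(cts, v_lookup, j_lookup)

    def test_tdt_off_everything_tdt_free(self):
        cfg = SimConfig(n_v=10, n_j=8, tdt_rate=0.0, n_cells=2000,
                        clone_alpha=8.0, seed=21)
        _, ann = self._annotate(cfg)
        summary = repertoire_summary(ann)
        assert summary["tdt_free_fraction"] == 1.0

    def test_all_mh_canonical_phases_all_in_frame(self):
        cfg = SimConfig(n_v=10, n_j=8, mh_join_prob=1.0,
                        v_rss_phase_fraction=1.0, j_primordial_fraction=1.0,
                        n_cells=2000, clone_alpha=8.0, seed=22)
        _, ann = self._annotate(cfg)
        summary = repertoire_summary(ann)
        assert summary["in_frame_fraction"] == 1.0

    def test_empty_repertoire_raises(self):
        import pandas as pd
        with pytest.raises(ValueError):
            repertoire_summary(pd.DataFrame())

    def test_summary_weights_are_molecule_counts(self):
        cfg = SimConfig(n_v=10, n_j=8, n_cells=2000, clone_alpha=2.0,
                        seed=23)
        asm, ann = self._annotate(cfg)
        summary = repertoire_summary(ann)
        assert summary["molecules"] == sum(a.clone_size for a in asm)
        hist = summary["cdr3_length_hist"]
        assert sum(hist.values()) == summary["molecules"]
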