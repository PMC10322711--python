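"""Synthetic germline loci, VJ recombination and UMI-tagged read simulation.

The generator emulates the statistical structure of a teleost-like TCRa
locus: V elements ending in a conserved Cys-to-RSS terminus that carries
terminal microhomology motifs (remnants of the target-site duplication of
the founding transposon insertion), J elements whose reading-frame phase
relative to their RSS is fixed, and a recombination process in which joins
are microhomology-directed, P-nucleotide-mediated, blunt, or trimmed with
optional non-templated (TdT) insertions.  Clone sizes follow a discrete
power law and each cDNA molecule is emitted as UMI-tagged reads with
configurable substitution/insertion error rates.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimConfig.seed``; identical configurations produce byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    Allele,
    GermlineSegment,
    JoinClass,
    MicrohomologyPattern,
    SegmentKind,
    TrueAssembly,
    default_patterns,
)

NT = "ACGT"
COMP = str.maketrans("ACGTacgt", "TGCAtgca")

# Conserved 3' terminus of V elements, from (and including) the Cys codon
# to the RSS boundary; the RSS then begins at position 15.
V_TERMINUS = "TGTGCTCTGAGGCC"

# Canonical RSS parts in V orientation (heptamer abuts the coding end).
RSS_HEPTAMER = "CACAGTG"
RSS_NONAMER = "ACAAAAACC"
V_SPACER_LEN = 23   # 23-RSS downstream of V
J_SPACER_LEN = 12   # 12-RSS upstream of J

# Constant-region exon-1 openers.  The wild-type trac exon encodes the
# CLxTD(F) signature, the trdc exon the CLxxxFxP signature.  The mutant
# trac template carries an in-frame stop codon ("non-selectable" allele).
TRAC_WT = "TGCCTGAGCACCGATTTCTTCAAGAACACC"
TRAC_MUT = "TGCCTGTAAACCGATTTCTTCAAGAACACC"
TRDC = "TGTCTGGCAGCTGCCTTCGCTCCA"

# Codons that never introduce a stop; used for random coding filler.
_SAFE_CODONS = [a + b + c for a in NT for b in NT for c in NT
                if a + b + c not in ("TAA", "TAG", "TGA")]

# Phe-codon (1-based) positions of the five J length classes; all are
# multiples of 3, i.e. primordial phase 2.  The CDR3-side J lengths are
# phe_pos + 2, hence always congruent to 2 mod 3.
J_PHE_POSITIONS = (12, 15, 18, 21, 24)
J_CANONICAL_PHE = 18


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    Defaults describe the teleost-like (zebrafish) regime: microhomology
    dominates, TdT is silent, V and J elements sit almost uniformly at
    their canonical RSS phases and an individual carries 200,000 T cells.
    """

    n_v: int = 124
    n_j: int = 137
    v_rss_phase_fraction: float = 0.992
    j_primordial_fraction: float = 134 / 137
    pattern_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.20, 3: 0.15, 4: 0.15})
    mh_join_prob: float = 0.65
    p_nuc_prob: float = 0.15
    blunt_prob: float = 0.10
    trim_geom_p: float = 0.4
    trim_cap: int = 10
    tdt_rate: float = 0.0
    clone_alpha: float = 2.0
    n_cells: int = 200_000
    umi_len: int = 12
    seq_error_sub: float = 0.001
    seq_error_ins: float = 0.0002
    reads_per_molecule_mean: float = 3.0
    nonselectable_fraction: float = 0.0
    v_len: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_v < 1 or self.n_j < 1:
            raise ValueError("n_v and n_j must be positive")
        for name in ("v_rss_phase_fraction", "j_primordial_fraction",
                     "mh_join_prob", "p_nuc_prob", "blunt_prob",
                     "seq_error_sub", "seq_error_ins",
                     "nonselectable_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if sum(self.pattern_weights.values()) > 1.0 + 1e-9:
            raise ValueError("pattern_weights must sum to at most 1")
        if self.p_nuc_prob + self.blunt_prob > 1.0 + 1e-9:
            raise ValueError("p_nuc_prob + blunt_prob must not exceed 1")
        if not 0.0 < self.trim_geom_p <= 1.0:
            raise ValueError("trim_geom_p must be in (0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.clone_alpha <= 1.0:
            raise ValueError("clone_alpha must exceed 1")
        if (self.v_len - len(V_TERMINUS)) % 3 != 0:
            raise ValueError("v_len must keep the Cys codon in frame")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Locus:
    """A synthetic germline locus: segments plus the genome they live on."""

    segments: list[GermlineSegment]
    genome: str
    contig: str = "synthetic_tra_locus"
    patterns: list[MicrohomologyPattern] = field(default_factory=default_patterns)

    @property
    def v_segments(self) -> list[GermlineSegment]:
        return [s for s in self.segments if s.kind is SegmentKind.V]

    @property
    def j_segments(self) -> list[GermlineSegment]:
        return [s for s in self.segments if s.kind is SegmentKind.J]

    def get(self, seg_id: str) -> GermlineSegment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(seg_id)


# ---------------------------------------------------------------------------
# germline construction
# ---------------------------------------------------------------------------

def _random_codons(rng: np.random.Generator, n_nt: int) -> str:
    """Stop-free random coding sequence of n_nt nucleotides (n_nt % 3 == 0)."""
    idx = rng.integers(0, len(_SAFE_CODONS), size=n_nt // 3)
    return "".join(_SAFE_CODONS[i] for i in idx)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[i] for i in rng.integers(0, 4, size=n))


def make_v_sequence(rng: np.random.Generator, total_len: int,
                    canonical: bool = True) -> tuple[str, int, int]:
    """Build one V coding sequence ending in the conserved terminus.

    Returns (seq, frame_anchor, rss_pos).  A non-canonical element carries
    one extra nucleotide between the Cys codon and the microhomology motif,
    displacing the RSS to position 16; the motif itself stays anchored to
    the RSS boundary, which is what shifts microhomology joins out of frame.
    """
    body = _random_codons(rng, total_len - len(V_TERMINUS))
    anchor = len(body)
    if canonical:
        seq = body + V_TERMINUS
        rss_pos = len(V_TERMINUS) + 1        # 15
    else:
        seq = body + V_TERMINUS[:7] + _random_nt(rng, 1) + V_TERMINUS[7:]
        rss_pos = len(V_TERMINUS) + 2        # 16
    return seq, anchor, rss_pos


def make_j_exon(rng: np.random.Generator, phe_pos: int = J_CANONICAL_PHE,
                primordial: bool = True) -> tuple[str, int]:
    """Build one J coding exon (without the intronic GT donor).

    The exon begins with the TGCC microhomology block, places the FGXG
    tetrad so that the distance from the F nucleotide to the splice donor
    (inclusive of both) is 34 nt, and embeds the degenerate nucleotide
    signature (T.4 TT . GG .4 GG . AC ...) that the genomic Ja scanner
    keys on.  Returns (exon_seq, frame_anchor).  A non-primordial exon has
    one extra nucleotide downstream of the microhomology block, shifting
    the RSS phase from 2 to 0.
    """
    if phe_pos % 3 != 0 or phe_pos < 10:
        raise ValueError("phe_pos must be a multiple of 3 and >= 10")
    # positions are 1-based within the canonical exon
    exon = ["N"] * (phe_pos + 32)
    exon[0:4] = "TGCC"                      # pattern motifs (TG / C / C)
    for i in range(4, phe_pos - 1):
        exon[i] = _random_nt(rng, 1)
    exon[phe_pos - 6] = "T"                 # degenerate-signature anchor
    phe = "TT" + ("T" if rng.random() < 0.5 else "C")
    aa_block = (
        phe,                                 # F
        "GG" + NT[rng.integers(0, 4)],       # G
        _SAFE_CODONS[rng.integers(0, len(_SAFE_CODONS))],  # X
        "GG" + NT[rng.integers(0, 4)],       # G
        "AC" + NT[rng.integers(0, 4)],       # T
        # the consensus continuation of the tetrad is T-K-L; keep Lys common
        ("AA" + "AG"[rng.integers(0, 2)]) if rng.random() < 0.6
        else _SAFE_CODONS[rng.integers(0, len(_SAFE_CODONS))],  # X (often K)
        ("CT" if rng.random() < 0.5 else "GT") + NT[rng.integers(0, 4)],  # L/V
        _SAFE_CODONS[rng.integers(0, len(_SAFE_CODONS))],  # X
        ("GT" + NT[rng.integers(0, 4)]) if rng.random() < 0.5
        else ("AT" + ("TC"[rng.integers(0, 2)])),          # V/I
    )
    tail = "".join(aa_block) + _random_codons(rng, 6)
    exon[phe_pos - 1:] = tail
    seq = "".join(exon)
    anchor = phe_pos - 1
    if not primordial:
        seq = seq[:4] + _random_nt(rng, 1) + seq[4:]
        anchor += 1
    return seq, anchor


def generate_germline(config: SimConfig,
                      rng: Optional[np.random.Generator] = None) -> Locus:
    """Generate germline V/J/C segments embedded in a synthetic genome.

    The genome follows the canonical 5'-(v)n-trdc-(traj)n-trac-3' layout.
    Each V is followed by a 23-RSS (heptamer CACAGTG, random spacer,
    nonamer ACAAAAACC); each J is preceded by the reverse complement of a
    12-RSS and followed by its GT splice donor.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    segments: list[GermlineSegment] = []
    chunks: list[str] = []
    pos = 0

    def emit(seq: str) -> tuple[int, int]:
        nonlocal pos
        chunks.append(seq)
        start = pos
        pos += len(seq)
        return start, pos

    n_canonical_v = int(round(config.v_rss_phase_fraction * config.n_v))
    for i in range(config.n_v):
        emit(_random_nt(rng, 40))
        seq, anchor, rss_pos = make_v_sequence(
            rng, config.v_len, canonical=i < n_canonical_v)
        start, end = emit(seq)
        emit(RSS_HEPTAMER + _random_nt(rng, V_SPACER_LEN) + RSS_NONAMER)
        segments.append(GermlineSegment(
            id=f"V{i + 1}", kind=SegmentKind.V, seq=seq, rss_pos=rss_pos,
            frame_anchor=anchor, locus_start=start, locus_end=end))

    emit(_random_nt(rng, 60))
    start, end = emit(TRDC)
    segments.append(GermlineSegment(
        id="TRDC", kind=SegmentKind.C, seq=TRDC, rss_pos=0,
        frame_anchor=0, locus_start=start, locus_end=end))

    n_primordial_j = int(round(config.j_primordial_fraction * config.n_j))
    for i in range(config.n_j):
        emit(_random_nt(rng, 30))
        emit(revcomp(RSS_HEPTAMER + _random_nt(rng, J_SPACER_LEN) + RSS_NONAMER))
        phe_pos = J_PHE_POSITIONS[rng.integers(0, len(J_PHE_POSITIONS))]
        seq, anchor = make_j_exon(rng, phe_pos, primordial=i < n_primordial_j)
        start, end = emit(seq)
        emit("GT" + _random_nt(rng, 28))
        exon_len = len(seq)
        segments.append(GermlineSegment(
            id=f"J{i + 1}", kind=SegmentKind.J, seq=seq,
            rss_pos=-(exon_len + 2 + 28), frame_anchor=anchor,
            locus_start=start, locus_end=end))

    emit(_random_nt(rng, 60))
    start, end = emit(TRAC_WT)
    segments.append(GermlineSegment(
        id="TRAC", kind=SegmentKind.C, seq=TRAC_WT, rss_pos=0,
        frame_anchor=0, locus_start=start, locus_end=end))
    emit(_random_nt(rng, 40))

    return Locus(segments=segments, genome="".join(chunks))


# ---------------------------------------------------------------------------
# recombination
# ---------------------------------------------------------------------------

def _mh_product(v_term: str, j_part: str,
                pattern: MicrohomologyPattern) -> tuple[str, int, int]:
    """CDR3 and trims of a microhomology join under ``pattern``.

    The V motif is anchored to the RSS boundary (segment 3' end), the J
    motif to the coding start, so phase-displaced segments yield displaced,
    generally out-of-frame products.
    """
    off_last = len(V_TERMINUS) - pattern.v_positions[-1]  # nt beyond motif
    v_keep = len(v_term) - off_last
    j_from = pattern.j_positions[-1]                       # 0-based after motif
    cdr3 = v_term[:v_keep] + j_part[j_from:]
    v_trim = off_last
    j_trim = pattern.j_positions[0] - 1
    return cdr3, v_trim, j_trim


def _pattern_applicable(v_term: str, j_part: str,
                        pattern: MicrohomologyPattern) -> bool:
    k = len(pattern.motif)
    off_last = len(V_TERMINUS) - pattern.v_positions[-1]
    v_lo = len(v_term) - off_last - k
    if v_lo < 0:
        return False
    j_lo = pattern.j_positions[0] - 1
    return (v_term[v_lo:v_lo + k] == pattern.motif
            and j_part[j_lo:j_lo + k] == pattern.motif)


def _draw_clone_sizes(rng: np.random.Generator, alpha: float,
                      n_cells: int) -> np.ndarray:
    """Discrete power-law (Zipf) clone sizes truncated at n_cells,
    summing exactly to n_cells."""
    sizes: list[int] = []
    total = 0
    while total < n_cells:
        batch = rng.zipf(alpha, size=max(64, (n_cells - total) // 4))
        for s in batch:
            s = int(min(s, n_cells))
            sizes.append(s)
            total += s
            if total >= n_cells:
                break
    sizes[-1] -= total - n_cells
    if sizes[-1] == 0:
        sizes.pop()
    return np.asarray(sizes, dtype=np.int64)


def simulate_recombination(locus: Locus, config: SimConfig,
                           rng: Optional[np.random.Generator] = None,
                           v_usage: Optional[np.ndarray] = None,
                           j_usage: Optional[np.ndarray] = None,
                           ) -> list[TrueAssembly]:
    """Simulate VJ assemblies (one per clone) with power-law clone sizes.

    Each clone draws a V and a J (uniformly unless usage distributions are
    given) and a join mechanism: with probability ``mh_join_prob`` a
    microhomology pattern (weights renormalised over the patterns whose
    motifs are present in both chosen segments; if none is applicable the
    join falls back to the trimming branch); otherwise a P-nucleotide,
    blunt, or trim(+TdT) join according to ``p_nuc_prob``/``blunt_prob``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    vs, js = locus.v_segments, locus.j_segments
    if not vs or not js:
        raise ValueError("locus must contain V and J segments")
    patterns = locus.patterns
    weights = np.array([config.pattern_weights.get(p.id, 0.0) for p in patterns])

    sizes = _draw_clone_sizes(rng, config.clone_alpha, config.n_cells)
    n_clones = len(sizes)
    v_idx = rng.choice(len(vs), size=n_clones, p=v_usage)
    j_idx = rng.choice(len(js), size=n_clones, p=j_usage)
    mech_u = rng.random(n_clones)
    allele_u = rng.random(n_clones)

    assemblies: list[TrueAssembly] = []
    n_fallback = 0
    for ci in range(n_clones):
        v, j = vs[v_idx[ci]], js[j_idx[ci]]
        v_term, j_part = v.v_terminus, j.j_cdr3_part
        assembly = None
        forced_trim = False
        if mech_u[ci] < config.mh_join_prob:
            ok = [k for k, p in enumerate(patterns)
                  if weights[k] > 0 and _pattern_applicable(v_term, j_part, p)]
            if ok:
                w = weights[ok] / weights[ok].sum()
                pat = patterns[ok[int(rng.choice(len(ok), p=w))]]
                cdr3, v_trim, j_trim = _mh_product(v_term, j_part, pat)
                canon = pat.id
                for k in ok:
                    alt, _, _ = _mh_product(v_term, j_part, patterns[k])
                    if alt == cdr3 and patterns[k].id < canon:
                        canon = patterns[k].id
                assembly = TrueAssembly(
                    v_id=v.id, j_id=j.id, cdr3=cdr3, join_class=JoinClass.MH,
                    pattern_id=pat.id, canonical_pattern_id=canon,
                    v_trim=v_trim, j_trim=j_trim,
                    mh_len=len(pat.motif), n_len=0)
            else:
                n_fallback += 1
                forced_trim = True
        if assembly is None:
            rest = 1.0 - config.mh_join_prob
            u = (mech_u[ci] - config.mh_join_prob) / rest if rest > 0 else 1.0
            if forced_trim:
                u = 1.0  # inapplicable MH draw falls back to the trim branch
            if u < config.p_nuc_prob:
                p_len = int(rng.integers(1, 3))
                if rng.random() < 0.5:
                    p_seq = revcomp(v_term[-p_len:])
                else:
                    p_seq = revcomp(j_part[:p_len])
                cdr3 = v_term + p_seq + j_part
                assembly = TrueAssembly(
                    v_id=v.id, j_id=j.id, cdr3=cdr3, join_class=JoinClass.P,
                    pattern_id=None, v_trim=0, j_trim=0, mh_len=0,
                    n_len=0, p_len=p_len)
            elif u < config.p_nuc_prob + config.blunt_prob:
                cdr3 = v_term + j_part
                assembly = TrueAssembly(
                    v_id=v.id, j_id=j.id, cdr3=cdr3, join_class=JoinClass.BLUNT,
                    pattern_id=None, v_trim=0, j_trim=0, mh_len=0, n_len=0)
            else:
                cap = config.trim_cap
                v_trim = int(min(rng.geometric(config.trim_geom_p) - 1, cap))
                j_trim = int(min(rng.geometric(config.trim_geom_p) - 1, cap))
                if config.tdt_rate > 0:
                    n_len = int(rng.geometric(1.0 / (1.0 + config.tdt_rate)) - 1)
                else:
                    n_len = 0
                n_seq = _random_nt(rng, n_len)
                cdr3 = v_term[:len(v_term) - v_trim] + n_seq + j_part[j_trim:]
                assembly = TrueAssembly(
                    v_id=v.id, j_id=j.id, cdr3=cdr3, join_class=JoinClass.N_INS,
                    pattern_id=None, v_trim=v_trim, j_trim=j_trim,
                    mh_len=0, n_len=n_len)
        assembly.clone_size = int(sizes[ci])
        if allele_u[ci] < config.nonselectable_fraction:
            assembly.allele = Allele.NON_SELECTABLE
        assemblies.append(assembly)
    if n_fallback:
        import logging
        logging.getLogger(__name__).info(
            "%d microhomology draws had no applicable pattern; "
            "fell back to trimming", n_fallback)
    return assemblies


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def molecule_cdna(assembly: TrueAssembly, locus: Locus) -> str:
    """Full-length cDNA of a molecule: V body, CDR3, J tail, constant opener."""
    v = locus.get(assembly.v_id)
    j = locus.get(assembly.j_id)
    c_seq = TRAC_MUT if assembly.allele is Allele.NON_SELECTABLE else TRAC_WT
    return (v.seq[:v.frame_anchor] + assembly.cdr3
            + j.seq[j.frame_anchor + 3:] + c_seq)


def _apply_errors(seq: str, rng: np.random.Generator,
                  sub_rate: float, ins_rate: float) -> str:
    if sub_rate <= 0 and ins_rate <= 0:
        return seq
    out = []
    subs = rng.random(len(seq)) < sub_rate
    inss = rng.random(len(seq)) < ins_rate
    for i, base in enumerate(seq):
        if subs[i]:
            base = NT[(NT.index(base) + int(rng.integers(1, 4))) % 4]
        out.append(base)
        if inss[i]:
            out.append(NT[rng.integers(0, 4)])
    return "".join(out)


@dataclass
class SimulatedRead:
    read_id: str
    seq: str            # UMI prefix followed by the cDNA sequence
    molecule_id: str


def simulate_reads(assemblies: list[TrueAssembly], locus: Locus,
                   config: SimConfig,
                   rng: Optional[np.random.Generator] = None,
                   ) -> tuple[list[SimulatedRead], "pd.DataFrame"]:
    """Expand clones into UMI-tagged molecules and error-bearing reads.

    Every molecule receives a unique random UMI of ``umi_len`` placed as a
    read prefix; read counts are Poisson(``reads_per_molecule_mean``) with
    a minimum of one.  Returns the reads and a ground-truth table with one
    row per read (read_id, molecule_id, umi, v_id, j_id, cdr3, allele).
    """
    import pandas as pd

    if not assemblies:
        raise ValueError("assemblies must be nonempty")
    if config.umi_len < 8:
        import warnings
        warnings.warn("umi_len < 8: UMI collisions become likely")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)

    reads: list[SimulatedRead] = []
    truth_rows = []
    mol_counter = 0
    for ai, asm in enumerate(assemblies):
        cdna = molecule_cdna(asm, locus)
        for _ in range(asm.clone_size):
            umi = _random_nt(rng, config.umi_len)
            mol_id = f"mol{mol_counter}"
            mol_counter += 1
            n_reads = max(1, int(rng.poisson(config.reads_per_molecule_mean)))
            for ri in range(n_reads):
                seq = _apply_errors(umi + cdna, rng, config.seq_error_sub,
                                    config.seq_error_ins)
                rid = f"{mol_id}_r{ri}"
                reads.append(SimulatedRead(rid, seq, mol_id))
                truth_rows.append({
                    "read_id": rid, "molecule_id": mol_id, "assembly": ai,
                    "umi": umi, "v_id": asm.v_id, "j_id": asm.j_id,
                    "cdr3": asm.cdr3, "allele": asm.allele.value,
                })
    return reads, pd.DataFrame(truth_rows)
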