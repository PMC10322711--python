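"""Core containers shared across the simulation and analysis modules.

Coordinate conventions
----------------------
Internally every genomic interval is 0-based, half-open.  Reports use the
immunogenetics conventions instead: for a V element, position +1 is the first
nucleotide of the conserved Cys codon at its 3' end, so a recombination
signal sequence (RSS) immediately after a 14-nt Cys-to-heptamer terminus
"begins at position 15".  For a J element positions are counted backwards
from the GT splice donor, with -1 the thymidine of the donor dinucleotide.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from typing import Optional


class SegmentKind(str, enum.Enum):
    V = "V"
    D = "D"
    J = "J"
    C = "C"


class JoinClass(str, enum.Enum):
    MH = "MH"          # microhomology-directed
    P = "P"            # P-nucleotide-mediated (palindromic additions only)
    BLUNT = "BLUNT"    # direct ligation, no unexplained nucleotides
    N_INS = "N_INS"    # non-templated (TdT) insertions present


class Allele(str, enum.Enum):
    SELECTABLE = "SELECTABLE"
    NON_SELECTABLE = "NON_SELECTABLE"
    NA = "NA"


@dataclass
class GermlineSegment:
    """A germline V, D, J or C element.

    ``seq`` is the coding-strand sequence of the element.  For V elements it
    ends at the RSS boundary (the heptamer is *not* part of ``seq``); for J
    elements it is the full coding exon, from the nucleotide following the
    RSS to the last exonic base before the GT splice donor.

    ``frame_anchor`` is the 0-based offset of the Cys codon (V) or of the
    first nucleotide of the Phe of the FGXG tetrad (J) within ``seq``.
    ``rss_pos`` follows the reporting convention described in the module
    docstring (1-based from the Cys codon for V; negative from the splice
    donor for J, where -1 is the t of gt and -3 the last exonic base).
    """

    id: str
    kind: SegmentKind
    seq: str
    rss_pos: int
    frame_anchor: int
    locus_start: int = -1
    locus_end: int = -1
    strand: str = "+"

    # -- derived views -----------------------------------------------------
    @property
    def v_terminus(self) -> str:
        """Cys codon through the RSS-adjacent 3' terminus (V only)."""
        if self.kind is not SegmentKind.V:
            raise ValueError("v_terminus is defined for V segments only")
        return self.seq[self.frame_anchor:]

    @property
    def j_cdr3_part(self) -> str:
        """5' end of the J exon through the FGXG Phe codon inclusive (J only)."""
        if self.kind is not SegmentKind.J:
            raise ValueError("j_cdr3_part is defined for J segments only")
        return self.seq[: self.frame_anchor + 3]

    @property
    def j_phase(self) -> int:
        """Reading-frame phase of a J element: nt upstream of the first
        Phe-frame codon, mod 3.  Phase 2 is the primordial configuration."""
        if self.kind is not SegmentKind.J:
            raise ValueError("j_phase is defined for J segments only")
        return self.frame_anchor % 3


@dataclass
class MicrohomologyPattern:
    """A short terminal homology shared by V and J ends.

    ``v_positions``/``j_positions`` are 1-based, counted from the first
    nucleotide of the V Cys codon and from the first nucleotide of the J
    coding region respectively.  The motif must be contiguous and at most
    5 nt, the length of the target-site duplication that such terminal
    homologies are thought to descend from.
    """

    id: int
    v_positions: list[int]
    j_positions: list[int]
    motif: str

    def __post_init__(self) -> None:
        if not (len(self.v_positions) == len(self.j_positions) == len(self.motif)):
            raise ValueError("positions and motif must have equal lengths")
        if not 1 <= len(self.motif) <= 5:
            raise ValueError("motif length must be in [1, 5] (TSD bound)")
        for pos in (self.v_positions, self.j_positions):
            if list(pos) != list(range(pos[0], pos[0] + len(pos))):
                raise ValueError("motif positions must be contiguous")

    def applicable(self, v_terminus: str, j_cdr3_part: str) -> bool:
        """True when the motif is present at its positions in both segments."""
        v0, j0 = self.v_positions[0] - 1, self.j_positions[0] - 1
        k = len(self.motif)
        return (v_terminus[v0:v0 + k] == self.motif
                and j_cdr3_part[j0:j0 + k] == self.motif)


def default_patterns() -> list[MicrohomologyPattern]:
    """The four dominant terminal-microhomology patterns of the default
    (teleost-like) germline templates.

    Pattern 1 is the TG dinucleotide at V positions 8-9 / J positions 1-2;
    patterns 2-4 are single characteristic G or C nucleotides.  Coordinates
    are chosen so that on canonical-phase segments patterns 2 and 3 yield
    identical CDR3 lengths and all four yield in-frame joints.
    """
    return [
        MicrohomologyPattern(1, [8, 9], [1, 2], "TG"),
        MicrohomologyPattern(2, [12], [2], "G"),
        MicrohomologyPattern(3, [13], [3], "C"),
        MicrohomologyPattern(4, [14], [4], "C"),
    ]


@dataclass
class TrueAssembly:
    """Ground truth for one simulated VJ rearrangement (one T-cell clone)."""

    v_id: str
    j_id: str
    cdr3: str
    join_class: JoinClass
    pattern_id: Optional[int]
    v_trim: int
    j_trim: int
    mh_len: int
    n_len: int
    p_len: int = 0
    clone_size: int = 1
    # lowest-numbered pattern producing a byte-identical CDR3 on this V/J
    # pair; equals pattern_id unless two patterns are sequence-degenerate.
    canonical_pattern_id: Optional[int] = None
    allele: Allele = Allele.SELECTABLE

    @property
    def in_frame(self) -> bool:
        return len(self.cdr3) % 3 == 0


@dataclass
class Molecule:
    """One UMI-resolved cDNA molecule."""

    umi: str
    v_id: str
    j_id: str
    cdr3: str
    reads: int
    allele: Allele = Allele.NA

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.umi, self.v_id, self.cdr3, self.j_id)

    @property
    def clonotype_key(self) -> tuple[str, str, str]:
        return (self.v_id, self.cdr3, self.j_id)


@dataclass
class Clonotype:
    v_id: str
    j_id: str
    cdr3: str
    molecule_count: int
    read_count: int

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.v_id, self.cdr3, self.j_id)

    @property
    def in_frame(self) -> bool:
        return len(self.cdr3) % 3 == 0


@dataclass
class Repertoire:
    """UMI-resolved molecules of one individual, with their clonotypes."""

    individual_id: str
    molecules: list[Molecule] = field(default_factory=list)
    locus: str = "tra"

    @property
    def clonotypes(self) -> list[Clonotype]:
        agg: dict[tuple[str, str, str], list[int]] = {}
        for mol in self.molecules:
            entry = agg.setdefault(mol.clonotype_key, [0, 0])
            entry[0] += 1
            entry[1] += mol.reads
        return [
            Clonotype(v, j, cdr3, molecule_count=m, read_count=r)
            for (v, cdr3, j), (m, r) in sorted(agg.items())
        ]

    def __len__(self) -> int:
        return len(self.molecules)


@dataclass
class JunctionAnnotation:
    """Per-nucleotide provenance of a CDR3.

    ``labels`` is a string over {V, J, A, N} of CDR3 length: V/J for
    unambiguously germline-templated positions, A for microhomology overlap
    (attributable to either segment), N for non-templated positions.
    P nucleotides are labelled N but counted in ``p_len``; ``n_len`` is the
    total number of N labels, so the TdT-attributable insertion count is
    ``n_len - p_len``.
    """

    labels: str
    v_match: int
    j_match: int
    v_trim: int
    j_trim: int
    mh_len: int
    n_len: int
    p_len: int
    join_class: JoinClass
    pattern_id: Optional[int] = None
    multi_fit: bool = False

    @property
    def tdt_free(self) -> bool:
        return self.n_len - self.p_len == 0

    def to_row(self) -> dict:
        d = asdict(self)
        d["join_class"] = self.join_class.value
        d["tdt_free"] = self.tdt_free
        return d
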