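"""UMI-resolved repertoire extraction from amplicon reads.

Reads carry the unique molecular identifier (UMI) as a prefix, followed by
the cDNA: V body, CDR3, J tail and the opening of the constant region.
Each read is assigned a J (by suffix match against the invariant 3' part
of the J exon), a V (by match against the expressed-V dictionary, the
sequence ending at the conserved Cys codon), and a CDR3 delimited from
the Cys codon through the FGXG Phe codon inclusive.  Unique
(UMI, V, CDR3, J) combinations are cDNA molecules; combinations read
fewer than ``min_reads`` times are discarded.

Two error-correction stages follow: stage 1 collapses molecules of equal
CDR3 length whose UMIs are within Hamming distance 1 and CDR3s within
Hamming distance 2 (UMI and CDR3 should be independent, so such
neighbours are artefacts); stage 2 resolves UMIs still carrying several
CDR3s, keeping only sequences pairwise more than Levenshtein 3 apart.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import networkx as nx
from Bio.Seq import Seq

from .model import Allele, GermlineSegment, Molecule, Repertoire, SegmentKind

# invariant 3' part of a J exon: everything beyond the deepest trimming
# the recombination model allows
J_ANCHOR_FROM = 10

V_DICT_LEN = 180          # expressed-V dictionary entry length
MAX_V_DISTANCE = 5        # germline mapping tolerance, nt
MAX_J_DISTANCE = 2
ORF_MIN_AA = 60
CYS_SEARCH_AA = 20        # how far upstream of the J Phe the Cys may sit

J_SIG_RE = re.compile(r"FG.G")
C_SIG_RE = re.compile(r"CL.TD(?:F|.F)")


@dataclass
class SegmentIndex:
    """Matching index over germline V and J segments."""

    v_entries: dict[str, str]          # id -> sequence ending at Cys codon end
    j_anchors: dict[str, str]          # id -> invariant exon suffix
    j_phe_end: dict[str, int]          # id -> offset of Phe codon end in anchor
    j_exon_len: dict[str, int]

    @classmethod
    def from_segments(cls, segments: Iterable[GermlineSegment]) -> "SegmentIndex":
        v_entries, j_anchors, j_phe_end, j_exon_len = {}, {}, {}, {}
        for seg in segments:
            if seg.kind is SegmentKind.V:
                entry = seg.seq[:seg.frame_anchor + 3]
                v_entries[seg.id] = entry[-V_DICT_LEN:]
            elif seg.kind is SegmentKind.J:
                j_anchors[seg.id] = seg.seq[J_ANCHOR_FROM:]
                j_phe_end[seg.id] = seg.frame_anchor + 3 - J_ANCHOR_FROM
                j_exon_len[seg.id] = len(seg.seq)
        if not v_entries or not j_anchors:
            raise ValueError("segment dictionaries must be nonempty")
        return cls(v_entries, j_anchors, j_phe_end, j_exon_len)


@dataclass
class ParseStats:
    n_reads: int = 0
    unmatched_v: int = 0
    unmatched_j: int = 0
    bad_anchor: int = 0
    below_threshold: int = 0
    counts: dict = field(default_factory=dict)


def _best_match(body: str, queries: dict[str, str], max_dist: int,
                ) -> tuple[Optional[str], int, int]:
    """Locate the best-matching query inside ``body``.

    Exact substring search first; otherwise the lowest-edit-distance infix
    alignment within ``max_dist``.  Returns (id, start, end) of the match
    in ``body`` (end exclusive), or (None, -1, -1).
    """
    for qid, q in queries.items():
        pos = body.find(q)
        if pos >= 0:
            return qid, pos, pos + len(q)
    best = (None, -1, -1)
    best_d = max_dist + 1
    tied = False
    for qid, q in queries.items():
        res = edlib.align(q, body, mode="HW", task="locations", k=max_dist)
        d = res["editDistance"]
        if d < 0 or d > best_d:
            continue
        if d == best_d:
            tied = True
            continue
        start, end = res["locations"][0]
        best = (qid, start, end + 1)
        best_d = d
        tied = False
    if tied:  # equally close entries: ambiguous, excluded
        return (None, -1, -1)
    return best


def classify_allele(c_portion: str) -> Allele:
    """Selectability of the constant-region allele: an in-frame stop codon
    in the constant region marks the non-selectable allele."""
    usable = len(c_portion) - len(c_portion) % 3
    if usable < 6:
        return Allele.NA
    aa = str(Seq(c_portion[:usable]).translate())
    return Allele.NON_SELECTABLE if "*" in aa else Allele.SELECTABLE


def delimit_cdr3(body: str, index: SegmentIndex,
                 v_id: str, j_id: str, j_start: int, j_end: int,
                 v_end: int) -> tuple[str, bool, Allele]:
    """CDR3 (Cys codon through FGXG Phe codon inclusive), frame flag and
    allele flag for one cDNA whose V and J matches are already located."""
    cys_start = v_end - 3
    phe_end = j_start + index.j_phe_end[j_id]
    cdr3 = body[cys_start:phe_end]
    allele = classify_allele(body[j_end:j_end + 30])
    return cdr3, len(cdr3) % 3 == 0, allele


def parse_reads(reads: Iterable, segments: Sequence[GermlineSegment],
                min_reads: int = 2, umi_len: int = 12,
                ) -> tuple[list[Molecule], ParseStats]:
    """Turn UMI-prefixed reads into molecules.

    ``reads`` yields objects with a ``seq`` attribute (or plain strings).
    Unmatchable reads are counted, never fatal.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    index = SegmentIndex.from_segments(segments)
    stats = ParseStats()
    combos: dict[tuple, list] = {}
    for read in reads:
        seq = read if isinstance(read, str) else read.seq
        stats.n_reads += 1
        umi, body = seq[:umi_len], seq[umi_len:]
        j_id, j_start, j_end = _best_match(body, index.j_anchors, MAX_J_DISTANCE)
        if j_id is None:
            stats.unmatched_j += 1
            continue
        v_id, _, v_end = _best_match(body[:j_start + 3], index.v_entries,
                                     MAX_V_DISTANCE)
        if v_id is None:
            stats.unmatched_v += 1
            continue
        cdr3, _, allele = delimit_cdr3(body, index, v_id, j_id,
                                       j_start, j_end, v_end)
        if not cdr3:
            stats.bad_anchor += 1
            continue
        entry = combos.setdefault((umi, v_id, cdr3, j_id), [0, []])
        entry[0] += 1
        entry[1].append(allele)
    mols = []
    for (umi, v_id, cdr3, j_id), (count, alleles) in sorted(combos.items()):
        if count < min_reads:
            stats.below_threshold += 1
            continue
        allele = max(sorted(set(alleles), key=lambda a: a.value),
                     key=alleles.count)
        mols.append(Molecule(umi=umi, v_id=v_id, j_id=j_id, cdr3=cdr3,
                             reads=count, allele=allele))
    stats.counts = {"molecules": len(mols)}
    return mols, stats


# ---------------------------------------------------------------------------
# UMI error correction
# ---------------------------------------------------------------------------

def _hamming_leq(a: str, b: str, k: int) -> bool:
    if len(a) != len(b):
        return False
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > k:
                return False
    return True


def umi_correct_stage1(mols: Sequence[Molecule]) -> list[Molecule]:
    """Collapse artefactual UMI/CDR3 neighbours.

    Molecules of equal CDR3 length whose UMIs are at Hamming distance <= 1
    and CDR3s at Hamming distance <= 2 are connected; each connected
    component keeps only its highest-read member (ties: lexicographically
    smallest UMI), which absorbs the reads of the rest.
    """
    by_len: dict[int, list[int]] = defaultdict(list)
    for i, m in enumerate(mols):
        by_len[len(m.cdr3)].append(i)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(mols)))
    for idxs in by_len.values():
        for a in range(len(idxs)):
            ma = mols[idxs[a]]
            for b in range(a + 1, len(idxs)):
                mb = mols[idxs[b]]
                if (_hamming_leq(ma.umi, mb.umi, 1)
                        and _hamming_leq(ma.cdr3, mb.cdr3, 2)):
                    graph.add_edge(idxs[a], idxs[b])
    out = []
    for comp in nx.connected_components(graph):
        members = [mols[i] for i in comp]
        keep = min(members, key=lambda m: (-m.reads, m.umi))
        total = sum(m.reads for m in members)
        out.append(Molecule(umi=keep.umi, v_id=keep.v_id, j_id=keep.j_id,
                            cdr3=keep.cdr3, reads=total, allele=keep.allele))
    out.sort(key=lambda m: m.key)
    return out


def _levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def umi_correct_stage2(mols: Sequence[Molecule]) -> list[Molecule]:
    """Resolve UMIs that still carry several CDR3s.

    Within one UMI, CDR3s are kept only if pairwise at Levenshtein
    distance greater than 3; in a conflict the most-read sequence wins.
    This removes insertion artefacts that stage 1 (same-length only)
    cannot see.
    """
    by_umi: dict[str, list[Molecule]] = defaultdict(list)
    for m in mols:
        by_umi[m.umi].append(m)
    out = []
    for umi in sorted(by_umi):
        group = sorted(by_umi[umi], key=lambda m: (-m.reads, m.cdr3))
        kept: list[Molecule] = []
        for m in group:
            if all(_levenshtein(m.cdr3, k.cdr3) > 3 for k in kept):
                kept.append(m)
        out.extend(kept)
    out.sort(key=lambda m: m.key)
    return out


def extract_repertoire(reads: Iterable, segments: Sequence[GermlineSegment],
                       individual_id: str = "ind1", min_reads: int = 2,
                       umi_len: int = 12) -> tuple[Repertoire, ParseStats]:
    """Full pipeline: parse, then both UMI corrections."""
    mols, stats = parse_reads(reads, segments, min_reads=min_reads,
                              umi_len=umi_len)
    mols = umi_correct_stage2(umi_correct_stage1(mols))
    return Repertoire(individual_id=individual_id, molecules=mols), stats


# ---------------------------------------------------------------------------
# expressed-V dictionary
# ---------------------------------------------------------------------------

def build_v_dictionary(cdnas: Iterable[str],
                       germline_v: Optional[dict[str, str]] = None,
                       ) -> "pd.DataFrame":
    """Derive the expressed-V dictionary from cDNA sequences.

    For each cDNA: find an open reading frame of at least 60 residues that
    carries the J signature (FG.G followed by TKL with at most one
    mismatch) and the constant-region signature; locate the conserved Cys
    at most 20 residues upstream of the J Phe; extract the 180 nucleotides
    ending at (and including) the Cys codon as the expressed V.  Entries
    are deduplicated and, when a germline dictionary is supplied, mapped
    to it allowing up to 5 nt edit distance.
    """
    import pandas as pd

    seen: dict[str, int] = {}
    for cdna in cdnas:
        hit = _expressed_v(cdna)
        if hit is not None:
            seen[hit] = seen.get(hit, 0) + 1
    rows = []
    for seq, count in sorted(seen.items(), key=lambda kv: (-kv[1], kv[0])):
        germ_id, dist = None, None
        if germline_v:
            best = MAX_V_DISTANCE + 1
            for gid, gseq in germline_v.items():
                d = _levenshtein(seq, gseq[-V_DICT_LEN:])
                if d < best:
                    germ_id, dist, best = gid, d, d
            if best > MAX_V_DISTANCE:
                germ_id, dist = None, best
        rows.append({"expressed_v": seq, "cdnas": count,
                     "germline_id": germ_id, "distance": dist})
    return pd.DataFrame(rows)


def _expressed_v(cdna: str) -> Optional[str]:
    for frame in range(3):
        usable = len(cdna) - frame
        usable -= usable % 3
        if usable < ORF_MIN_AA * 3:
            continue
        aa = str(Seq(cdna[frame:frame + usable]).translate())
        for orf_match in re.finditer(r"[^*]+", aa):
            orf = orf_match.group()
            if len(orf) < ORF_MIN_AA:
                continue
            if not C_SIG_RE.search(orf):
                continue
            for jm in J_SIG_RE.finditer(orf):
                tail = orf[jm.end():jm.end() + 3]
                if len(tail) == 3 and sum(a != b for a, b in
                                          zip(tail, "TKL")) > 1:
                    continue
                phe_idx = jm.start()
                window = orf[max(0, phe_idx - CYS_SEARCH_AA):phe_idx]
                cys_rel = window.rfind("C")
                if cys_rel < 0:
                    continue
                cys_idx = max(0, phe_idx - CYS_SEARCH_AA) + cys_rel
                cys_nt = frame + 3 * (orf_match.start() + cys_idx)
                lo = cys_nt + 3 - V_DICT_LEN
                if lo < 0:
                    continue
                return cdna[lo:cys_nt + 3]
    return None
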