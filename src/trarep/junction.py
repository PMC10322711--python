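"""Per-nucleotide provenance of CDR3 junctions.

Every CDR3 nucleotide is assigned to one of four origins: unambiguously
V-templated, unambiguously J-templated, ambiguous (microhomology overlap,
attributable to either germline segment), or non-templated.  The
assignment is by maximal germline attribution: the longest CDR3 prefix
matching the germline V and the longest CDR3 suffix matching the germline
J are taken; where they overlap the shared nucleotides are microhomology,
where they leave a gap the gap is non-templated, with palindromic
(P) nucleotides at untrimmed ends recognised and flagged separately.

This is inference from sequence alone: a trimmed join whose flanks happen
to share homology annotates as a microhomology join.  That conservatism is
deliberate and mirrors how junction provenance must be read from real
repertoire data.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    Clonotype,
    JoinClass,
    JunctionAnnotation,
    MicrohomologyPattern,
    default_patterns,
)
from .synthdata import V_TERMINUS, revcomp

P_NUC_CAP = 2  # longest inverted repeat accepted as P nucleotides, per end


def _prefix_match(cdr3: str, v_germ: str) -> int:
    n = min(len(cdr3), len(v_germ))
    i = 0
    while i < n and cdr3[i] == v_germ[i]:
        i += 1
    return i


def _suffix_match(cdr3: str, j_germ: str) -> int:
    n = min(len(cdr3), len(j_germ))
    i = 0
    while i < n and cdr3[-1 - i] == j_germ[-1 - i]:
        i += 1
    return i


def annotate_junction(cdr3: str, v_germ: str, j_germ: str) -> JunctionAnnotation:
    """Annotate one CDR3 against its germline V terminus and J coding region.

    ``v_germ`` is the germline V from the Cys codon through the
    RSS-adjacent terminus; ``j_germ`` the germline J coding region through
    the FGXG Phe codon.  Among all decompositions of the CDR3 into a
    germline V prefix, an insert, and a germline J suffix, the one with
    maximal total germline attribution is chosen (ties broken toward the
    larger V match); overlap between the maximal prefix and suffix is
    labelled ambiguous ('A'), any gap non-templated ('N').
    """
    if not cdr3:
        raise ValueError("cdr3 must be nonempty")
    n = len(cdr3)
    v_match = _prefix_match(cdr3, v_germ)
    j_match = _suffix_match(cdr3, j_germ)
    v_trim = len(v_germ) - v_match
    j_trim = len(j_germ) - j_match

    overlap = max(0, v_match + j_match - n)
    gap = max(0, n - v_match - j_match)

    # P nucleotides: an untrimmed germline end whose reverse complement
    # opens (V side) or closes (J side) the non-templated gap.
    p_len = 0
    if gap > 0:
        gap_seq = cdr3[v_match:n - j_match]
        if v_trim == 0 and v_germ:
            for k in range(min(P_NUC_CAP, len(gap_seq), len(v_germ)), 0, -1):
                if gap_seq[:k] == revcomp(v_germ[-k:]):
                    p_len += k
                    break
        if j_trim == 0 and j_germ:
            remaining = gap - (p_len if v_trim == 0 else 0)
            for k in range(min(P_NUC_CAP, remaining, len(j_germ)), 0, -1):
                if gap_seq[-k:] == revcomp(j_germ[:k]):
                    p_len += k
                    break

    labels = ("V" * (n - j_match - gap) + "A" * overlap + "N" * gap
              + "J" * (n - v_match - gap))
    assert len(labels) == n

    if overlap > 0:
        join_class = JoinClass.MH
    elif gap == 0:
        join_class = JoinClass.BLUNT
    elif gap == p_len:
        join_class = JoinClass.P
    else:
        join_class = JoinClass.N_INS

    return JunctionAnnotation(
        labels=labels, v_match=v_match, j_match=j_match,
        v_trim=v_trim, j_trim=j_trim, mh_len=overlap,
        n_len=gap, p_len=p_len, join_class=join_class)


def match_pattern(annotation: JunctionAnnotation, cdr3: str, v_germ: str,
                  j_germ: str,
                  patterns: Optional[Sequence[MicrohomologyPattern]] = None,
                  ) -> Optional[int]:
    """Return the id of the microhomology pattern consistent with a junction.

    A pattern fits when its motif is present at the expected positions of
    both germline segments (V positions anchored to the RSS boundary, J
    positions to the coding start) and the junction sequence is exactly
    the one that joining on that motif produces.  If several patterns fit
    the lowest id wins and the annotation is flagged ``multi_fit``.
    """
    if annotation.join_class is not JoinClass.MH:
        return None
    if patterns is None:
        patterns = default_patterns()
    fits = []
    for pat in patterns:
        k = len(pat.motif)
        off_last = len(V_TERMINUS) - pat.v_positions[-1]
        v_keep = len(v_germ) - off_last
        if v_keep < k:
            continue
        if v_germ[v_keep - k:v_keep] != pat.motif:
            continue
        j0 = pat.j_positions[0] - 1
        if j_germ[j0:j0 + k] != pat.motif:
            continue
        if cdr3 == v_germ[:v_keep] + j_germ[j0 + k:]:
            fits.append(pat.id)
    if not fits:
        return None
    fits.sort()
    if len(fits) > 1:
        annotation.multi_fit = True
    annotation.pattern_id = fits[0]
    return fits[0]


def annotate_repertoire(clonotypes: Iterable[Clonotype],
                        v_lookup: dict[str, str], j_lookup: dict[str, str],
                        patterns: Optional[Sequence[MicrohomologyPattern]] = None,
                        ) -> pd.DataFrame:
    """Annotate every clonotype; returns one row per clonotype.

    ``v_lookup``/``j_lookup`` map segment ids to the germline sequences
    used for provenance (V: Cys through terminus; J: coding start through
    Phe codon).
    """
    rows = []
    for ct in clonotypes:
        ann = annotate_junction(ct.cdr3, v_lookup[ct.v_id], j_lookup[ct.j_id])
        match_pattern(ann, ct.cdr3, v_lookup[ct.v_id], j_lookup[ct.j_id],
                      patterns)
        row = ann.to_row()
        row.update(v_id=ct.v_id, j_id=ct.j_id, cdr3=ct.cdr3,
                   molecule_count=ct.molecule_count,
                   read_count=ct.read_count,
                   cdr3_len=len(ct.cdr3), in_frame=ct.in_frame)
        rows.append(row)
    return pd.DataFrame(rows)


def repertoire_summary(annotations: pd.DataFrame) -> dict:
    """Molecule-weighted summary statistics of an annotated repertoire.

    Reports the in-frame fraction, per-pattern contribution fractions,
    mean insertion and microhomology lengths, the fraction of junctions
    explainable without TdT, the CDR3 length histogram and the fraction
    of possible V x J combinations observed.
    """
    if annotations.empty:
        raise ValueError("empty repertoire")
    w = annotations["molecule_count"].to_numpy(dtype=float)
    total = w.sum()

    pattern_fracs = {}
    for pid, grp in annotations.groupby("pattern_id", dropna=True):
        pattern_fracs[int(pid)] = grp["molecule_count"].sum() / total

    length_hist = (annotations.groupby("cdr3_len")["molecule_count"]
                   .sum().sort_index())

    n_v = annotations["v_id"].nunique()
    n_j = annotations["j_id"].nunique()
    observed_vj = annotations[["v_id", "j_id"]].drop_duplicates().shape[0]

    tdt_attrib = (annotations["n_len"] - annotations["p_len"]).to_numpy()
    return {
        "molecules": float(total),
        "clonotypes": int(len(annotations)),
        "in_frame_fraction": float((w * annotations["in_frame"]).sum() / total),
        "pattern_fractions": pattern_fracs,
        "mean_n_len": float((w * tdt_attrib).sum() / total),
        "mean_mh_len": float((w * annotations["mh_len"]).sum() / total),
        "tdt_free_fraction": float((w * (tdt_attrib == 0)).sum() / total),
        "cdr3_length_hist": {int(k): float(v) for k, v in length_hist.items()},
        "vj_combinations_observed": int(observed_vj),
        "vj_combinations_possible": int(n_v * n_j),
        "vj_coverage": float(observed_vj / (n_v * n_j)),
        "join_class_fractions": {
            k: float(v) for k, v in
            (annotations.groupby("join_class")["molecule_count"].sum() / total)
            .items()},
    }
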