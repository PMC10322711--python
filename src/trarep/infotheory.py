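"""Entropy decomposition of CDR3 repertoire diversity.

The sequence entropy of a repertoire, H(S), is split as

    H(S) = H(L) + sum_l p(l) * H(S | L = l)

where L is CDR3 length (H(L|S) = 0 since a sequence determines its
length).  For each length class, H(S|L=l) is estimated as the sum over
positions of the per-position entropy minus the germline-explained part,

    H(S | L = l) = sum_n [ H(CDR3_n | l) - max(I(CDR3_n; V | l),
                                               I(CDR3_n; J | l)) ]
                   + H(V, J | l),

taking for each position the larger of the V- and J-mutual information
rather than the information of the (V, J) pair.  That simplification
needs far shallower sampling (alphabet |V|*4 or |J|*4 instead of
|V|*|J|*4 per position) and can only under-estimate the explained
information, so the resulting H(S) is an upper bound on the plug-in
pair-based estimate.

All frequencies are molecule-weighted plug-in estimates in bits; no
small-sample bias correction is applied, but (gene, position) cells
supported by fewer than 5 molecules are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from Bio.Seq import Seq

NT_ALPHABET = "ACGT"
LOW_COUNT = 5


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector (0 log 0 = 0)."""
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _as_table(repertoire, alphabet: str = "nt") -> pd.DataFrame:
    """Normalise input to a (v_id, j_id, seq, weight) table.

    Accepts a Repertoire, a list of clonotypes, or a DataFrame with
    v_id/j_id/cdr3/molecule_count columns.  For the amino-acid alphabet
    only in-frame CDR3s are translatable and retained.
    """
    if isinstance(repertoire, pd.DataFrame):
        df = repertoire[["v_id", "j_id", "cdr3", "molecule_count"]].copy()
    else:
        cts = repertoire.clonotypes if hasattr(repertoire, "clonotypes") \
            else repertoire
        df = pd.DataFrame([{"v_id": c.v_id, "j_id": c.j_id, "cdr3": c.cdr3,
                            "molecule_count": c.molecule_count}
                           for c in cts])
    if df.empty:
        raise ValueError("empty repertoire")
    if alphabet == "nt":
        df["seq"] = df["cdr3"]
    elif alphabet == "aa":
        df = df[df["cdr3"].str.len() % 3 == 0].copy()
        if df.empty:
            raise ValueError("no in-frame CDR3s to translate")
        df["seq"] = df["cdr3"].map(lambda s: str(Seq(s).translate()))
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    df["length"] = df["seq"].str.len()
    return df


def _position_matrix(seqs: pd.Series) -> np.ndarray:
    return np.array([list(s) for s in seqs])


def position_entropy(repertoire, l: int, alphabet: str = "nt") -> np.ndarray:
    """Per-position Shannon entropy (bits) of CDR3s of length ``l``."""
    df = _as_table(repertoire, alphabet)
    sub = df[df["length"] == l]
    if sub.empty:
        raise ValueError(f"no sequences of length {l}")
    mat = _position_matrix(sub["seq"])
    w = sub["molecule_count"].to_numpy(dtype=float)
    out = np.empty(l)
    for n in range(l):
        counts = pd.Series(w).groupby(mat[:, n]).sum().to_numpy()
        out[n] = _entropy(counts)
    return out


def mutual_information(repertoire, l: int, gene: str = "V",
                       alphabet: str = "nt") -> np.ndarray:
    """Per-position mutual information I(CDR3_n ; gene | L = l) in bits.

    ``gene`` is "V", "J", or "VJ" (the pair, used for the exact
    decomposition on deeply sampled data).
    """
    df = _as_table(repertoire, alphabet)
    sub = df[df["length"] == l]
    if sub.empty:
        raise ValueError(f"no sequences of length {l}")
    if gene == "V":
        gid = sub["v_id"]
    elif gene == "J":
        gid = sub["j_id"]
    elif gene == "VJ":
        gid = sub["v_id"] + "|" + sub["j_id"]
    else:
        raise ValueError("gene must be V, J or VJ")
    mat = _position_matrix(sub["seq"])
    w = sub["molecule_count"].to_numpy(dtype=float)
    total = w.sum()
    out = np.empty(l)
    for n in range(l):
        joint = pd.DataFrame({"x": mat[:, n], "g": gid.to_numpy(), "w": w})
        pivot = joint.pivot_table(index="x", columns="g", values="w",
                                  aggfunc="sum", fill_value=0.0).to_numpy()
        h_x = _entropy(pivot.sum(axis=1))
        h_g = _entropy(pivot.sum(axis=0))
        h_xg = _entropy(pivot.ravel())
        out[n] = max(0.0, h_x + h_g - h_xg)
    return out


@dataclass
class LengthDecomposition:
    pos_entropy: np.ndarray
    mi_v: np.ndarray
    mi_j: np.ndarray
    chosen_gene: list[str]
    h_vj: float
    h_s_given_l: float
    low_count_positions: list[int] = field(default_factory=list)


@dataclass
class EntropyDecomposition:
    per_length: dict[int, LengthDecomposition]
    p_l: dict[int, float]
    h_l: float
    h_s: float
    alphabet: str


def entropy_decomposition(repertoire, alphabet: str = "nt",
                          mi_mode: str = "max") -> EntropyDecomposition:
    """Full repertoire entropy decomposition.

    ``mi_mode`` "max" uses max(I(.;V), I(.;J)) per position (the default,
    robust at realistic depth); "pair" uses I(.; (V,J)) and is exact for
    deterministic CDR3s but demands much deeper sampling.
    """
    df = _as_table(repertoire, alphabet)
    total = df["molecule_count"].sum()
    per_length: dict[int, LengthDecomposition] = {}
    p_l: dict[int, float] = {}
    h_s_given_l_sum = 0.0
    for l, sub in df.groupby("length"):
        l = int(l)
        p = sub["molecule_count"].sum() / total
        p_l[l] = float(p)
        pos_h = _pos_entropy_from(sub, l)
        mi_v = _mi_inner(sub, l, "V")
        mi_j = _mi_inner(sub, l, "J")
        if mi_mode == "pair":
            explained = _mi_inner(sub, l, "VJ")
            chosen = ["VJ"] * l
        elif mi_mode == "max":
            explained = np.maximum(mi_v, mi_j)
            chosen = ["V" if v >= j else "J" for v, j in zip(mi_v, mi_j)]
        else:
            raise ValueError("mi_mode must be 'max' or 'pair'")
        vj_counts = (sub.groupby(["v_id", "j_id"])["molecule_count"].sum()
                     .to_numpy(dtype=float))
        h_vj = _entropy(vj_counts)
        residual = np.clip(pos_h - explained, 0.0, None)
        h_s_given_l = float(residual.sum() + h_vj)
        low = _low_count_positions(sub, l)
        per_length[l] = LengthDecomposition(
            pos_entropy=pos_h, mi_v=mi_v, mi_j=mi_j, chosen_gene=chosen,
            h_vj=h_vj, h_s_given_l=h_s_given_l, low_count_positions=low)
        h_s_given_l_sum += p * h_s_given_l
    h_l = _entropy(df.groupby("length")["molecule_count"].sum().to_numpy())
    return EntropyDecomposition(per_length=per_length, p_l=p_l, h_l=h_l,
                                h_s=float(h_l + h_s_given_l_sum),
                                alphabet=alphabet)


def _pos_entropy_from(sub: pd.DataFrame, l: int) -> np.ndarray:
    mat = _position_matrix(sub["seq"])
    w = sub["molecule_count"].to_numpy(dtype=float)
    return np.array([
        _entropy(pd.Series(w).groupby(mat[:, n]).sum().to_numpy())
        for n in range(l)])


def _mi_inner(sub: pd.DataFrame, l: int, gene: str) -> np.ndarray:
    if gene == "V":
        gid = sub["v_id"]
    elif gene == "J":
        gid = sub["j_id"]
    else:
        gid = sub["v_id"] + "|" + sub["j_id"]
    mat = _position_matrix(sub["seq"])
    w = sub["molecule_count"].to_numpy(dtype=float)
    out = np.empty(l)
    for n in range(l):
        joint = pd.DataFrame({"x": mat[:, n], "g": gid.to_numpy(), "w": w})
        pivot = joint.pivot_table(index="x", columns="g", values="w",
                                  aggfunc="sum", fill_value=0.0).to_numpy()
        out[n] = max(0.0, _entropy(pivot.sum(axis=1))
                     + _entropy(pivot.sum(axis=0)) - _entropy(pivot.ravel()))
    return out


def _low_count_positions(sub: pd.DataFrame, l: int) -> list[int]:
    """Positions where some (nucleotide, gene) cell holds < 5 molecules."""
    mat = _position_matrix(sub["seq"])
    w = sub["molecule_count"].to_numpy(dtype=float)
    flagged = []
    for n in range(l):
        joint = pd.DataFrame({"x": mat[:, n], "g": sub["v_id"].to_numpy(),
                              "w": w})
        cells = joint.groupby(["x", "g"])["w"].sum()
        if (cells < LOW_COUNT).any():
            flagged.append(n)
    return flagged


def sequence_entropy_direct(repertoire, alphabet: str = "nt") -> float:
    """Plug-in entropy of full (V, CDR3, J) clonotype frequencies, the
    model-free reference value for small repertoires."""
    df = _as_table(repertoire, alphabet)
    counts = (df.groupby(["v_id", "seq", "j_id"])["molecule_count"].sum()
              .to_numpy(dtype=float))
    return _entropy(counts)


def decomposition_table(dec: EntropyDecomposition) -> pd.DataFrame:
    """Long-format per-length, per-position table for export/plotting."""
    rows = []
    for l, d in sorted(dec.per_length.items()):
        for n in range(l):
            rows.append({
                "length": l, "position": n + 1,
                "entropy_bits": d.pos_entropy[n],
                "mi_v_bits": d.mi_v[n], "mi_j_bits": d.mi_j[n],
                "gene_used": d.chosen_gene[n],
                "low_count": n in d.low_count_positions,
            })
    return pd.DataFrame(rows)
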