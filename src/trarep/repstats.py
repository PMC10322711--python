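"""Repertoire-level statistics.

* Publicity: the probability that a randomly picked cDNA molecule's
  (V, CDR3, J) sequence occurs in exactly k of the n individuals of a
  cohort.  Molecule weighting is deliberate: molecules proxy clone sizes,
  and clonotype weighting would let rare sequences dominate.
* Clone-size power law: maximum-likelihood fit of a discrete power law
  with tail-threshold (x_min) selection by the Kolmogorov-Smirnov
  distance, plus the log-log rank-frequency slope as a diagnostic.
* Generation probability: for a germline locus with known microhomology
  patterns, every (V, J, pattern) triple yields one deterministic CDR3;
  enumerating them with V/J usage and mechanism probabilities gives each
  assembly's per-rearrangement probability p_gen, and, treating the
  n_cells recombination events of an individual as independent draws,
  the probability p_present = 1 - (1 - p_gen)^n_cells of finding the
  assembly at least once in that individual.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .model import Repertoire
from .synthdata import Locus, SimConfig, _mh_product, _pattern_applicable


# ---------------------------------------------------------------------------
# publicity
# ---------------------------------------------------------------------------

@dataclass
class PublicityProfile:
    n_individuals: int
    p_shared: dict[int, float]          # sharing level k -> probability
    molecules: int

    def __post_init__(self) -> None:
        total = sum(self.p_shared.values())
        if self.molecules and not np.isclose(total, 1.0):
            raise ValueError("p_shared must sum to 1")


def publicity(repertoires: Sequence[Repertoire]) -> PublicityProfile:
    """Molecule-weighted sharing profile of a cohort."""
    if len(repertoires) < 2:
        raise ValueError("publicity needs at least two repertoires")
    loci = {r.locus for r in repertoires}
    if len(loci) > 1:
        raise ValueError(f"repertoires from different loci: {loci}")
    presence: dict[tuple, set] = defaultdict(set)
    for rep in repertoires:
        for mol in rep.molecules:
            presence[mol.clonotype_key].add(rep.individual_id)
    level = {key: len(inds) for key, inds in presence.items()}
    counts: dict[int, float] = defaultdict(float)
    total = 0
    for rep in repertoires:
        for mol in rep.molecules:
            counts[level[mol.clonotype_key]] += 1
            total += 1
    p = {k: counts.get(k, 0.0) / total for k in range(1, len(repertoires) + 1)}
    return PublicityProfile(n_individuals=len(repertoires), p_shared=p,
                            molecules=total)


# ---------------------------------------------------------------------------
# power-law clone sizes
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    alpha: float
    x_min: int
    ks_distance: float
    n_tail: int
    rank_frequency_slope: float


def _discrete_powerlaw_mll(x: np.ndarray, x_min: int) -> tuple[float, float]:
    """Maximum-likelihood alpha for P(s) = s^-a / zeta(a, x_min), s >= x_min."""
    tail = x[x >= x_min].astype(float)
    slog = np.log(tail).sum()
    n = len(tail)

    def nll(alpha: float) -> float:
        return n * np.log(special.zeta(alpha, x_min)) + alpha * slog

    res = optimize.minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
    return float(res.x), float(res.fun)


def _ks_distance(x: np.ndarray, alpha: float, x_min: int) -> float:
    tail = np.sort(x[x >= x_min])
    values, counts = np.unique(tail, return_counts=True)
    ecdf = np.cumsum(counts) / counts.sum()
    z = special.zeta(alpha, x_min)
    # theoretical CDF at each observed value
    upper = values.max()
    pmf = np.arange(x_min, upper + 1, dtype=float) ** -alpha / z
    cdf = np.cumsum(pmf)
    tcdf = cdf[values - x_min]
    return float(np.abs(ecdf - tcdf).max())


def powerlaw_fit(clone_sizes: Sequence[int],
                 x_min: Optional[int] = None) -> PowerLawFit:
    """Discrete power-law fit with x_min selection by KS distance."""
    x = np.asarray(clone_sizes, dtype=np.int64)
    if len(x) < 100:
        raise ValueError("need at least 100 clones")
    if (x <= 0).any():
        raise ValueError("clone sizes must be positive")
    if np.unique(x).size < 2:
        raise ValueError("degenerate clone-size distribution")

    candidates = [x_min] if x_min is not None else \
        [int(v) for v in np.unique(x)[:20] if (x >= v).sum() >= 50]
    if not candidates:
        candidates = [int(x.min())]
    best: Optional[PowerLawFit] = None
    for xm in candidates:
        alpha, _ = _discrete_powerlaw_mll(x, xm)
        ks = _ks_distance(x, alpha, xm)
        if best is None or ks < best.ks_distance:
            best = PowerLawFit(alpha=alpha, x_min=xm, ks_distance=ks,
                               n_tail=int((x >= xm).sum()),
                               rank_frequency_slope=0.0)

    # diagnostic: log-log slope of size against rank
    s = np.sort(x)[::-1].astype(float)
    ranks = np.arange(1, len(s) + 1, dtype=float)
    slope = np.polyfit(np.log(ranks), np.log(s), 1)[0]
    best.rank_frequency_slope = float(slope)
    return best


# ---------------------------------------------------------------------------
# generation probability
# ---------------------------------------------------------------------------

def presence_probability(p_gen: float, n_cells: int) -> float:
    """P(assembly occurs at least once among n_cells independent
    recombination events)."""
    if not 0.0 <= p_gen <= 1.0:
        raise ValueError("p_gen must be a probability")
    return float(-np.expm1(n_cells * np.log1p(-p_gen))) if p_gen < 1.0 else 1.0


def pgen_enumerate(locus: Locus, config: SimConfig,
                   usage_v: Optional[np.ndarray] = None,
                   usage_j: Optional[np.ndarray] = None,
                   threshold: float = 0.95) -> pd.DataFrame:
    """Enumerate deterministic microhomology assemblies with p_gen and
    p_present.

    Every applicable (V, J, pattern) yields one CDR3 with
    p_gen = P(V) * P(J) * mh_join_prob * w(pattern | applicable);
    patterns producing a byte-identical CDR3 on the same V/J pair are
    aggregated (lowest pattern id reported).  ``p_present`` uses
    ``config.n_cells`` independent recombination events.
    """
    vs, js = locus.v_segments, locus.j_segments
    if usage_v is None:
        usage_v = np.full(len(vs), 1.0 / len(vs))
    if usage_j is None:
        usage_j = np.full(len(js), 1.0 / len(js))
    for name, usage, n in (("usage_v", usage_v, len(vs)),
                           ("usage_j", usage_j, len(js))):
        usage = np.asarray(usage, dtype=float)
        if len(usage) != n or not np.isclose(usage.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{name} must be a length-{n} distribution")
    patterns = locus.patterns
    weights = np.array([config.pattern_weights.get(p.id, 0.0)
                        for p in patterns])

    rows = []
    for vi, v in enumerate(vs):
        v_term = v.v_terminus
        for ji, j in enumerate(js):
            j_part = j.j_cdr3_part
            ok = [k for k, p in enumerate(patterns)
                  if weights[k] > 0
                  and _pattern_applicable(v_term, j_part, p)]
            if not ok:
                continue
            w_norm = weights[ok] / weights[ok].sum()
            by_cdr3: dict[str, list] = {}
            for w, k in zip(w_norm, ok):
                cdr3, _, _ = _mh_product(v_term, j_part, patterns[k])
                entry = by_cdr3.setdefault(cdr3, [0.0, patterns[k].id])
                entry[0] += w
                entry[1] = min(entry[1], patterns[k].id)
            for cdr3, (w_sum, pid) in by_cdr3.items():
                p_gen = (usage_v[vi] * usage_j[ji]
                         * config.mh_join_prob * w_sum)
                rows.append({
                    "v_id": v.id, "j_id": j.id, "pattern_id": pid,
                    "cdr3": cdr3, "p_gen": p_gen,
                    "p_present": presence_probability(p_gen, config.n_cells),
                })
    df = pd.DataFrame(rows)
    df.attrs["n_above_threshold"] = int((df["p_present"] > threshold).sum()) \
        if not df.empty else 0
    df.attrs["threshold"] = threshold
    return df
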