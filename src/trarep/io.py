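"""File-format plumbing: FASTA/FASTQ via Biopython, tables via pandas."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import Allele, GermlineSegment, Molecule, Repertoire, SegmentKind
from .synthdata import Locus, SimConfig, SimulatedRead


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    SeqIO.write((SeqRecord(Seq(s), id=name, description="")
                 for name, s in records.items()), str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    def records():
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(r.seq)
            yield rec
    SeqIO.write(records(), str(path), "fastq")


def read_fastq(path: str | Path) -> list[SimulatedRead]:
    return [SimulatedRead(rec.id, str(rec.seq).upper(), rec.id)
            for rec in SeqIO.parse(str(path), "fastq")]


def segments_to_tsv(segments: Iterable[GermlineSegment],
                    path: str | Path) -> None:
    pd.DataFrame([{
        "id": s.id, "kind": s.kind.value, "seq": s.seq, "rss_pos": s.rss_pos,
        "frame_anchor": s.frame_anchor, "locus_start": s.locus_start,
        "locus_end": s.locus_end, "strand": s.strand,
    } for s in segments]).to_csv(path, sep="\t", index=False)


def segments_from_tsv(path: str | Path) -> list[GermlineSegment]:
    df = pd.read_csv(path, sep="\t")
    return [GermlineSegment(
        id=str(r.id), kind=SegmentKind(r.kind), seq=str(r.seq),
        rss_pos=int(r.rss_pos), frame_anchor=int(r.frame_anchor),
        locus_start=int(r.locus_start), locus_end=int(r.locus_end),
        strand=str(r.strand)) for r in df.itertuples()]


def write_locus(locus: Locus, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta({locus.contig: locus.genome}, out / "genome.fasta")
    segments_to_tsv(locus.segments, out / "segments.tsv")


def read_locus(out_dir: str | Path) -> Locus:
    out = Path(out_dir)
    genome = read_fasta(out / "genome.fasta")
    contig, seq = next(iter(genome.items()))
    return Locus(segments=segments_from_tsv(out / "segments.tsv"),
                 genome=seq, contig=contig)


def write_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "pattern_weights" in data:
        data["pattern_weights"] = {int(k): float(v)
                                   for k, v in data["pattern_weights"].items()}
    return SimConfig(**data)


def molecules_to_tsv(molecules: Iterable[Molecule], path: str | Path) -> None:
    pd.DataFrame([{
        "umi": m.umi, "v_id": m.v_id, "cdr3_nt": m.cdr3, "j_id": m.j_id,
        "reads": m.reads, "allele": m.allele.value,
    } for m in molecules]).to_csv(path, sep="\t", index=False)


def molecules_from_tsv(path: str | Path,
                       individual_id: str = "ind1") -> Repertoire:
    df = pd.read_csv(path, sep="\t")
    mols = [Molecule(umi=str(r.umi), v_id=str(r.v_id), j_id=str(r.j_id),
                     cdr3=str(r.cdr3_nt), reads=int(r.reads),
                     allele=Allele(r.allele)) for r in df.itertuples()]
    return Repertoire(individual_id=individual_id, molecules=mols)


def clonotypes_to_tsv(repertoire: Repertoire, path: str | Path) -> None:
    allele_by_ct: dict[tuple, list] = {}
    for m in repertoire.molecules:
        allele_by_ct.setdefault(m.clonotype_key, []).append(m.allele)
    rows = []
    for ct in repertoire.clonotypes:
        alleles = allele_by_ct.get(ct.key, [Allele.NA])
        allele = max(sorted(set(alleles), key=lambda a: a.value),
                     key=alleles.count)
        rows.append({
            "v_id": ct.v_id, "cdr3_nt": ct.cdr3, "j_id": ct.j_id,
            "molecules": ct.molecule_count, "reads": ct.read_count,
            "frame": "in" if ct.in_frame else "out",
            "allele": allele.value,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def clonotypes_from_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"cdr3_nt": "cdr3",
                              "molecules": "molecule_count",
                              "reads": "read_count"})


def hits_to_bed(hits, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.contig}\t{h.start}\t{h.end}\t{h.kind.value}\t"
                     f"{h.score:.3f}\t{h.strand}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
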