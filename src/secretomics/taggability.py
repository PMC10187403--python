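"""Methionine content and ANL-taggability of protein sequences.

The MetRS(L274G)/azidonorleucine labeling system installs azide handles at
methionine positions.  Because the initiator methionine is frequently
excised post-translationally, only *internal* methionines (1-based position
>= 2) are counted toward taggability: a protein is considered taggable when
it carries at least one internal Met.  The initiator is always discounted —
a conservative assumption, since excision is frequent but not universal.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class ProteinRecord:
    """One protein with its methionine accounting."""

    protein_id: str
    sequence: str
    total_met: int
    internal_met: int
    taggable: bool


@dataclass(frozen=True)
class ProteomeSummary:
    n_proteins: int
    n_taggable: int
    fraction_taggable: float
    internal_met_distribution: dict[int, int]


def annotate_protein(protein_id: str, sequence: str) -> ProteinRecord:
    """Count methionines and decide taggability for one sequence.

    Whitespace is stripped, one terminal ``*`` (stop) is removed, and
    letters are upper-cased.  Ambiguity codes and non-standard letters
    (X, U, B, Z, ...) simply contribute nothing to the Met counts.
    """
    seq = "".join(sequence.split())
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise ValueError(f"protein {protein_id!r}: empty sequence")
    if not seq.isalpha():
        bad = sorted({c for c in seq if not c.isalpha()})
        raise ValueError(
            f"protein {protein_id!r}: non-alphabetic character(s) {bad} in sequence"
        )
    seq = seq.upper()
    total = seq.count("M")
    internal = seq[1:].count("M")
    return ProteinRecord(
        protein_id=protein_id,
        sequence=seq,
        total_met=total,
        internal_met=internal,
        taggable=internal >= 1,
    )


def summarize_proteome(records: Sequence[ProteinRecord]) -> ProteomeSummary:
    """Aggregate taggability over a set of annotated proteins."""
    if not records:
        raise ValueError("cannot summarize an empty proteome")
    n = len(records)
    n_tag = sum(r.taggable for r in records)
    dist = Counter(r.internal_met for r in records)
    return ProteomeSummary(
        n_proteins=n,
        n_taggable=n_tag,
        fraction_taggable=n_tag / n,
        internal_met_distribution=dict(sorted(dist.items())),
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file, plain or gzipped."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            return [(r.id, str(r.seq)) for r in SeqIO.parse(fh, "fasta")]
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records),
        str(path),
        "fasta",
    )


def annotate_fasta(path: str | Path) -> list[ProteinRecord]:
    """Annotate every sequence in a FASTA file."""
    return [annotate_protein(pid, seq) for pid, seq in read_fasta(path)]


def write_protein_table(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("protein_id\tlength\ttotal_met\tinternal_met\ttaggable\n")
        for r in records:
            fh.write(
                f"{r.protein_id}\t{len(r.sequence)}\t{r.total_met}\t"
                f"{r.internal_met}\t{str(r.taggable).lower()}\n"
            )


def write_summary(summary: ProteomeSummary, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_proteins\t{summary.n_proteins}\n")
        fh.write(f"n_taggable\t{summary.n_taggable}\n")
        fh.write(f"fraction_taggable\t{summary.fraction_taggable:.6g}\n")
        for k, v in summary.internal_met_distribution.items():
            fh.write(f"internal_met_{k}\t{v}\n")
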