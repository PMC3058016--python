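"""Coding sequences and per-gene codon composition.

A gene's codon composition is summarised by the count matrix S, where
``S[j, i]`` is the number of occurrences of codon ``i`` in gene ``j``.
Rows normalised by the total codon content of the gene give the codon
frequency matrix that downstream clustering consumes.  An alternative
summary over the 20 amino acids (translating each sense codon under the
standard nuclear code) is available for comparison.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import ALL_CODONS, AMINO_ACIDS, GENETIC_CODE, SENSE_CODONS

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Exclusion:
    """One dropped input record and the reason it was dropped."""

    gene_id: str
    reason: str


@dataclass
class GeneSequenceSet:
    """Ordered collection of coding sequences, one record per gene.

    Sequences are upper-case nucleotide strings read in frame 0 (the
    reading frame starts at base 0 of each record; coordinates are
    0-based, half-open).  Retained sequences have length a positive
    multiple of 3.  ``exclusions`` records inputs that were filtered out.
    """

    records: list[tuple[str, str]]
    exclusions: list[Exclusion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.records]


@dataclass
class CodonCountMatrix:
    """Per-gene codon counts S (genes x codons), nonnegative integers."""

    gene_ids: list[str]
    codon_alphabet: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.codon_alphabet)):
            raise ValueError("counts shape does not match gene_ids x alphabet")
        if np.any(self.counts < 0):
            raise ValueError("codon counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(self.codon_alphabet),
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class CodonFrequencyMatrix:
    """Row-normalised codon (or amino-acid) composition; rows sum to 1."""

    gene_ids: list[str]
    codon_alphabet: tuple[str, ...]
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.gene_ids), len(self.codon_alphabet)):
            raise ValueError("freqs shape does not match gene_ids x alphabet")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freqs, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(self.codon_alphabet),
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def read_cds_fasta(
    path: str | Path, max_ambiguous_fraction: float = 0.05
) -> GeneSequenceSet:
    """Read CDS records from a FASTA file.

    Records are kept in file order, upper-cased, with the description
    after the first whitespace ignored.  A record is excluded (and
    logged) if its length is not a positive multiple of 3 or if its
    fraction of non-ACGT characters exceeds ``max_ambiguous_fraction``.

    Raises ``ValueError`` on duplicate gene ids or if no record survives.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    exclusions: list[Exclusion] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id in FASTA: {gene_id!r}")
        seen.add(gene_id)
        seq = str(rec.seq).upper()
        if len(seq) == 0 or len(seq) % 3 != 0:
            exclusions.append(
                Exclusion(gene_id, f"length {len(seq)} not a positive multiple of 3")
            )
            continue
        n_ambig = sum(1 for ch in seq if ch not in _ACGT)
        if n_ambig / len(seq) > max_ambiguous_fraction:
            exclusions.append(
                Exclusion(gene_id, f"ambiguous fraction {n_ambig / len(seq):.4f} "
                                   f"exceeds {max_ambiguous_fraction}")
            )
            continue
        records.append((gene_id, seq))
    if not records:
        raise ValueError(f"no valid CDS records retained from {path}")
    return GeneSequenceSet(records=records, exclusions=exclusions)


def write_cds_fasta(seqs: GeneSequenceSet, path: str | Path) -> None:
    """Write records as FASTA (inverse of :func:`read_cds_fasta`)."""
    recs = [
        SeqRecord(Seq(seq), id=gene_id, description="")
        for gene_id, seq in seqs.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def _iter_triplets(seq: str) -> Iterable[str]:
    for i in range(0, len(seq) - len(seq) % 3, 3):
        yield seq[i : i + 3]


def codon_count_matrix(
    seqs: GeneSequenceSet, include_stop_codons: bool = False
) -> CodonCountMatrix:
    """Count codons per gene over non-overlapping frame-0 triplets.

    Triplets containing non-ACGT characters are skipped.  With
    ``include_stop_codons=False`` (default) the alphabet is the 61 sense
    codons and stop triplets are also skipped; otherwise all 64 codons
    are counted.  A gene whose counted total is 0 raises ``ValueError``.
    """
    if len(seqs) == 0:
        raise ValueError("empty sequence set")
    alphabet = ALL_CODONS if include_stop_codons else SENSE_CODONS
    index = {c: i for i, c in enumerate(alphabet)}
    counts = np.zeros((len(seqs), len(alphabet)), dtype=np.int64)
    for row, (gene_id, seq) in enumerate(seqs.records):
        tallied = Counter(_iter_triplets(seq))
        total = 0
        for codon, n in tallied.items():
            i = index.get(codon)
            if i is None:
                continue  # ambiguous triplet, or stop in sense-only mode
            counts[row, i] = n
            total += n
        if total == 0:
            raise ValueError(f"gene {gene_id!r} has zero countable codons")
    return CodonCountMatrix(seqs.gene_ids, alphabet, counts)


def normalize_frequencies(counts: CodonCountMatrix) -> CodonFrequencyMatrix:
    """Divide each count row by the gene's total codon content."""
    totals = counts.counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"gene {counts.gene_ids[zero[0]]!r} has zero total count")
    freqs = counts.counts / totals[:, None]
    return CodonFrequencyMatrix(list(counts.gene_ids), counts.codon_alphabet, freqs)


def amino_acid_composition(seqs: GeneSequenceSet) -> CodonFrequencyMatrix:
    """Per-gene amino-acid frequencies, rows summing to 1.

    Sense codons are translated under the standard nuclear code; stop
    and ambiguous triplets are skipped, mirroring codon counting.
    """
    if len(seqs) == 0:
        raise ValueError("empty sequence set")
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((len(seqs), len(AMINO_ACIDS)), dtype=np.int64)
    for row, (gene_id, seq) in enumerate(seqs.records):
        for codon in _iter_triplets(seq):
            aa = GENETIC_CODE.get(codon)
            if aa is None:
                continue
            counts[row, index[aa]] += 1
        if counts[row].sum() == 0:
            raise ValueError(f"gene {gene_id!r} has zero countable codons")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return CodonFrequencyMatrix(seqs.gene_ids, AMINO_ACIDS, freqs)
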