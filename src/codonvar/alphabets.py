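"""Codon and amino-acid alphabets under the standard nuclear genetic code."""

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: The 64 codons in alphabetical order.
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)

#: The three stop codons (TAA, TAG, TGA under the standard code).
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: The 61 sense codons in alphabetical order — the default feature alphabet.
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if c not in STOP_CODONS
)

#: Codon -> one-letter amino acid, sense codons only.
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)

#: The 20 amino acids, alphabetical by one-letter code.
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(GENETIC_CODE.values())))
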