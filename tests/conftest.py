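import numpy as np
import pytest

from codonvar import CodonFrequencyMatrix, SENSE_CODONS


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_cds(rng, n_codons: int) -> str:
    """A random in-frame CDS over the sense codons (no internal stops)."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


@pytest.fixture
def cds_fasta(tmp_path, rng):
    """FASTA of 50 random valid CDS records; returns (path, records)."""
    records = [(f"gene{i:03d}", random_cds(rng, int(rng.integers(5, 40))))
               for i in range(50)]
    path = tmp_path / "cds.fasta"
    with open(path, "w") as fh:
        for gene_id, seq in records:
            fh.write(f">{gene_id}\n{seq}\n")
    return path, records


def frequency_matrix(rng, n_genes: int, n_features: int = 61,
                     alpha: float = 1.0) -> CodonFrequencyMatrix:
    labels = SENSE_CODONS if n_features == 61 else tuple(
        f"f{i}" for i in range(n_features)
    )
    X = rng.dirichlet(np.full(n_features, alpha), size=n_genes)
    return CodonFrequencyMatrix([f"g{i}" for i in range(n_genes)], labels, X)


# Standard nuclear code written out literally, as an oracle independent
# of the package's table (amino acid -> codons).
_CODE_BY_AA = {
    "A": "GCT GCC GCA GCG", "C": "TGT TGC", "D": "GAT GAC", "E": "GAA GAG",
    "F": "TTT TTC", "G": "GGT GGC GGA GGG", "H": "CAT CAC",
    "I": "ATT ATC ATA", "K": "AAA AAG", "L": "TTA TTG CTT CTC CTA CTG",
    "M": "ATG", "N": "AAT AAC", "P": "CCT CCC CCA CCG",
    "Q": "CAA CAG", "R": "CGT CGC CGA CGG AGA AGG",
    "S": "TCT TCC TCA TCG AGT AGC", "T": "ACT ACC ACA ACG",
    "V": "GTT GTC GTA GTG", "W": "TGG", "Y": "TAT TAC",
}
STANDARD_CODE = {
    codon: aa for aa, codons in _CODE_BY_AA.items() for codon in codons.split()
}
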