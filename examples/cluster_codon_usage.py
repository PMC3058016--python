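"""Cluster genes by codon frequency with a batch Self-Organizing Map.

A synthetic FASTA is realised from a generated world, read back through
the sequence layer, normalised to codon frequencies and mapped onto a
5x4 unit grid; the U-matrix summarises distances between neighboring
units (large values mark cluster boundaries).
"""

import tempfile
from pathlib import Path

import numpy as np

from codonvar import (
    SOMConfig,
    assign_clusters,
    codon_count_matrix,
    counts_to_fasta_records,
    init_som,
    normalize_frequencies,
    quantization_error,
    read_cds_fasta,
    sample_world,
    simulate_dataset,
    train_som,
    u_matrix,
    write_cds_fasta,
)

truth = sample_world(n_clusters=8, genes_per_cluster=50,
                     codons_per_gene=300, seed=11)
counts, _ = simulate_dataset(truth)

with tempfile.TemporaryDirectory() as tmp:
    fasta = Path(tmp) / "genes.fasta"
    write_cds_fasta(counts_to_fasta_records(counts), fasta)
    seqs = read_cds_fasta(fasta)

freqs = normalize_frequencies(codon_count_matrix(seqs))
model = train_som(init_som(SOMConfig(epochs=30), freqs), freqs)
clusters = assign_clusters(model, freqs)

print(f"genes: {len(clusters.gene_ids)}; nonempty units: "
      f"{int((clusters.cluster_sizes > 0).sum())} of {model.config.n_units}")
print(f"largest cluster {clusters.cluster_sizes.max()}, "
      f"smallest nonempty {clusters.cluster_sizes[clusters.cluster_sizes > 0].min()}")
print(f"final quantization error: {quantization_error(model, freqs):.4f}")
print("U-matrix (mean distance to grid neighbors):")
print(np.array_str(u_matrix(model), precision=3))
# Genes sharing a codon-frequency archetype land on the same unit; the
# quantization error is the mean distance of a gene to its unit's profile.
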