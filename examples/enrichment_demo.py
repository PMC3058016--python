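"""Per-cluster term over-representation with the hypergeometric test
and Benjamini-Hochberg FDR.

A toy universe of 40 genes in two clusters, where term 'ribosome' is
concentrated in cluster 0; the test quantifies how surprising that
concentration is under random sampling without replacement.
"""

import numpy as np

from codonvar import AnnotationMap, ClusterAssignment, hypergeometric_enrichment

genes = [f"g{i:02d}" for i in range(40)]
labels = np.array([0] * 20 + [1] * 20)
clusters = ClusterAssignment(genes, labels, np.bincount(labels))

mapping = {g: {"ribosome"} for g in genes[:15]}          # 15 of 20 in cluster 0
mapping.update({g: {"transport"} for g in genes[20:28]})  # 8 of 20 in cluster 1
ann = AnnotationMap(mapping, universe=set(genes))

table = hypergeometric_enrichment(clusters, ann, alpha=0.01)
print(table.to_string(index=False))
# k of n cluster genes carry the term, K of N universe genes overall;
# p is the chance of >= k hits by chance, q the FDR-adjusted value.
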