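"""Per-cluster annotation-term over-representation analysis.

For each (cluster, term) pair the tail probability of the hypergeometric
distribution gives the chance of seeing at least k annotated genes in a
cluster of size n, when K of the N universe genes carry the term.
P-values are adjusted with the Benjamini-Hochberg step-up procedure,
jointly across all (cluster, term) tests by default (a ``per_cluster``
flag restricts the correction scope to each cluster's own tests).

Annotation term structure (e.g. the GO DAG) is not modelled; annotations
are taken exactly as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .som import ClusterAssignment


@dataclass
class AnnotationMap:
    gene_to_terms: dict[str, set[str]]
    term_to_genes: dict[str, set[str]] = field(init=False)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set(self.gene_to_terms)
        stray = set(self.gene_to_terms) - self.universe
        if stray:
            raise ValueError(
                f"annotated gene {next(iter(stray))!r} is not in the universe"
            )
        inverse: dict[str, set[str]] = {}
        for gene, terms in self.gene_to_terms.items():
            for term in terms:
                inverse.setdefault(term, set()).add(gene)
        self.term_to_genes = inverse


def read_annotations(
    path: str | Path,
    format: str = "two_column_tsv",
    universe: set[str] | None = None,
) -> AnnotationMap:
    """Read a gene->term map from a two-column TSV or a GAF 2.x file.

    GAF: gene id from column 2, term from column 5; lines starting with
    ``!`` are skipped.  The universe defaults to all genes seen, but may
    be overridden explicitly.
    """
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if format == "gaf":
                if line.startswith("!"):
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    raise ValueError(f"{path}:{lineno}: GAF line has < 5 columns")
                gene, term = fields[1], fields[4]
            elif format == "two_column_tsv":
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, "
                        f"got {len(fields)}"
                    )
                gene, term = fields
            else:
                raise ValueError(f"unknown annotation format {format!r}")
            if not gene or not term:
                raise ValueError(f"{path}:{lineno}: empty gene or term field")
            mapping.setdefault(gene, set()).add(term)
    if universe is not None:
        mapping = {g: t for g, t in mapping.items() if g in universe}
        return AnnotationMap(mapping, universe=set(universe))
    return AnnotationMap(mapping)


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    """Write the map as a two-column TSV (sorted for reproducibility)."""
    with open(path, "w") as handle:
        for gene in sorted(ann.gene_to_terms):
            for term in sorted(ann.gene_to_terms[gene]):
                handle.write(f"{gene}\t{term}\n")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def hypergeometric_enrichment(
    clusters: ClusterAssignment,
    ann: AnnotationMap,
    alpha: float = 0.01,
    per_cluster: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test per (cluster, term), BH-adjusted.

    Cluster genes absent from the universe are dropped (their count is
    reported in the frame's ``attrs['dropped_genes']``).  Rows with
    k >= 1 are tested; output is sorted by (cluster, p_value) and rows
    with q_value < alpha are flagged significant.
    """
    if not ann.universe:
        raise ValueError("empty annotation universe")
    N = len(ann.universe)
    labels = np.asarray(clusters.labels)
    rows: list[dict] = []
    dropped = 0
    for c in np.unique(labels):
        members = {
            g for g, lab in zip(clusters.gene_ids, labels) if lab == c
        }
        in_universe = members & ann.universe
        dropped += len(members) - len(in_universe)
        n = len(in_universe)
        if n == 0:
            continue
        term_counts: dict[str, int] = {}
        for g in in_universe:
            for term in ann.gene_to_terms.get(g, ()):
                term_counts[term] = term_counts.get(term, 0) + 1
        for term, k in term_counts.items():
            K = len(ann.term_to_genes[term])
            rows.append(
                {
                    "cluster": int(c),
                    "term": term,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "p_value": hypergeom_upper_tail(k, N, K, n),
                }
            )
    df = pd.DataFrame(
        rows, columns=["cluster", "term", "k", "n", "K", "N", "p_value"]
    )
    if len(df):
        if per_cluster:
            df["q_value"] = df.groupby("cluster")["p_value"].transform(
                lambda s: bh_fdr(s.to_numpy())
            )
        else:
            df["q_value"] = bh_fdr(df["p_value"].to_numpy())
        df["significant"] = df["q_value"] < alpha
        df = df.sort_values(
            ["cluster", "p_value", "term"], kind="stable"
        ).reset_index(drop=True)
    else:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    df.attrs["dropped_genes"] = dropped
    return df
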