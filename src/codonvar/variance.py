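"""Amplification factors and within/between-cluster variance partition.

The analysis variable is the log2 amplification factor per gene,

    x_j = log2(f_P / f_R),

the part of the protein fold change not explained by the mRNA fold
change.  Its total sum of squares over all genes decomposes into a
within-cluster part (scatter of genes around their cluster mean) and a
between-cluster part (scatter of cluster means around the grand mean):

    SS_total = SS_within + SS_between
    SS_within  = sum_c sum_j (x_jc - xbar_c)^2
    SS_between = sum_c n_c (xbar_c - xbar)^2

If clusters group genes of similar codon usage, a large between fraction
means codon composition explains most of the protein-mRNA decoupling.
The one-way F statistic (SS_between/df1) / (SS_within/df2), with
df1 = k - 1 and df2 = N - k, tests equality of cluster means; a
permutation companion avoids the normality assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .som import ClusterAssignment


@dataclass
class AmplificationVector:
    """x_j = log2(f_P/f_R) per retained gene, plus exclusion log."""

    gene_ids: list[str]
    x: np.ndarray
    excluded: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class VariancePartitionResult:
    ss_within: float
    ss_between: float
    ss_total: float
    frac_within: float
    frac_between: float
    k_used: int
    n_used: int
    f_stat: float
    df1: int
    df2: int
    p_value: float
    degenerate: str | None = None  # "all_x_identical" or "zero_within"

    def to_dict(self) -> dict:
        return {
            "ss_within": self.ss_within,
            "ss_between": self.ss_between,
            "ss_total": self.ss_total,
            "frac_within": self.frac_within,
            "frac_between": self.frac_between,
            "k_used": self.k_used,
            "n_used": self.n_used,
            "f_stat": self.f_stat,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
            "degenerate": self.degenerate,
        }


def amplification_factors(table) -> AmplificationVector:
    """Compute x_j = log2(f_P/f_R); genes with nonpositive or missing
    fold changes are excluded with reasons, never imputed."""
    gene_ids = list(table.gene_ids)
    f_P = np.asarray(table.f_P, dtype=float)
    f_R = np.asarray(table.f_R, dtype=float)
    if len(gene_ids) == 0:
        raise ValueError("empty fold-change table")
    kept_ids: list[str] = []
    kept_x: list[float] = []
    excluded: list[tuple[str, str]] = []
    for g, p, r in zip(gene_ids, f_P, f_R):
        if not np.isfinite(p) or not np.isfinite(r):
            excluded.append((g, "missing or non-finite fold change"))
        elif p <= 0 or r <= 0:
            excluded.append((g, "nonpositive fold change"))
        else:
            kept_ids.append(g)
            kept_x.append(np.log2(p / r))
    if not kept_ids:
        raise ValueError("no genes retained after fold-change filtering")
    return AmplificationVector(kept_ids, np.asarray(kept_x), excluded)


def _partition(x: np.ndarray, labels: np.ndarray) -> VariancePartitionResult:
    """Core decomposition on aligned arrays; labels are re-indexed over
    nonempty clusters, so empty units drop out of k_used."""
    _, dense = np.unique(labels, return_inverse=True)
    k = int(dense.max()) + 1
    n = x.size
    if k < 2:
        raise ValueError("need at least 2 nonempty clusters")
    if n <= k:
        raise ValueError("need more genes than clusters")
    n_c = np.bincount(dense, minlength=k).astype(float)
    sum_c = np.bincount(dense, weights=x, minlength=k)
    mean_c = sum_c / n_c
    grand = float(x.mean())
    ss_between = float(np.dot(n_c, (mean_c - grand) ** 2))
    ss_within = float(np.sum((x - mean_c[dense]) ** 2))
    ss_total = ss_within + ss_between
    df1, df2 = k - 1, n - k
    degenerate = None
    if ss_total == 0.0:
        degenerate = "all_x_identical"
        frac_w = frac_b = float("nan")
        f_stat = float("nan")
        p_value = float("nan")
    else:
        frac_w = ss_within / ss_total
        frac_b = ss_between / ss_total
        if ss_within == 0.0:
            degenerate = "zero_within"
            f_stat = float("inf")
            p_value = 0.0
        else:
            f_stat = (ss_between / df1) / (ss_within / df2)
            p_value = float(stats.f.sf(f_stat, df1, df2))
    return VariancePartitionResult(
        ss_within=ss_within,
        ss_between=ss_between,
        ss_total=ss_total,
        frac_within=frac_w,
        frac_between=frac_b,
        k_used=k,
        n_used=n,
        f_stat=f_stat,
        df1=df1,
        df2=df2,
        p_value=p_value,
        degenerate=degenerate,
    )


def partition_variance(
    x: AmplificationVector, clusters: ClusterAssignment
) -> VariancePartitionResult:
    """Decompose the variance of x within/between the given clusters.

    Every retained gene must carry a cluster label; clusters with no
    retained gene are dropped from ``k_used`` (singletons are kept and
    contribute 0 to SS_within).
    """
    label_of = dict(zip(clusters.gene_ids, np.asarray(clusters.labels)))
    missing = [g for g in x.gene_ids if g not in label_of]
    if missing:
        raise ValueError(f"gene {missing[0]!r} has no cluster label")
    labels = np.array([label_of[g] for g in x.gene_ids])
    return _partition(np.asarray(x.x, dtype=float), labels)


def partition_variance_arrays(x, labels) -> VariancePartitionResult:
    """Array-level entry point (no gene-id alignment), for simulations."""
    return _partition(np.asarray(x, dtype=float), np.asarray(labels))


def per_cluster_summary(x: AmplificationVector, clusters: ClusterAssignment):
    """Per-cluster n_c, mean of x and within-cluster sum of squares."""
    import pandas as pd

    label_of = dict(zip(clusters.gene_ids, np.asarray(clusters.labels)))
    labels = np.array([label_of[g] for g in x.gene_ids])
    rows = []
    for c in np.unique(labels):
        xc = x.x[labels == c]
        rows.append(
            {
                "cluster": int(c),
                "n_c": int(xc.size),
                "mean_x": float(xc.mean()),
                "ss_within_c": float(np.sum((xc - xc.mean()) ** 2)),
            }
        )
    return pd.DataFrame(rows)


def permutation_reference(
    x: AmplificationVector | np.ndarray,
    clusters: ClusterAssignment | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for the F statistic: the fraction of label
    permutations with F at least the observed value, with the add-one
    correction (r + 1) / (n_perm + 1)."""
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if isinstance(x, AmplificationVector):
        label_of = dict(zip(clusters.gene_ids, np.asarray(clusters.labels)))
        labels = np.array([label_of[g] for g in x.gene_ids])
        values = np.asarray(x.x, dtype=float)
    else:
        values = np.asarray(x, dtype=float)
        labels = np.asarray(clusters)
    observed = _partition(values, labels)
    if observed.degenerate == "all_x_identical":
        return 1.0
    rng = np.random.default_rng(seed)
    obs_f = observed.f_stat
    r = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        f = _partition(values, perm).f_stat
        if f >= obs_f:
            r += 1
    return (r + 1) / (n_perm + 1)
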