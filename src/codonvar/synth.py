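"""Synthetic transcriptome/proteome generator from a mechanistic
translation model.

The model: a protein's elongation time is the codon-count-weighted sum
of per-codon specific times, t_j = sum_i S_ij tau_i, where tau_i
reflects the availability of the cognate tRNA for codon i in a given
condition.  At protein steady state (synthesis = degradation + dilution),
the protein fold change between two conditions factorises as

    f_P = C * T_j * f_R,      T_j = t_j(1) / t_j(2),

with C a gene-independent condition factor (ribosome density,
degradation and growth-rate changes) and T_j the codon-composition-
dependent translation factor.  Genes are organised into latent clusters
with distinct codon-frequency archetypes, so log2(f_P/f_R) varies
between clusters through T_j and within clusters through observation
noise — exactly the structure the variance-partition analysis measures.

Everything is reproducible bit-for-bit from the world seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alphabets import SENSE_CODONS
from .sequences import CodonCountMatrix, GeneSequenceSet


@dataclass(frozen=True)
class KineticParams:
    """Per-gene translation kinetics.

    rho_R: ribosomes engaged per mRNA molecule (dimensionless count).
    k_d:   protein degradation rate constant (1/time).
    mu:    specific growth rate, the dilution term (1/time).
    """

    rho_R: float
    k_d: float
    mu: float

    def __post_init__(self) -> None:
        if self.rho_R <= 0:
            raise ValueError("rho_R must be positive")
        if self.k_d + self.mu <= 0:
            raise ValueError("k_d + mu must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated world.

    tau_1/tau_2 are per-codon specific elongation times in each of the
    two compared conditions (arbitrary time units, aligned with
    ``codon_alphabet``); C is the scalar condition factor; archetype rows
    are the latent clusters' codon-frequency profiles; ``noise_sigma`` is
    the standard deviation (log2 scale) of multiplicative lognormal
    observation noise applied to the protein fold change.
    """

    tau_1: np.ndarray
    tau_2: np.ndarray
    C: float
    cluster_archetypes: np.ndarray   # (k, codons), rows sum to 1
    genes_per_cluster: np.ndarray    # (k,) integers
    codons_per_gene: int
    noise_sigma: float
    seed: int
    codon_alphabet: tuple[str, ...] = SENSE_CODONS

    def __post_init__(self) -> None:
        for name in ("tau_1", "tau_2"):
            tau = np.asarray(getattr(self, name), dtype=float)
            if np.any(tau <= 0):
                raise ValueError(f"{name} must be positive for every codon")
            setattr(self, name, tau)
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        arch = np.asarray(self.cluster_archetypes, dtype=float)
        if not np.allclose(arch.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("archetype rows must sum to 1")
        self.cluster_archetypes = arch

    @property
    def n_genes(self) -> int:
        return int(np.sum(self.genes_per_cluster))


@dataclass
class FoldChangeTable:
    """Per-gene protein and mRNA fold changes between two conditions."""

    gene_ids: list[str]
    f_P: np.ndarray
    f_R: np.ndarray
    latent_cluster: np.ndarray | None = None  # ground truth only

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {"fold_protein": self.f_P, "fold_mrna": self.f_R},
            index=pd.Index(self.gene_ids, name="gene_id"),
        )
        if self.latent_cluster is not None:
            df["latent_cluster"] = self.latent_cluster
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _tau_vector(tau, alphabet: tuple[str, ...]) -> np.ndarray:
    """Accept a mapping codon->time or an aligned array; validate coverage."""
    if isinstance(tau, dict):
        out = np.full(len(alphabet), np.nan)
        for i, codon in enumerate(alphabet):
            if codon in tau:
                out[i] = tau[codon]
        return out
    return np.asarray(tau, dtype=float)


def elongation_time(counts_row, tau, alphabet: tuple[str, ...] = SENSE_CODONS) -> float:
    """t_j = sum_i S_ij * tau_i over the codons of one gene.

    ``tau`` may be a codon->time mapping or an array aligned with
    ``alphabet``; a missing or non-finite tau for a codon with a nonzero
    count raises ``ValueError`` naming the codon.
    """
    if isinstance(counts_row, dict):
        counts = np.array([counts_row.get(c, 0) for c in alphabet], dtype=float)
    else:
        counts = np.asarray(counts_row, dtype=float)
    tau_v = _tau_vector(tau, alphabet)
    used = counts > 0
    if not used.any():
        raise ValueError("gene has no counted codons")
    bad = used & ~np.isfinite(tau_v)
    if bad.any():
        codon = alphabet[int(np.flatnonzero(bad)[0])]
        raise ValueError(f"no specific time defined for counted codon {codon!r}")
    return float(np.dot(counts[used], tau_v[used]))


def translation_factor(
    counts_row, tau_1, tau_2, alphabet: tuple[str, ...] = SENSE_CODONS
) -> float:
    """T_j = t_j(condition 1) / t_j(condition 2)."""
    return elongation_time(counts_row, tau_1, alphabet) / elongation_time(
        counts_row, tau_2, alphabet
    )


def steady_state_protein(mrna: float, kin: KineticParams, t_j: float) -> float:
    """Steady-state protein level: (rho_R / t_j) * mRNA / (k_d + mu)."""
    if t_j <= 0:
        raise ValueError("elongation time must be positive")
    return (kin.rho_R / t_j) * mrna / (kin.k_d + kin.mu)


def sample_world(
    n_clusters: int = 20,
    genes_per_cluster: int = 100,
    codons_per_gene: int = 500,
    world: str = "alternative",
    C: float = 1.0,
    noise_sigma: float = 0.25,
    tau_log_mean: float = 0.0,
    tau_log_sd: float = 0.5,
    dirichlet_concentration: float = 0.3,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw the latent parameters of one synthetic world.

    tau_1 is lognormal per codon (natural-log mean ``tau_log_mean``, sd
    ``tau_log_sd``); in the ``"null"`` world tau_2 equals tau_1 exactly
    (so every T_j = 1), in the ``"alternative"`` world tau_2 is redrawn
    independently.  Cluster archetypes are Dirichlet over the 61 sense
    codons with a sparse concentration (default 0.3) giving distinct
    profiles.  Deterministic given ``seed``.
    """
    if world not in ("null", "alternative"):
        raise ValueError(f"unknown world {world!r}")
    if n_clusters < 1 or genes_per_cluster < 1 or codons_per_gene < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    n_codons = len(SENSE_CODONS)
    tau_1 = np.exp(rng.normal(tau_log_mean, tau_log_sd, n_codons))
    tau_2 = tau_1.copy() if world == "null" else np.exp(
        rng.normal(tau_log_mean, tau_log_sd, n_codons)
    )
    archetypes = rng.dirichlet(
        np.full(n_codons, dirichlet_concentration), size=n_clusters
    )
    # Dirichlet with small concentration can zero out codons to machine
    # precision; floor and renormalise so archetypes are valid frequencies.
    archetypes = np.maximum(archetypes, 1e-12)
    archetypes /= archetypes.sum(axis=1, keepdims=True)
    return SyntheticTruth(
        tau_1=tau_1,
        tau_2=tau_2,
        C=C,
        cluster_archetypes=archetypes,
        genes_per_cluster=np.full(n_clusters, genes_per_cluster, dtype=int),
        codons_per_gene=codons_per_gene,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def between_cluster_variance(truth: SyntheticTruth) -> float:
    """Variance of log2(C * T_c) across clusters at the archetype level,
    weighted by cluster sizes (the generator's between-cluster variance
    component of x = log2(f_P / f_R))."""
    x_c = np.array(
        [
            np.log2(truth.C * translation_factor(a, truth.tau_1, truth.tau_2))
            for a in truth.cluster_archetypes
        ]
    )
    w = truth.genes_per_cluster / truth.genes_per_cluster.sum()
    mean = float(np.dot(w, x_c))
    return float(np.dot(w, (x_c - mean) ** 2))


def within_cluster_sampling_variance(truth: SyntheticTruth) -> float:
    """Expected within-cluster variance of log2 T_j caused by multinomial
    codon sampling (delta method), averaged over clusters by size.

    With counts S multinomial(n, p), t = S.tau has mean n p.tau and the
    usual multinomial (co)variances, so to first order

        Var(ln t1 - ln t2) = Var t1/Et1^2 + Var t2/Et2^2 - 2 Cov/(Et1 Et2),

    divided by (ln 2)^2 for the log2 scale.  This shrinks as 1/n with
    gene length, vanishing for deterministic archetype counts.
    """
    n = truth.codons_per_gene
    log2sq = np.log(2.0) ** 2
    per_cluster = []
    for p in truth.cluster_archetypes:
        e1 = n * np.dot(p, truth.tau_1)
        e2 = n * np.dot(p, truth.tau_2)
        v1 = n * (np.dot(p, truth.tau_1**2) - np.dot(p, truth.tau_1) ** 2)
        v2 = n * (np.dot(p, truth.tau_2**2) - np.dot(p, truth.tau_2) ** 2)
        c12 = n * (
            np.dot(p, truth.tau_1 * truth.tau_2)
            - np.dot(p, truth.tau_1) * np.dot(p, truth.tau_2)
        )
        per_cluster.append(
            (v1 / e1**2 + v2 / e2**2 - 2.0 * c12 / (e1 * e2)) / log2sq
        )
    w = truth.genes_per_cluster / truth.genes_per_cluster.sum()
    return float(np.dot(w, per_cluster))


def noise_sigma_for_between_fraction(
    truth: SyntheticTruth, f_star: float, include_sampling_variance: bool = True
) -> float:
    """Noise sigma (log2 scale) that makes the analytic between-cluster
    fraction of variance in x equal ``f_star``.

    The between-variance V_b comes from the spread of log2(C*T_c) across
    archetypes; the within-variance is sigma^2 plus (by default) the
    delta-method multinomial sampling term, so the solver returns
    sigma = sqrt(V_b (1 - f*)/f* - V_within_sampling).
    """
    if not 0 < f_star < 1:
        raise ValueError("f_star must be in (0, 1)")
    v_b = between_cluster_variance(truth)
    if v_b <= 0:
        raise ValueError("between-cluster variance is zero; no sigma attains f_star")
    target_within = v_b * (1.0 - f_star) / f_star
    if include_sampling_variance:
        target_within -= within_cluster_sampling_variance(truth)
    if target_within < 0:
        raise ValueError(
            "codon-sampling variance alone exceeds the within-variance "
            f"implied by f_star={f_star}; increase codons_per_gene"
        )
    return float(np.sqrt(target_within))


def _largest_remainder_counts(freqs: np.ndarray, total: int) -> np.ndarray:
    raw = freqs * total
    base = np.floor(raw).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def simulate_dataset(
    truth: SyntheticTruth, deterministic_counts: bool = False
) -> tuple[CodonCountMatrix, FoldChangeTable]:
    """Generate one dataset (codon counts + fold-change table) from a world.

    Per gene: codon counts are multinomial (``codons_per_gene`` trials at
    the gene's archetype frequencies), the mRNA fold change f_R is
    lognormal (log2-mean 0, log2-sd 1), and

        f_P = C * T_j * f_R * eps,   log2(eps) ~ Normal(0, noise_sigma).

    With ``deterministic_counts=True`` every gene in a cluster receives
    the same rounded archetype counts (useful for exactness checks).
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    labels = np.repeat(np.arange(len(truth.genes_per_cluster)), truth.genes_per_cluster)
    n = labels.size
    n_codons = truth.cluster_archetypes.shape[1]
    counts = np.empty((n, n_codons), dtype=np.int64)
    for c, n_c in enumerate(truth.genes_per_cluster):
        rows = labels == c
        if deterministic_counts:
            counts[rows] = _largest_remainder_counts(
                truth.cluster_archetypes[c], truth.codons_per_gene
            )
        else:
            counts[rows] = rng.multinomial(
                truth.codons_per_gene, truth.cluster_archetypes[c], size=int(n_c)
            )
    t1 = counts @ truth.tau_1
    t2 = counts @ truth.tau_2
    T = t1 / t2
    f_R = np.exp2(rng.normal(0.0, 1.0, n))
    eps = np.exp2(rng.normal(0.0, truth.noise_sigma, n)) if truth.noise_sigma > 0 else 1.0
    f_P = truth.C * T * f_R * eps
    width = len(str(n))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n)]
    count_matrix = CodonCountMatrix(gene_ids, truth.codon_alphabet, counts)
    table = FoldChangeTable(gene_ids, f_P, f_R, latent_cluster=labels)
    return count_matrix, table


def counts_to_fasta_records(counts: CodonCountMatrix) -> GeneSequenceSet:
    """Realise a count matrix as synthetic CDS sequences: each gene's
    codons concatenated in alphabet order, with ATG prepended and TAA
    appended (so re-reading adds one ATG to the counted total)."""
    records = []
    for gene_id, row in zip(counts.gene_ids, counts.counts):
        body = "".join(
            codon * int(k) for codon, k in zip(counts.codon_alphabet, row) if k
        )
        records.append((gene_id, "ATG" + body + "TAA"))
    return GeneSequenceSet(records=records)
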