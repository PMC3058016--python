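"""Batch Self-Organizing Map for codon-composition clustering.

A SOM maps high-dimensional composition rows onto a small rectangular
grid of units; each unit carries a codebook vector in feature space and
the genes mapped to a unit form one cluster.  Training is the batch
variant: every epoch assigns each row to its best-matching unit (BMU,
minimal Euclidean distance) and then replaces each codebook vector by
the Gaussian-neighborhood-weighted mean of the assigned rows.  Batch
training is deterministic given the initial codebook, which makes runs
bit-reproducible; the neighborhood radius decays geometrically from
``sigma_initial`` to ``sigma_final`` across epochs.

The default grid is 5x4 = 20 units, matching the cluster count used for
the yeast genome analysis this package supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .sequences import CodonFrequencyMatrix


@dataclass(frozen=True)
class SOMConfig:
    grid_rows: int = 5
    grid_cols: int = 4
    epochs: int = 30
    sigma_initial: float = 2.5
    sigma_final: float = 0.25
    init_mode: str = "pca_linear"  # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows * self.grid_cols < 2 and self.init_mode == "pca_linear":
            pass  # 1x1 grids are allowed; pca spread is then degenerate
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if not (self.sigma_initial >= self.sigma_final > 0):
            raise ValueError("require sigma_initial >= sigma_final > 0")
        if self.init_mode not in ("pca_linear", "random"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass
class SOMModel:
    config: SOMConfig
    codebook: np.ndarray          # (units, features)
    unit_positions: np.ndarray    # (units, 2) integer grid coordinates
    feature_labels: tuple[str, ...]
    qe_trace: list[float] = field(default_factory=list)


@dataclass
class ClusterAssignment:
    gene_ids: list[str]
    labels: np.ndarray        # unit index per gene
    cluster_sizes: np.ndarray  # n_c per unit (empty units allowed, n_c = 0)

    def __post_init__(self) -> None:
        if int(self.cluster_sizes.sum()) != len(self.gene_ids):
            raise ValueError("cluster sizes do not sum to the number of genes")


def _grid_positions(config: SOMConfig) -> np.ndarray:
    rr, cc = np.meshgrid(
        np.arange(config.grid_rows), np.arange(config.grid_cols), indexing="ij"
    )
    return np.column_stack([rr.ravel(), cc.ravel()])


def _principal_axes(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, first two principal directions and their component std devs.

    Deterministic: signs are fixed so the largest-magnitude loading of
    each direction is positive.
    """
    mean = data.mean(axis=0)
    centered = data - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(2, vt.shape[0])
    dirs = np.zeros((2, data.shape[1]))
    sds = np.zeros(2)
    n = max(data.shape[0] - 1, 1)
    for i in range(k):
        v = vt[i]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        dirs[i] = v
        sds[i] = s[i] / np.sqrt(n)
    return mean, dirs, sds


def init_som(config: SOMConfig, data: CodonFrequencyMatrix) -> SOMModel:
    """Initialise the codebook.

    ``pca_linear`` spreads codebook vectors over the grid along the first
    two principal axes of the data (deterministic).  ``random`` samples
    data rows with the configured seed.
    """
    X = np.asarray(data.freqs, dtype=float)
    positions = _grid_positions(config)
    if config.init_mode == "pca_linear":
        if X.shape[0] < config.n_units:
            raise ValueError(
                f"pca_linear init needs at least {config.n_units} genes, got {X.shape[0]}"
            )
        mean, dirs, sds = _principal_axes(X)
        # grid coordinate -> [-1, 1]; a single row/col collapses to 0
        def axis_coords(n: int, idx: np.ndarray) -> np.ndarray:
            return np.zeros(len(idx)) if n == 1 else 2.0 * idx / (n - 1) - 1.0

        a1 = axis_coords(config.grid_rows, positions[:, 0])
        a2 = axis_coords(config.grid_cols, positions[:, 1])
        codebook = (
            mean
            + a1[:, None] * sds[0] * dirs[0]
            + a2[:, None] * sds[1] * dirs[1]
        )
    else:
        rng = np.random.default_rng(config.seed)
        idx = rng.integers(0, X.shape[0], size=config.n_units)
        codebook = X[idx].copy()
    return SOMModel(config, codebook, positions, tuple(data.codon_alphabet))


def _bmu(codebook: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-matching unit per row (ties -> lowest unit index) and sq-distances."""
    d2 = cdist(X, codebook, metric="sqeuclidean")
    bmu = np.argmin(d2, axis=1)  # argmin takes the first (lowest) index on ties
    return bmu, d2


def train_som(model: SOMModel, data: CodonFrequencyMatrix) -> SOMModel:
    """Batch-train the map; returns a new model carrying a per-epoch
    quantization-error trace (mean distance of each row to its BMU,
    measured after each epoch's codebook update).

    Epoch updates are monotone-guarded: if the neighborhood-smoothed
    batch update would raise the quantization error (possible while the
    Gaussian radius is still wide), the codebook is left unchanged for
    that epoch and training continues with the next, smaller radius.
    The guard keeps the error trace non-increasing without altering the
    deterministic batch scheme.
    """
    X = np.asarray(data.freqs, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty data")
    if X.shape[1] != model.codebook.shape[1]:
        raise ValueError("feature dimension mismatch between data and codebook")
    cfg = model.config
    codebook = model.codebook.copy()
    grid_d2 = cdist(
        model.unit_positions.astype(float), model.unit_positions.astype(float),
        metric="sqeuclidean",
    )
    trace: list[float] = []
    qe_prev = np.inf
    for epoch in range(cfg.epochs):
        frac = epoch / (cfg.epochs - 1) if cfg.epochs > 1 else 1.0
        sigma = cfg.sigma_initial * (cfg.sigma_final / cfg.sigma_initial) ** frac
        bmu, _ = _bmu(codebook, X)
        h = np.exp(-grid_d2 / (2.0 * sigma * sigma))  # (units, units)
        n_b = np.bincount(bmu, minlength=cfg.n_units).astype(float)
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmu, X)
        denom = h @ n_b
        numer = h @ sums
        candidate = codebook.copy()
        nonzero = denom > 1e-300
        candidate[nonzero] = numer[nonzero] / denom[nonzero, None]
        _, d2 = _bmu(candidate, X)
        qe_cand = float(np.sqrt(d2.min(axis=1)).mean())
        if qe_cand <= qe_prev:
            codebook = candidate
            qe_prev = qe_cand
        trace.append(qe_prev)
    return SOMModel(cfg, codebook, model.unit_positions, model.feature_labels, trace)


def assign_clusters(model: SOMModel, data: CodonFrequencyMatrix) -> ClusterAssignment:
    """Label each gene with its best-matching unit (ties -> lowest index)."""
    X = np.asarray(data.freqs, dtype=float)
    if X.shape[1] != model.codebook.shape[1]:
        raise ValueError("feature dimension mismatch between data and codebook")
    bmu, _ = _bmu(model.codebook, X)
    sizes = np.bincount(bmu, minlength=model.config.n_units)
    return ClusterAssignment(list(data.gene_ids), bmu, sizes)


def u_matrix(model: SOMModel) -> np.ndarray:
    """Unified distance matrix: per unit, the mean Euclidean distance from
    its codebook vector to those of its 4-neighborhood grid neighbors."""
    rows, cols = model.config.grid_rows, model.config.grid_cols
    book = model.codebook.reshape(rows, cols, -1)
    out = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            dists = []
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols:
                    dists.append(np.linalg.norm(book[r, c] - book[nr, nc]))
            out[r, c] = np.mean(dists) if dists else 0.0
    return out


def quantization_error(model: SOMModel, data: CodonFrequencyMatrix) -> float:
    """Mean Euclidean distance of each row to its best-matching unit."""
    X = np.asarray(data.freqs, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty data")
    _, d2 = _bmu(model.codebook, X)
    return float(np.sqrt(d2.min(axis=1)).mean())


def codebook_projection(model: SOMModel, data: CodonFrequencyMatrix) -> np.ndarray:
    """Project codebook vectors onto the data's first two principal axes
    (the 'PCA-like projection' companion view to the U-matrix)."""
    X = np.asarray(data.freqs, dtype=float)
    mean, dirs, _ = _principal_axes(X)
    return (model.codebook - mean) @ dirs.T
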