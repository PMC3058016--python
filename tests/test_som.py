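"""Batch SOM: initialisation, training, assignment, diagnostics."""

import numpy as np
import pytest

from codonvar import (
    CodonFrequencyMatrix,
    SOMConfig,
    assign_clusters,
    codebook_projection,
    init_som,
    quantization_error,
    train_som,
    u_matrix,
)

from conftest import frequency_matrix


def constant_matrix(n, row):
    row = np.asarray(row, dtype=float)
    labels = tuple(f"f{i}" for i in range(row.size))
    return CodonFrequencyMatrix(
        [f"g{i}" for i in range(n)], labels, np.tile(row, (n, 1))
    )


class TestInit:
    def test_identical_rows_collapse_both_modes(self):
        data = constant_matrix(30, [0.2, 0.3, 0.5])
        for mode in ("pca_linear", "random"):
            cfg = SOMConfig(grid_rows=2, grid_cols=3, init_mode=mode)
            model = init_som(cfg, data)
            assert np.allclose(model.codebook, [0.2, 0.3, 0.5])

    def test_pca_linear_deterministic(self, rng):
        data = frequency_matrix(rng, 100, 10)
        cfg = SOMConfig(grid_rows=3, grid_cols=3)
        m1, m2 = init_som(cfg, data), init_som(cfg, data)
        assert np.array_equal(m1.codebook, m2.codebook)

    def test_random_mode_samples_data_rows(self, rng):
        data = frequency_matrix(rng, 50, 8)
        cfg = SOMConfig(grid_rows=2, grid_cols=2, init_mode="random", seed=7)
        model = init_som(cfg, data)
        for row in model.codebook:
            assert any(np.array_equal(row, x) for x in data.freqs)

    def test_too_few_genes_for_pca(self, rng):
        data = frequency_matrix(rng, 5, 8)
        with pytest.raises(ValueError, match="at least"):
            init_som(SOMConfig(grid_rows=3, grid_cols=3), data)


class TestTrain:
    def test_single_unit_converges_to_mean(self, rng):
        data = frequency_matrix(rng, 80, 6)
        cfg = SOMConfig(grid_rows=1, grid_cols=1, epochs=1,
                        sigma_initial=1.0, sigma_final=1.0, init_mode="random")
        model = train_som(init_som(cfg, data), data)
        assert np.allclose(model.codebook[0], data.freqs.mean(axis=0))

    def test_identical_rows_zero_error(self):
        data = constant_matrix(40, [0.1, 0.4, 0.5])
        cfg = SOMConfig(grid_rows=2, grid_cols=2, epochs=5)
        model = train_som(init_som(cfg, data), data)
        assert quantization_error(model, data) == pytest.approx(0.0, abs=1e-12)

    def test_two_blob_recovery(self, rng):
        a1 = rng.dirichlet(np.ones(8))
        a2 = rng.dirichlet(np.ones(8))
        X = np.vstack([np.tile(a1, (30, 1)), np.tile(a2, (30, 1))])
        X += rng.normal(0, 0.004, X.shape)
        data = CodonFrequencyMatrix(
            [f"g{i}" for i in range(60)], tuple(f"f{i}" for i in range(8)), X
        )
        cfg = SOMConfig(grid_rows=1, grid_cols=2, epochs=20,
                        sigma_initial=1.0, sigma_final=0.05)
        model = train_som(init_som(cfg, data), data)
        labels = assign_clusters(model, data).labels
        # oracle: nearest archetype
        d1 = np.linalg.norm(X - a1, axis=1)
        d2 = np.linalg.norm(X - a2, axis=1)
        oracle = (d2 < d1).astype(int)
        # unit numbering is arbitrary; compare the partition
        assert (np.array_equal(labels, oracle)
                or np.array_equal(labels, 1 - oracle))

    def test_bit_reproducible(self, rng):
        data = frequency_matrix(rng, 150, 12)
        cfg = SOMConfig(grid_rows=3, grid_cols=2, epochs=15)
        m1 = train_som(init_som(cfg, data), data)
        m2 = train_som(init_som(cfg, data), data)
        assert np.array_equal(m1.codebook, m2.codebook)
        assert m1.qe_trace == m2.qe_trace

    def test_qe_trace_non_increasing(self, rng):
        for _ in range(5):
            data = frequency_matrix(rng, 120, 10)
            model = train_som(init_som(SOMConfig(grid_rows=3, grid_cols=3), data), data)
            assert np.all(np.diff(model.qe_trace) <= 1e-9)

    def test_row_order_invariance(self, rng):
        data = frequency_matrix(rng, 100, 9)
        perm = rng.permutation(100)
        shuffled = CodonFrequencyMatrix(
            [data.gene_ids[i] for i in perm], data.codon_alphabet, data.freqs[perm]
        )
        cfg = SOMConfig(grid_rows=2, grid_cols=3, epochs=10)
        l1 = assign_clusters(train_som(init_som(cfg, data), data), data).labels
        l2 = assign_clusters(train_som(init_som(cfg, shuffled), shuffled), shuffled).labels
        assert sorted(l1) == sorted(l2)

    def test_kmeans_comparable_with_narrow_final_sigma(self, rng):
        """With a 1xK grid and sigma_final -> 0 the partition should be
        about as tight as Lloyd's algorithm from the same start."""
        data = frequency_matrix(rng, 120, 8)
        X = data.freqs
        cfg = SOMConfig(grid_rows=1, grid_cols=4, epochs=40,
                        sigma_initial=1.0, sigma_final=0.01)
        start = init_som(cfg, data)
        model = train_som(start, data)
        labels = assign_clusters(model, data).labels
        som_cost = sum(
            np.sum((X[labels == u] - X[labels == u].mean(axis=0)) ** 2)
            for u in np.unique(labels)
        )
        # Lloyd oracle from the same initial codebook
        centers = start.codebook.copy()
        for _ in range(100):
            d = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
            lab = d.argmin(axis=1)
            new = np.array([
                X[lab == u].mean(axis=0) if np.any(lab == u) else centers[u]
                for u in range(len(centers))
            ])
            if np.allclose(new, centers):
                break
            centers = new
        lloyd_cost = sum(
            np.sum((X[lab == u] - X[lab == u].mean(axis=0)) ** 2)
            for u in np.unique(lab)
        )
        assert som_cost <= 1.1 * lloyd_cost


class TestAssignAndDiagnostics:
    def test_exact_codebook_row_match(self, rng):
        data = frequency_matrix(rng, 60, 7)
        cfg = SOMConfig(grid_rows=3, grid_cols=3, epochs=10)
        model = train_som(init_som(cfg, data), data)
        probe = CodonFrequencyMatrix(
            ["probe"], data.codon_alphabet, model.codebook[[7]]
        )
        assert assign_clusters(model, probe).labels[0] == 7

    def test_sizes_partition_genes(self, rng):
        data = frequency_matrix(rng, 83, 6)
        cfg = SOMConfig(grid_rows=2, grid_cols=3, epochs=8)
        model = train_som(init_som(cfg, data), data)
        ca = assign_clusters(model, data)
        assert int(ca.cluster_sizes.sum()) == 83

    def test_labels_match_brute_force_nearest(self, rng):
        data = frequency_matrix(rng, 200, 10)
        cfg = SOMConfig(grid_rows=4, grid_cols=3, epochs=10)
        model = train_som(init_som(cfg, data), data)
        labels = assign_clusters(model, data).labels
        d = np.linalg.norm(
            data.freqs[:, None, :] - model.codebook[None], axis=2
        )
        assert np.array_equal(labels, d.argmin(axis=1))

    def test_u_matrix_identical_codebook_is_zero(self):
        data = constant_matrix(30, [0.25, 0.25, 0.5])
        cfg = SOMConfig(grid_rows=2, grid_cols=2, epochs=3)
        model = train_som(init_som(cfg, data), data)
        assert np.allclose(u_matrix(model), 0.0)

    def test_u_matrix_two_units(self, rng):
        data = frequency_matrix(rng, 30, 5)
        cfg = SOMConfig(grid_rows=1, grid_cols=2, epochs=5)
        model = train_som(init_som(cfg, data), data)
        d = np.linalg.norm(model.codebook[0] - model.codebook[1])
        assert np.allclose(u_matrix(model), [[d, d]])

    def test_u_matrix_matches_neighbor_list_oracle(self, rng):
        data = frequency_matrix(rng, 100, 61)
        cfg = SOMConfig(epochs=5)  # default 5x4
        model = train_som(init_som(cfg, data), data)
        um = u_matrix(model)
        book = model.codebook.reshape(5, 4, -1)
        for r in range(5):
            for c in range(4):
                ds = [np.linalg.norm(book[r, c] - book[nr, nc])
                      for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                      if 0 <= nr < 5 and 0 <= nc < 4]
                assert um[r, c] == pytest.approx(np.mean(ds))

    def test_codebook_projection_shape_and_determinism(self, rng):
        data = frequency_matrix(rng, 80, 12)
        cfg = SOMConfig(grid_rows=2, grid_cols=3, epochs=8)
        model = train_som(init_som(cfg, data), data)
        p1 = codebook_projection(model, data)
        p2 = codebook_projection(model, data)
        assert p1.shape == (6, 2)
        assert np.array_equal(p1, p2)

    def test_quantization_error_duplication_invariance(self, rng):
        data = frequency_matrix(rng, 40, 6)
        cfg = SOMConfig(grid_rows=2, grid_cols=2, epochs=5)
        model = train_som(init_som(cfg, data), data)
        doubled = CodonFrequencyMatrix(
            data.gene_ids + [g + "_dup" for g in data.gene_ids],
            data.codon_alphabet,
            np.vstack([data.freqs, data.freqs]),
        )
        assert quantization_error(model, doubled) == pytest.approx(
            quantization_error(model, data)
        )
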