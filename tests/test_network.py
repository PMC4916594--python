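"""Soft-threshold adjacency, topological overlap (vs a brute-force
oracle), module detection and hub extraction."""

import numpy as np
import pandas as pd
import pytest

from tissuespec.network import (
    GRAY,
    NetworkParams,
    adjacency,
    detect_modules,
    extract_hubs,
    intramodular_connectivity,
    module_class_composition,
    topological_overlap,
)
from tissuespec.specificity import SpecificityParams, call_specific


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Independent triple-loop unsigned TOM:
    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    n = a.shape[0]
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def random_adjacency(rng: np.random.Generator, n: int) -> pd.DataFrame:
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    ids = [f"n{i}" for i in range(n)]
    return pd.DataFrame(a, index=ids, columns=ids)


def _expr(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"g{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(rows.shape[1])])


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        expr = _expr([[1, 2, 3, 4], [2, 4, 6, 8]])
        adj = adjacency(expr, NetworkParams(beta=20, min_module_size=2))
        assert adj.iloc[0, 1] == pytest.approx(1.0)

    def test_soft_threshold_power(self):
        # build two rows with Pearson correlation exactly 0.9
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        xc = x - x.mean()
        e = rng.normal(size=200)
        ec = e - e.mean()
        ec -= xc * (xc @ ec) / (xc @ xc)  # orthogonalize against centered x
        y = 0.9 * xc / np.linalg.norm(xc) + np.sqrt(1 - 0.81) * ec / np.linalg.norm(ec)
        expr = _expr([x, y])
        adj = adjacency(expr, NetworkParams(beta=20, min_module_size=2))
        assert adj.iloc[0, 1] == pytest.approx(0.9**20, rel=1e-6)

    def test_negative_correlation_is_unsigned(self):
        expr = _expr([[1, 2, 3, 4], [8, 6, 4, 2]])
        adj = adjacency(expr, NetworkParams(beta=5, min_module_size=2))
        assert adj.iloc[0, 1] == pytest.approx(1.0)  # |-1|^5

    def test_zero_variance_row_instructs_removal(self):
        with pytest.raises(ValueError, match="zero-variance"):
            adjacency(_expr([[1, 1, 1], [1, 2, 3]]))

    def test_higher_beta_never_increases_adjacency(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.normal(size=(6, 10)))
        a5 = adjacency(expr, NetworkParams(beta=5, min_module_size=2)).to_numpy()
        a9 = adjacency(expr, NetworkParams(beta=9, min_module_size=2)).to_numpy()
        off = ~np.eye(6, dtype=bool)
        assert (a9[off] <= a5[off] + 1e-15).all()

    def test_symmetric_unit_diagonal_in_range(self):
        rng = np.random.default_rng(2)
        adj = adjacency(_expr(rng.normal(size=(8, 12))))
        a = adj.to_numpy()
        assert np.array_equal(a, a.T)
        np.testing.assert_allclose(np.diag(a), 1.0)
        assert ((a >= 0) & (a <= 1)).all()


class TestTopologicalOverlap:
    def test_identity_adjacency_gives_zero_overlap(self):
        adj = random_adjacency(np.random.default_rng(0), 5) * 0 + np.eye(5)
        adj = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
        tom, dissim = topological_overlap(adj)
        off = ~np.eye(5, dtype=bool)
        assert (tom.to_numpy()[off] == 0).all()
        assert (dissim.to_numpy()[off] == 1).all()

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_graph_gives_unit_overlap(self, n):
        ids = [f"n{i}" for i in range(n)]
        adj = pd.DataFrame(np.ones((n, n)), index=ids, columns=ids)
        tom, _ = topological_overlap(adj)
        np.testing.assert_allclose(tom.to_numpy(), 1.0)

    def test_matches_bruteforce_oracle_on_random_instances(self):
        # 100 random 4-8 node instances, elementwise agreement to 1e-12
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 9))
            adj = random_adjacency(rng, n)
            tom, dissim = topological_overlap(adj)
            expected = tom_bruteforce(adj.to_numpy())
            np.testing.assert_allclose(tom.to_numpy(), expected, atol=1e-12)
            np.testing.assert_allclose(dissim.to_numpy(), 1 - expected, atol=1e-12)

    def test_symmetry_range_and_diagonal(self):
        adj = random_adjacency(np.random.default_rng(7), 10)
        tom, _ = topological_overlap(adj)
        t = tom.to_numpy()
        assert np.array_equal(t, t.T)
        np.testing.assert_allclose(np.diag(t), 1.0)
        assert ((t >= 0) & (t <= 1)).all()


def _block_dissim(sizes, within=0.05, between=0.999, seed=0):
    """Block-structured dissimilarity with near-zero within, near-one between."""
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.where(
        labels[:, None] == labels[None, :],
        rng.uniform(0, within, (n, n)),
        rng.uniform(between, 1.0, (n, n)),
    )
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    ids = [f"n{i}" for i in range(n)]
    return pd.DataFrame(d, index=ids, columns=ids), labels


class TestDetectModules:
    def test_two_planted_blocks_recovered_perfectly(self):
        dissim, labels = _block_dissim([80, 80])
        modules, _ = detect_modules(dissim, NetworkParams(min_module_size=60))
        found = modules["module"].to_numpy()
        assert set(found) == {1, 2}
        # perfect membership: each planted block maps to exactly one label
        assert len(set(found[labels == 0])) == 1
        assert len(set(found[labels == 1])) == 1

    def test_fewer_nodes_than_min_size_all_gray(self):
        dissim, _ = _block_dissim([25, 25])
        modules, _ = detect_modules(dissim, NetworkParams(min_module_size=60))
        assert (modules["module"] == GRAY).all()

    def test_small_branches_become_gray(self):
        dissim, labels = _block_dissim([80, 10])
        modules, _ = detect_modules(dissim, NetworkParams(min_module_size=60))
        assert (modules["module"].to_numpy()[labels == 1] == GRAY).all()
        assert (modules["module"].to_numpy()[labels == 0] == 1).all()

    def test_labels_ordered_by_size_descending(self):
        dissim, labels = _block_dissim([60, 100, 80])
        modules, _ = detect_modules(dissim, NetworkParams(min_module_size=60))
        sizes = modules["module"].value_counts()
        assert sizes[1] == 100 and sizes[2] == 80 and sizes[3] == 60

    def test_planted_simulation_modules_recovered(self):
        from tissuespec.evaluate import module_recovery_ari
        from tissuespec.preprocess import TransformParams, log_transform
        from tissuespec.simulate import SimulationConfig, simulate_expression

        cfg = SimulationConfig(
            seed=31, n_tissues=8, n_coding=800, n_noncoding=80,
            n_specific_per_tissue=0, module_size_per_tissue=70,
            replicate_noise_sd=0.1,
        )
        expr, _, _, truth = simulate_expression(cfg)
        members = sorted(truth.module_of)
        sub = log_transform(expr.loc[members], TransformParams())
        adj = adjacency(sub, NetworkParams())
        _, dissim = topological_overlap(adj)
        modules, _ = detect_modules(dissim, NetworkParams())
        assert module_recovery_ari(modules, truth) >= 0.9


class TestHubs:
    def test_small_module_returns_all_members(self):
        dissim, _ = _block_dissim([80])
        adj = 1 - dissim
        np.fill_diagonal(adj.values, 1.0)
        modules, _ = detect_modules(dissim, NetworkParams(min_module_size=60))
        hubs, edges = extract_hubs(adj, modules, NetworkParams(n_hubs=200))
        assert len(hubs) == 80
        assert len(edges) == 80 * 79 // 2

    def test_star_center_has_top_connectivity(self):
        n = 6
        a = np.full((n, n), 1e-6)
        a[0, :] = a[:, 0] = 0.9
        np.fill_diagonal(a, 1.0)
        ids = [f"n{i}" for i in range(n)]
        adj = pd.DataFrame(a, index=ids, columns=ids)
        modules = pd.DataFrame({"module": [1] * n}, index=ids)
        hubs, _ = extract_hubs(adj, modules, NetworkParams(min_module_size=2, n_hubs=3))
        assert hubs.index[0] == "n0"
        assert hubs.loc["n0", "hub_rank"] == 1

    def test_hub_set_matches_bruteforce_topk(self):
        rng = np.random.default_rng(5)
        adj = random_adjacency(rng, 40)
        modules = pd.DataFrame({"module": [1] * 40}, index=adj.index)
        params = NetworkParams(min_module_size=2, n_hubs=10)
        hubs, _ = extract_hubs(adj, modules, params)
        # brute-force: recompute each node's within-module adjacency sum
        a = adj.to_numpy()
        kim = {adj.index[i]: a[i].sum() - 1.0 for i in range(40)}
        top = sorted(kim, key=lambda t: (-kim[t], t))[:10]
        assert list(hubs.index) == top
        np.testing.assert_allclose(
            hubs["intramodular_connectivity"].to_numpy(),
            [kim[t] for t in top],
        )

    def test_no_modules_is_error(self):
        adj = random_adjacency(np.random.default_rng(1), 5)
        modules = pd.DataFrame({"module": [GRAY] * 5}, index=adj.index)
        with pytest.raises(ValueError):
            extract_hubs(adj, modules)

    def test_intramodular_connectivity_zero_for_gray(self):
        adj = random_adjacency(np.random.default_rng(3), 6)
        modules = pd.DataFrame({"module": [1, 1, 1, GRAY, GRAY, 2]}, index=adj.index)
        kim = intramodular_connectivity(adj, modules)
        assert kim.loc[adj.index[3]] == 0.0
        assert kim.loc[adj.index[5]] == 0.0  # sole member of module 2


class TestComposition:
    def test_pure_module_has_unit_purity(self):
        ids = ["a", "b", "c"]
        modules = pd.DataFrame({"module": [1, 1, 1]}, index=ids)
        calls = pd.DataFrame(
            {"specific_tissue": ["liver"] * 3, "cls": ["TSCT", "TSCT", "TSNT"],
             "fold_change": [3.0] * 3},
            index=ids,
        )
        comp = module_class_composition(modules, calls)
        assert comp.loc[1, "dominant_tissue"] == "liver"
        assert comp.loc[1, "purity"] == 1.0
        assert comp.loc[1, "n_TSCT"] == 2 and comp.loc[1, "n_TSNT"] == 1

    def test_empty_modules_give_empty_table(self):
        comp = module_class_composition(
            pd.DataFrame(columns=["module"]), pd.DataFrame(columns=["specific_tissue", "cls"])
        )
        assert comp.empty
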