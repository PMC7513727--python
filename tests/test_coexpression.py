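"""Network construction: adjacency, TOM, modules, eigengenes, hubs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ecodiverge import coexpression as cx


def tom_oracle(a):
    """Direct formula evaluation, element by element."""
    a = np.asarray(a, dtype=float)
    n = len(a)
    k = a.sum(axis=0) - np.diag(a)
    t = np.empty_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                t[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n)
                         if u not in (i, j))
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def planted_expression(rng, n_blocks=4, block_size=150, n_samples=60,
                       within_r=0.8):
    """Block-correlated matrix: factor share chosen so cor ~= within_r."""
    lam = np.sqrt(within_r)
    genes = []
    labels = []
    for b in range(n_blocks):
        f = rng.normal(0, 1, n_samples)
        for _ in range(block_size):
            g = lam * f + np.sqrt(1 - lam ** 2) * rng.normal(0, 1, n_samples)
            genes.append(g)
            labels.append(b)
    return pd.DataFrame(genes), np.array(labels)


class TestAdjacency:
    def test_perfect_pair_and_symmetry(self, rng):
        x = rng.normal(0, 1, size=(1, 50))
        expr = pd.DataFrame(np.vstack([x, 2 * x + 3, rng.normal(0, 1, (3, 50))]))
        a = cx.adjacency(expr, softpower=6)
        assert a[0, 1] == pytest.approx(1.0)
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 1.0)

    def test_uncorrelated_pair_near_zero(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, size=(2, 90)))
        a = cx.adjacency(expr, softpower=6)
        assert a[0, 1] <= 0.01


class TestTom:
    def test_isolated_perfect_pair_is_one(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 1.0
        t = cx.tom(a)
        assert t[0, 1] == pytest.approx(1.0)

    def test_five_gene_toy_matches_formula(self, rng):
        r = rng.random((5, 5))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 1.0)
        assert np.allclose(cx.tom(a), tom_oracle(a), atol=1e-12)

    def test_bounded_and_symmetric(self, rng):
        for n in (2, 3, 6):
            r = rng.random((n, n))
            a = (r + r.T) / 2
            np.fill_diagonal(a, 1.0)
            t = cx.tom(a)
            assert (t >= 0).all() and (t <= 1).all()
            assert np.allclose(t, t.T)
            assert np.allclose(np.diag(t), 1.0)


class TestModules:
    def test_planted_blocks_recovered(self, rng):
        expr, truth = planted_expression(rng)
        a = cx.adjacency(expr, 6)
        t = cx.tom(a)
        cfg = cx.NetworkConfig()
        asg = cx.detect_modules(t, cfg, gene_ids=expr.index, expr=expr)
        ari = adjusted_rand_score(truth, asg.labels.to_numpy())
        assert ari >= 0.9

    def test_recovery_degrades_with_weaker_correlation(self, rng):
        scores = []
        for r_within in (0.8, 0.3):
            expr, truth = planted_expression(
                rng, n_blocks=3, block_size=60, within_r=r_within)
            t = cx.tom(cx.adjacency(expr, 6))
            asg = cx.detect_modules(t, cx.NetworkConfig(),
                                    gene_ids=expr.index)
            scores.append(adjusted_rand_score(truth, asg.labels.to_numpy()))
        assert scores[0] >= scores[1]

    def test_noise_yields_few_modules(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, size=(200, 60)))
        t = cx.tom(cx.adjacency(expr, 6))
        asg = cx.detect_modules(t, cx.NetworkConfig(), gene_ids=expr.index)
        assert len(asg.modules) <= 2

    def test_deterministic(self, rng):
        expr, _ = planted_expression(rng, n_blocks=2, block_size=40)
        t = cx.tom(cx.adjacency(expr, 6))
        a1 = cx.detect_modules(t, cx.NetworkConfig(), gene_ids=expr.index)
        a2 = cx.detect_modules(t, cx.NetworkConfig(), gene_ids=expr.index)
        assert a1.labels.equals(a2.labels)


class TestEigengene:
    def test_single_gene_module(self, rng):
        x = rng.normal(5, 2, size=(1, 30))
        e = cx.module_eigengene(pd.DataFrame(x))
        z = (x[0] - x[0].mean()) / x[0].std()
        assert np.allclose(e, z / np.linalg.norm(z))

    def test_three_gene_toy_matches_svd_oracle(self, rng):
        x = rng.normal(0, 1, size=(3, 20))
        e = cx.module_eigengene(pd.DataFrame(x))
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        # oracle: leading eigenvector of the sample covariance Z'Z
        w, v = np.linalg.eigh(z.T @ z)
        lead = v[:, -1]
        assert abs(abs(np.dot(e, lead / np.linalg.norm(lead))) - 1) < 1e-9

    def test_sign_convention(self, rng):
        x = rng.normal(0, 1, size=(5, 30)) + rng.normal(0, 1, 30)
        e1 = cx.module_eigengene(pd.DataFrame(x))
        e2 = cx.module_eigengene(pd.DataFrame(-x))
        # orientation follows the module mean in both cases
        z1 = ((x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)).mean(0)
        assert np.corrcoef(e1, z1)[0, 1] > 0
        assert np.corrcoef(e2, -z1)[0, 1] > 0


class TestMerge:
    def _assignment(self, expr, labels):
        lab = pd.Series(labels, index=expr.index)
        eig = {m: cx.module_eigengene(expr.loc[lab == m])
               for m in sorted(set(labels)) if m != 0}
        return cx.ModuleAssignment(lab, eig)

    def test_identical_factor_modules_merge(self, rng):
        f = rng.normal(0, 1, 40)
        genes = [f + rng.normal(0, 0.2, 40) for _ in range(60)]
        expr = pd.DataFrame(genes)
        labels = [1] * 30 + [2] * 30
        merged = cx.merge_modules(expr, self._assignment(expr, labels), 0.20)
        assert len(merged.modules) == 1

    def test_orthogonal_modules_never_merge(self, rng):
        f1, f2 = rng.normal(0, 1, (2, 40))
        genes = [f1 + rng.normal(0, 0.2, 40) for _ in range(30)] + \
                [f2 + rng.normal(0, 0.2, 40) for _ in range(30)]
        expr = pd.DataFrame(genes)
        labels = [1] * 30 + [2] * 30
        merged = cx.merge_modules(expr, self._assignment(expr, labels), 0.20)
        assert len(merged.modules) == 2


class TestTraitCorrelation:
    def test_trait_equal_to_eigengene(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, size=(35, 30)))
        asg = cx.detect_modules(
            cx.tom(cx.adjacency(expr, 1)), cx.NetworkConfig(
                min_module_size=2, cut_method="height", cut_height=1.01),
            gene_ids=expr.index, expr=expr)
        m = asg.modules[0]
        traits = pd.DataFrame({"T": asg.eigengenes[m]})
        out = cx.module_trait_correlation(asg, traits)
        row = out[(out["module"] == m) & (out["trait"] == "T")].iloc[0]
        assert row["r"] == pytest.approx(1.0)

    def test_constant_trait_missing(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, size=(10, 20)))
        asg = self_assign = cx.ModuleAssignment(
            pd.Series([1] * 10, index=expr.index),
            {1: cx.module_eigengene(expr)})
        out = cx.module_trait_correlation(
            asg, pd.DataFrame({"T": np.ones(20)}))
        assert np.isnan(out["r"].iloc[0])


class TestHubs:
    def _cfg(self, **kw):
        base = dict(min_module_size=2)
        base.update(kw)
        return cx.NetworkConfig(**base)

    def test_star_topology_center_is_unique_hub(self):
        # 6 nodes: ceil(0.15 * 6) = 1, so only the top edge count qualifies
        n = 6
        t = np.full((n, n), 0.001)
        t[0, :] = t[:, 0] = 0.5
        np.fill_diagonal(t, 1.0)
        asg = cx.ModuleAssignment(pd.Series([1] * n), {})
        hubs = cx.hub_genes(t, asg, self._cfg(edge_threshold=0.01,
                                              hub_fraction=0.15))
        assert hubs.iloc[0] and hubs.sum() == 1

    def test_all_tied_includes_everyone(self):
        n = 30
        t = np.full((n, n), 0.5)
        np.fill_diagonal(t, 1.0)
        asg = cx.ModuleAssignment(pd.Series([1] * n), {})
        hubs = cx.hub_genes(t, asg, self._cfg())
        assert hubs.all()

    def test_counts_match_direct_enumeration(self, rng):
        n = 50
        r = rng.random((n, n)) * 0.2
        t = (r + r.T) / 2
        np.fill_diagonal(t, 1.0)
        cfg = self._cfg(edge_threshold=0.1, hub_fraction=0.15)
        asg = cx.ModuleAssignment(pd.Series([1] * n), {})
        hubs = cx.hub_genes(t, asg, cfg)
        edges = np.array([sum(t[i, j] >= 0.1 for j in range(n) if j != i)
                          for i in range(n)])
        k = int(np.ceil(0.15 * n))
        boundary = np.sort(edges)[::-1][k - 1]
        assert np.array_equal(hubs.to_numpy(), edges >= boundary)
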