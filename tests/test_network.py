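"""Co-expression network layers against brute-force oracles and planted truth."""

import numpy as np
import pandas as pd
import pytest

from telncrna.network import (
    NetworkConfig,
    build_network,
    detect_modules,
    find_hubs,
    kme_kim,
    module_eigengene,
    module_eigengenes,
    module_trait_correlation,
    soft_adjacency,
    tom_similarity,
    trait_indicators,
    vst_transform,
)


def brute_force_tom(a):
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (shared + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return out


class TestVst:
    def test_values(self):
        counts = pd.DataFrame({"s": [0, 7]}, index=["a", "b"])
        expr, flat = vst_transform(counts, pd.Series({"s": 1.0}))
        assert expr.loc["a", "s"] == 0.0
        assert expr.loc["b", "s"] == pytest.approx(3.0)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(15)
        counts = pd.DataFrame(
            rng.integers(0, 200, size=(20, 4)), columns=list("abcd")
        )
        f = pd.Series(1.0, index=counts.columns)
        expr1, _ = vst_transform(counts, f)
        doubled = counts.copy()
        doubled["a"] *= 2
        f2 = f.copy()
        f2["a"] = 2.0
        expr2, _ = vst_transform(doubled, f2)
        assert np.allclose(expr1["a"], expr2["a"])

    def test_flat_rows_flagged(self):
        counts = pd.DataFrame({"s1": [5, 0], "s2": [5, 0]}, index=["a", "b"])
        _expr, flat = vst_transform(counts, pd.Series({"s1": 1.0, "s2": 1.0}))
        assert set(flat) == {"a", "b"}


class TestAdjacency:
    def test_powers(self):
        x = np.linspace(0, 1, 10)
        expr = pd.DataFrame(
            {"s" + str(i): [v, v, -v] for i, v in enumerate(x)},
            index=["a", "b", "c"],
        )
        a = soft_adjacency(expr, beta=12.0)
        assert a.loc["a", "b"] == pytest.approx(1.0)
        assert a.loc["a", "c"] == pytest.approx(1.0)  # unsigned: |r|
        assert np.all(np.diag(a) == 1.0)

    def test_power_arithmetic(self):
        assert 0.9**12 == pytest.approx(0.2824, abs=1e-4)

    def test_bad_beta(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 5)))
        with pytest.raises(ValueError):
            soft_adjacency(expr, beta=0.5)


class TestTom:
    def test_two_node_collapse(self):
        a = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]])
        tom = tom_similarity(a)
        assert tom.iloc[0, 1] == pytest.approx(0.4)

    def test_three_node_hand_evaluation(self):
        a = pd.DataFrame(np.full((3, 3), 0.5))
        np.fill_diagonal(a.to_numpy(), 1.0)
        tom = tom_similarity(a)
        # (0.25 + 0.5) / (1 + 1 - 0.5)
        assert tom.iloc[0, 1] == pytest.approx(0.5)

    def test_matches_triple_loop_fuzzed(self):
        rng = np.random.default_rng(16)
        for _ in range(20):
            n = int(rng.integers(3, 50))
            r = rng.uniform(0, 1, size=(n, n))
            a = (r + r.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = tom_similarity(pd.DataFrame(a)).to_numpy()
            assert np.allclose(tom, brute_force_tom(a), atol=1e-12)


def _planted_expr(rng, n_modules=3, size=30, n_background=60, n_samples=40, noise=0.3):
    rows, labels = [], []
    for m in range(n_modules):
        z = rng.standard_normal(n_samples)
        for i in range(size):
            rows.append(z + noise * rng.standard_normal(n_samples))
            labels.append(m + 1)
    for i in range(n_background):
        rows.append(rng.standard_normal(n_samples))
        labels.append(0)
    idx = [f"t{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), pd.Series(labels, index=idx)


class TestModules:
    def test_separable_blocks(self):
        rng = np.random.default_rng(17)
        expr, truth = _planted_expr(rng, n_modules=2, n_background=0)
        tom = tom_similarity(soft_adjacency(expr, 12.0))
        modules = detect_modules(tom, NetworkConfig())
        assert set(modules.unique()) == {"M1", "M2"}
        # each inferred module is exactly one planted block
        for m in ("M1", "M2"):
            assert truth[modules == m].nunique() == 1

    def test_pure_noise_goes_grey(self):
        rng = np.random.default_rng(18)
        expr = pd.DataFrame(
            rng.standard_normal((80, 40)), index=[f"t{i}" for i in range(80)]
        )
        tom = tom_similarity(soft_adjacency(expr, 12.0))
        modules = detect_modules(tom, NetworkConfig())
        assert (modules == "grey").all()

    def test_labels_invariant_to_input_order(self):
        rng = np.random.default_rng(19)
        expr, _ = _planted_expr(rng)
        tom = tom_similarity(soft_adjacency(expr, 12.0))
        modules = detect_modules(tom, NetworkConfig())
        perm = rng.permutation(len(expr))
        expr2 = expr.iloc[perm]
        tom2 = tom_similarity(soft_adjacency(expr2, 12.0))
        modules2 = detect_modules(tom2, NetworkConfig())
        assert (modules2.reindex(modules.index) == modules).all()


class TestEigengene:
    def test_single_member(self):
        expr = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]}, index=["a"])
        eig = module_eigengene(expr, ["a"])
        assert np.allclose(eig, (np.array([1, 2, 3]) - 2) / np.std([1, 2, 3]))

    def test_identical_members(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0]] * 2, index=["a", "b"],
            columns=["s1", "s2", "s3", "s4"],
        )
        eig = module_eigengene(expr, ["a", "b"])
        r = np.corrcoef(eig, expr.loc["a"])[0, 1]
        assert r == pytest.approx(1.0)

    def test_recovers_latent_factor(self):
        rng = np.random.default_rng(20)
        z = rng.standard_normal(50)
        expr = pd.DataFrame(
            [z + 0.3 * rng.standard_normal(50) for _ in range(30)],
            index=[f"t{i}" for i in range(30)],
        )
        eig = module_eigengene(expr, list(expr.index))
        assert abs(np.corrcoef(eig, z)[0, 1]) >= 0.95


class TestModuleTrait:
    def test_perfect_and_orthogonal(self):
        ind = np.array([1.0, 1, 0, 0, 0, 0, 1, 0, 0, 0])
        rng = np.random.default_rng(21)
        orth = rng.standard_normal(10)
        orth -= orth.mean()
        ind_c = ind - ind.mean()
        orth -= orth @ ind_c / (ind_c @ ind_c) * ind_c
        eig = pd.DataFrame([ind, orth], index=["M1", "M2"])
        traits = pd.DataFrame({"heat_V3": ind})
        res = module_trait_correlation(eig, traits)
        assert res.r.loc["M1", "heat_V3"] == pytest.approx(1.0)
        assert res.p.loc["M1", "heat_V3"] == pytest.approx(0.0, abs=1e-12)
        assert abs(res.r.loc["M2", "heat_V3"]) < 1e-8

    def test_constant_trait_dropped(self):
        eig = pd.DataFrame([[1.0, 2, 3, 4]], index=["M1"])
        traits = pd.DataFrame({"flat": [1.0, 1, 1, 1], "ok": [0.0, 1, 0, 1]})
        res = module_trait_correlation(eig, traits)
        assert res.dropped_traits == ["flat"]
        assert list(res.r.columns) == ["ok"]

    def test_planted_trait_is_rowwise_max(self, default_run):
        mt = default_run["module_trait"]
        truth = default_run["truth"]
        net = default_run["network"]
        # each planted module was tied to one stress trait; that cell should
        # dominate its row
        for m in net.eigengenes.index:
            members = set(net.modules.index[net.modules == m])
            planted = {truth.module_labels.get(t) for t in members}
            planted.discard(None)
            if len(planted) != 1:
                continue
            best = mt.best_trait(m)
            assert mt.r.loc[m].abs()[best] == mt.r.loc[m].abs().max()


class TestKmeKim:
    def test_member_identical_to_eigengene(self):
        rng = np.random.default_rng(22)
        z = rng.standard_normal(30)
        expr = pd.DataFrame(
            [z, z + 0.1 * rng.standard_normal(30)], index=["a", "b"]
        )
        modules = pd.Series(["M1", "M1"], index=["a", "b"])
        eig = module_eigengenes(expr, modules)
        adj = soft_adjacency(expr, 12.0)
        kme, kim = kme_kim(expr, adj, modules, eig)
        assert kme.loc["a", "M1"] >= 0.99

    def test_two_member_kim_is_mutual_adjacency(self):
        rng = np.random.default_rng(23)
        expr = pd.DataFrame(rng.standard_normal((2, 20)), index=["a", "b"])
        modules = pd.Series(["M1", "M1"], index=["a", "b"])
        adj = soft_adjacency(expr, 6.0)
        eig = module_eigengenes(expr, modules)
        _kme, kim = kme_kim(expr, adj, modules, eig)
        assert kim["a"] == pytest.approx(adj.loc["a", "b"])
        assert kim["b"] == pytest.approx(adj.loc["a", "b"])

    def test_kim_matches_restricted_row_sum(self):
        rng = np.random.default_rng(24)
        expr, truth = _planted_expr(rng, n_modules=2, size=10, n_background=5)
        adj = soft_adjacency(expr, 12.0)
        tom = tom_similarity(adj)
        modules = detect_modules(tom, NetworkConfig(min_module_size=5))
        eig = module_eigengenes(expr, modules)
        kme, kim = kme_kim(expr, adj, modules, eig)
        for t in expr.index:
            m = modules[t]
            if m == "grey":
                assert np.isnan(kim[t])
                continue
            members = [u for u in expr.index if modules[u] == m and u != t]
            assert kim[t] == pytest.approx(
                sum(adj.loc[t, u] for u in members)
            )


class TestHubs:
    def test_kme_gate(self, default_run):
        hubs = default_run["hubs"]
        assert (hubs["kME"] > 0.9).all()

    def test_count_bounded_by_top_fraction(self, default_run):
        net = default_run["network"]
        hubs = default_run["hubs"]
        for m, sub in hubs.groupby("module"):
            size = int((net.modules == m).sum())
            assert len(sub) <= int(np.ceil(0.1 * size))

    def test_hubs_are_module_members(self, default_run):
        net = default_run["network"]
        for _, row in default_run["hubs"].iterrows():
            assert net.modules[row["transcript_id"]] == row["module"]

    def test_planted_hubs_recovered(self, default_run):
        truth = default_run["truth"]
        found = set(default_run["hubs"]["transcript_id"])
        recall = len(found & set(truth.hub_ids)) / len(truth.hub_ids)
        assert recall >= 0.5  # per-seed; the 20-seed average is checked in acceptance


class TestPlantedModuleRecovery:
    def test_within_module_correlation(self, default_dataset):
        """module_cor=0.9 should yield mean within-module |r| >= 0.8 on the
        variance-stabilized scale."""
        from telncrna.diffexpr import median_ratio_size_factors

        counts = default_dataset["counts"]
        samples = default_dataset["samples"]
        truth = default_dataset["truth"]
        polya = samples.index[samples["library_type"] == "polyA"]
        factors = median_ratio_size_factors(counts[polya])
        expr, _ = vst_transform(counts[polya], factors)
        for m in {1, 2, 3}:
            members = [t for t, lab in truth.module_labels.items() if lab == m]
            sub = expr.loc[members].to_numpy()
            r = np.corrcoef(sub)
            vals = np.abs(r[np.triu_indices_from(r, k=1)])
            assert vals.mean() >= 0.8

    def test_module_ari(self, default_run):
        from sklearn.metrics import adjusted_rand_score

        truth = default_run["truth"]
        modules = default_run["network"].modules
        t_lab = [truth.module_labels.get(t, 0) for t in modules.index]
        i_lab = [0 if m == "grey" else int(m[1:]) for m in modules]
        assert adjusted_rand_score(t_lab, i_lab) >= 0.9
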