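import numpy as np
import pandas as pd
import pytest

from immunopipe.exceptions import ParameterError
from immunopipe.signature_network import (
    build_network,
    detect_modules,
    flag_nonrobust_representatives,
    prediction_strength,
    select_eigen_signatures,
)


def tom_bruteforce(adj: np.ndarray) -> np.ndarray:
    """Triple-loop signed TOM, independent of the vectorized implementation."""
    s = adj.shape[0]
    a = adj.copy()
    for i in range(s):
        a[i, i] = 0.0
    k = [sum(a[i, u] for u in range(s)) for i in range(s)]
    tom = np.eye(s)
    for i in range(s):
        for j in range(s):
            if i == j:
                continue
            shared = 0.0
            for u in range(s):
                shared += a[i, u] * a[u, j]
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def plant_scores(rng, n_modules=3, per_module=5, n_samples=60, within=0.9):
    """Signature scores with block correlation structure; returns (df, truth)."""
    factors = rng.standard_normal((n_samples, n_modules))
    rows, truth = [], []
    for m in range(n_modules):
        for j in range(per_module):
            rows.append(np.sqrt(within) * factors[:, m]
                        + np.sqrt(1 - within) * rng.standard_normal(n_samples))
            truth.append(m)
    ids = [f"sig{m}_{j}" for m in range(n_modules) for j in range(per_module)]
    return pd.DataFrame(rows, index=ids), np.array(truth)


class TestBuildNetwork:
    def test_anticorrelated_pairs(self, rng):
        # two perfectly correlated pairs, perfectly anticorrelated across:
        # within-pair a = TOM = 1, across a = 0
        base = rng.standard_normal(20)
        scores = pd.DataFrame(
            [base, 2 * base + 1, -base, -3 * base],
            index=["a1", "a2", "b1", "b2"],
        )
        net = build_network(scores, power=20)
        assert net.adjacency[0, 1] == pytest.approx(1.0)
        assert net.adjacency[0, 2] == pytest.approx(0.0)  # ((1-1)/2)^20
        assert net.tom[0, 1] == pytest.approx(1.0)
        assert net.tom[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_tom_matches_bruteforce(self, rng):
        for _ in range(10):
            scores = pd.DataFrame(rng.standard_normal((6, 20)),
                                  index=[f"s{i}" for i in range(6)])
            net = build_network(scores, power=float(rng.integers(1, 25)))
            assert np.max(np.abs(net.tom - tom_bruteforce(net.adjacency))) < 1e-12

    def test_tom_symmetric_bounded(self, rng):
        scores = pd.DataFrame(rng.standard_normal((8, 30)))
        net = build_network(scores, power=6)
        assert np.allclose(net.tom, net.tom.T, atol=1e-12)
        assert np.all(net.tom >= 0) and np.all(net.tom <= 1 + 1e-12)
        assert np.allclose(np.diag(net.tom), 1.0)
        assert np.allclose(np.diag(net.adjacency), 1.0)

    def test_power_monotonicity(self, rng):
        scores = pd.DataFrame(rng.standard_normal((5, 25)))
        low = build_network(scores, power=4).adjacency
        high = build_network(scores, power=12).adjacency
        off = ~np.eye(5, dtype=bool)
        assert np.all(high[off] <= low[off] + 1e-12)

    def test_constant_row_rejected(self, rng):
        scores = pd.DataFrame(rng.standard_normal((3, 10)), index=["a", "b", "c"])
        scores.loc["b"] = 5.0
        with pytest.raises(ParameterError, match="b"):
            build_network(scores)

    def test_too_few_signatures(self, rng):
        with pytest.raises(ParameterError):
            build_network(pd.DataFrame(rng.standard_normal((2, 10))))


class TestDetectModules:
    def test_planted_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        for seed in range(5):
            rng = np.random.default_rng(seed)
            scores, truth = plant_scores(rng)
            net = build_network(scores, power=20)
            mods = detect_modules(net, min_module_size=3)
            labels = np.array([mods.assignment[s] for s in scores.index])
            assert adjusted_rand_score(truth, labels) == 1.0

    def test_min_module_size_exceeds_s(self, rng):
        scores, _ = plant_scores(rng)
        net = build_network(scores)
        with pytest.raises(ParameterError):
            detect_modules(net, min_module_size=99)

    def test_eigen_is_connectivity_max(self, rng):
        scores, _ = plant_scores(rng)
        net = build_network(scores, power=20)
        mods = detect_modules(net)
        for mod, eig in mods.eigen_signature.items():
            members = [s for s, m in mods.assignment.items() if m == mod]
            best = max(members, key=lambda s: (mods.connectivity[s], s))
            assert mods.connectivity[eig] == pytest.approx(mods.connectivity[best])

    def test_eigen_reselected_after_removal(self, rng):
        scores, _ = plant_scores(rng)
        net = build_network(scores, power=20)
        mods = detect_modules(net)
        victim = mods.eigen_signature[1]
        reduced = scores.drop(index=victim)
        mods2 = detect_modules(build_network(reduced, power=20))
        for mod, eig in mods2.eigen_signature.items():
            assert eig != victim
            members = [s for s, m in mods2.assignment.items() if m == mod]
            assert mods2.connectivity[eig] == pytest.approx(
                max(mods2.connectivity[s] for s in members)
            )


class TestSelectEigenSignatures:
    def test_ordered_by_module_size(self, rng):
        scores, _ = plant_scores(rng, n_modules=2, per_module=4)
        extra, _ = plant_scores(np.random.default_rng(99), n_modules=1, per_module=6)
        extra.index = [f"x{i}" for i in range(6)]
        combined = pd.concat([scores, extra])
        mods = detect_modules(build_network(combined, power=20))
        reps = select_eigen_signatures(mods)
        sizes = [mods.module_sizes[mods.assignment[r]] for r in reps]
        assert sizes == sorted(sizes, reverse=True)

    def test_one_per_module(self, rng):
        scores, _ = plant_scores(rng)
        mods = detect_modules(build_network(scores, power=20))
        reps = select_eigen_signatures(mods)
        assert len(reps) == len(mods.module_sizes)


class TestPredictionStrength:
    def test_perfectly_separated_two_clusters(self, rng):
        n = 80
        x = np.vstack([rng.standard_normal((n // 2, 2)) - 20,
                       rng.standard_normal((n // 2, 2)) + 20])
        scores = pd.DataFrame(x.T, index=["d1", "d2"])
        assert prediction_strength(scores, k=2, n_splits=3, seed=0) == pytest.approx(1.0)

    def test_k_too_large(self, rng):
        scores = pd.DataFrame(rng.standard_normal((2, 10)))
        with pytest.raises(ParameterError):
            prediction_strength(scores, k=6)

    def test_flag_nonrobust(self, rng):
        # three-cluster structure carried by three representatives; a pure
        # noise representative cannot support k=3 on its own
        n = 120
        sep = np.repeat([-10.0, 0.0, 10.0], n // 3)
        informative = [sep + rng.standard_normal(n) for _ in range(3)]
        noise = rng.standard_normal(n)
        scores = pd.DataFrame(informative + [noise],
                              index=["i1", "i2", "i3", "noise"])
        flagged = flag_nonrobust_representatives(scores, k=3, n_splits=3, seed=1)
        assert flagged == ["noise"]
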