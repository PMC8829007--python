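import numpy as np
import pandas as pd
import pytest

from immunopipe.exceptions import ParameterError
from immunopipe.itb_pipeline import (
    compare_classifiers,
    compute_itbscore,
    cox_on_score,
    CoxResult,
    km_logrank,
    lasso_select,
    optimal_cutpoint,
    run_itb,
    split_cohort,
    univariate_cox,
)
from tests.conftest import make_survival


def sim_survival(rng, x, beta=0.7, censor_max=120.0, base_rate=0.02):
    t = rng.exponential(1.0 / (base_rate * np.exp(beta * x)))
    c = rng.uniform(0, censor_max, size=len(x))
    return make_survival(np.minimum(t, c), (t <= c).astype(int))


class TestSplitCohort:
    def test_stratified_70_30(self):
        ids = [f"s{i}" for i in range(100)]
        labels = np.repeat([0, 1], 50)
        train, test = split_cohort(ids, labels, 0.7, seed=0)
        assert len(train) == 70 and len(test) == 30
        lab = dict(zip(ids, labels))
        assert sum(lab[s] for s in train) == 35
        assert sum(lab[s] for s in test) == 15
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)

    def test_same_seed_identical(self):
        ids = [f"s{i}" for i in range(40)]
        labels = np.tile([0, 1], 20)
        assert split_cohort(ids, labels, 0.7, seed=3) == split_cohort(ids, labels, 0.7, seed=3)

    def test_fraction_one_rejected(self):
        with pytest.raises(ParameterError):
            split_cohort(["a", "b", "c", "d"], [0, 0, 1, 1], 1.0)

    def test_tiny_subtype_rejected(self):
        with pytest.raises(ParameterError):
            split_cohort(["a", "b", "c"], [0, 0, 1], 0.7)


class TestLassoSelect:
    def test_extreme_lambda_empty(self, rng):
        expr = pd.DataFrame(rng.standard_normal((20, 40)),
                            index=[f"g{i}" for i in range(20)])
        labels = np.tile([0, 1], 20)
        sel = lasso_select(expr, labels, lambda_grid=np.array([1e6]), seed=0)
        assert sel == []

    def test_constant_labels_rejected(self, rng):
        expr = pd.DataFrame(rng.standard_normal((5, 20)))
        with pytest.raises(ParameterError):
            lasso_select(expr, np.zeros(20))

    def test_informative_genes_recovered(self, rng):
        n = 120
        labels = np.tile([0, 1], n // 2)
        x = rng.standard_normal((50, n))
        x[:5, labels == 1] += 2.0
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(50)])
        sel = lasso_select(expr, labels, cv_folds=3, seed=0)
        informative = {f"g{i}" for i in range(5)}
        assert len(informative & set(sel)) >= 4
        assert len(set(sel) - informative) <= 10


class TestUnivariateCox:
    def test_zero_events_rejected(self, rng):
        x = rng.standard_normal(50)
        surv = make_survival(rng.uniform(1, 10, 50), np.zeros(50))
        with pytest.raises(ParameterError):
            univariate_cox(x, surv)

    def test_beta_recovery(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(500)
        surv = sim_survival(rng, x, beta=0.7)
        res = univariate_cox(x, surv)
        assert 0.5 <= res.coefficient <= 0.9
        assert res.ci_low <= res.hr <= res.ci_high
        assert res.hr == pytest.approx(np.exp(res.coefficient))

    def test_degenerate_covariate_flagged(self, rng):
        surv = sim_survival(rng, np.zeros(60))
        res = univariate_cox(np.zeros(60), surv)
        assert not res.converged
        assert res.ci_high == np.inf


def pc1_oracle_2x2(z1, z2):
    """First eigenvector of the 2x2 covariance, by the closed form."""
    cov = np.cov(np.vstack([z1, z2]), bias=True)
    tr, det = cov[0, 0] + cov[1, 1], cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    lam = tr / 2 + np.sqrt(tr ** 2 / 4 - det)
    v = np.array([cov[0, 1], lam - cov[0, 0]])
    return v / np.linalg.norm(v)


class TestComputeItbscore:
    def make_cox(self, gene, coef):
        return CoxResult(gene, coef, float(np.exp(coef)), 0.5, 2.0, 0.05, 30)

    def test_two_gene_hand_computation(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 1.0, 2.0]],
            index=["gp", "gn"], columns=list("abcd"),
        )
        cox = [self.make_cox("gp", 0.8), self.make_cox("gn", -0.5)]
        res = compute_itbscore(expr, cox)
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=0), axis=0)
        v = pc1_oracle_2x2(z.loc["gp"], z.loc["gn"])
        if v[0] - v[1] < 0:  # package sign rule: sum(pos) - sum(neg) >= 0
            v = -v
        expected = v[0] * z.loc["gp"].to_numpy() - v[1] * z.loc["gn"].to_numpy()
        assert res.score.to_numpy() == pytest.approx(expected, abs=1e-10)
        assert res.positive_genes == ["gp"]
        assert res.negative_genes == ["gn"]

    def test_decomposition_identity(self, rng):
        expr = pd.DataFrame(rng.standard_normal((6, 30)),
                            index=[f"g{i}" for i in range(6)])
        cox = [self.make_cox(f"g{i}", (-1) ** i * (0.2 + 0.1 * i)) for i in range(6)]
        res = compute_itbscore(expr, cox)
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=0), axis=0)
        manual = np.zeros(expr.shape[1])
        for g in res.positive_genes:
            manual += res.pc1_loadings[g] * z.loc[g].to_numpy()
        for g in res.negative_genes:
            manual -= res.pc1_loadings[g] * z.loc[g].to_numpy()
        assert res.score.to_numpy() == pytest.approx(manual, abs=1e-12)

    def test_all_positive_is_full_pc1_projection(self, rng):
        expr = pd.DataFrame(rng.standard_normal((5, 25)),
                            index=[f"g{i}" for i in range(5)])
        cox = [self.make_cox(f"g{i}", 0.5) for i in range(5)]
        res = compute_itbscore(expr, cox)
        assert res.negative_genes == []
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=0), axis=0)
        loadings = np.array([res.pc1_loadings[g] for g in res.gene_panel])
        assert res.score.to_numpy() == pytest.approx(loadings @ z.to_numpy(), abs=1e-12)

    def test_duplicating_samples_preserves_scores(self, rng):
        expr = pd.DataFrame(rng.standard_normal((4, 20)),
                            index=[f"g{i}" for i in range(4)],
                            columns=[f"s{j}" for j in range(20)])
        cox = [self.make_cox(f"g{i}", (-1) ** i * 0.4) for i in range(4)]
        base = compute_itbscore(expr, cox)
        doubled = pd.concat([expr, expr.add_suffix("_dup", axis=1)], axis=1)
        dup = compute_itbscore(doubled, cox)
        assert dup.score.iloc[:20].to_numpy() == pytest.approx(
            base.score.to_numpy(), abs=1e-8)

    def test_zero_coefficient_excluded(self, rng):
        expr = pd.DataFrame(rng.standard_normal((3, 15)), index=["a", "b", "c"])
        cox = [self.make_cox("a", 0.5), self.make_cox("b", -0.5), self.make_cox("c", 0.0)]
        res = compute_itbscore(expr, cox)
        assert "c" not in res.positive_genes + res.negative_genes
        assert "c" not in res.gene_panel

    def test_single_gene_rejected(self, rng):
        expr = pd.DataFrame(rng.standard_normal((1, 10)), index=["a"])
        with pytest.raises(ParameterError):
            compute_itbscore(expr, [self.make_cox("a", 1.0)])

    def test_split_mode(self, rng):
        expr = pd.DataFrame(rng.standard_normal((6, 40)),
                            index=[f"g{i}" for i in range(6)])
        cox = [self.make_cox(f"g{i}", (-1) ** i * 0.3) for i in range(6)]
        res = compute_itbscore(expr, cox, pca_mode="split")
        assert res.pca_mode == "split"
        assert len(res.score) == 40


class TestOptimalCutpoint:
    def test_step_hazard_recovered_near_zero(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            score = rng.uniform(-1, 1, 400)
            rate = np.where(score > 0, 0.06, 0.02)
            t = rng.exponential(1.0 / rate)
            c = rng.uniform(0, 80, 400)
            surv = make_survival(np.minimum(t, c), (t <= c).astype(int))
            cut, groups = optimal_cutpoint(pd.Series(score), surv)
            central = np.quantile(score, [0.45, 0.55])
            hits += central[0] <= cut <= central[1]
            assert set(groups.unique()) == {"high", "low"}
        assert hits >= 4

    def test_minprop_half_gives_median_split(self, rng):
        n = 40
        score = pd.Series(np.arange(n, dtype=float))
        t = rng.exponential(10, n)
        surv = make_survival(t, np.ones(n))
        cut, groups = optimal_cutpoint(score, surv, minprop=0.5)
        assert cut == pytest.approx(np.median(score.to_numpy()))
        assert (groups == "high").sum() == n // 2

    def test_degenerate_identical_event_times(self):
        score = pd.Series(np.arange(30, dtype=float))
        surv = make_survival(np.ones(30), np.ones(30))
        with pytest.raises(ParameterError):
            optimal_cutpoint(score, surv)

    def test_too_few_samples(self, rng):
        with pytest.raises(ParameterError):
            optimal_cutpoint(pd.Series(rng.standard_normal(10)),
                             make_survival(np.arange(10) + 1.0, np.ones(10)))


class TestKmLogrank:
    def test_single_group_rejected(self, rng):
        surv = make_survival(rng.uniform(1, 5, 10), np.ones(10))
        with pytest.raises(ParameterError):
            km_logrank(pd.Series(["a"] * 10), surv)

    def test_complete_separation(self):
        time = np.concatenate([np.arange(1, 21), np.arange(100, 120)]).astype(float)
        surv = make_survival(time, np.ones(40))
        groups = pd.Series(["a"] * 20 + ["b"] * 20)
        _, chi2, p = km_logrank(groups, surv)
        assert p < 1e-6

    def test_km_plateau_after_last_event(self, rng):
        time = np.array([1.0, 2.0, 3.0, 4.0] * 5)
        surv = make_survival(time, np.ones(20))
        groups = pd.Series(["a"] * 10 + ["b"] * 10)
        curves, _, _ = km_logrank(groups, surv)
        sf = curves["a"].iloc[:, 0]
        assert sf.iloc[-1] == pytest.approx(sf.min())

    def test_null_relabeling_p_roughly_uniform(self):
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            surv = make_survival(rng.exponential(10, 60), rng.binomial(1, 0.8, 60))
            groups = pd.Series(rng.permutation(np.repeat(["a", "b"], 30)))
            _, _, p = km_logrank(groups, surv)
            ps.append(p)
        assert 0.0 < np.mean(ps) < 1.0
        assert (np.array(ps) < 0.05).mean() <= 0.2


class TestCoxOnScore:
    def test_hr_direction(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(300)
        surv = sim_survival(rng, x, beta=0.5)
        res = cox_on_score(x, surv)
        assert res.hr > 1.0
        assert res.p_value < 0.01


class TestCompareClassifiers:
    def test_separable_subtypes(self, rng):
        n = 80
        labels = np.repeat([1, 2], n // 2)
        x = rng.standard_normal((30, n))
        x[:4, labels == 2] += 3.0
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(30)],
                            columns=[f"s{j}" for j in range(n)])
        reports = compare_classifiers(expr, labels, folds=5, seed=0, target=2)
        assert {r.algorithm for r in reports} == {"logistic", "svm", "random_forest"}
        for r in reports:
            assert len(r.fold_aucs) == 5
            assert r.cv_auc > 0.9


class TestRunItb:
    def test_end_to_end_small(self):
        rng = np.random.default_rng(11)
        n = 150
        q = rng.standard_normal(n)
        x = np.vstack([q + 0.7 * rng.standard_normal(n) for _ in range(6)])
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(6)],
                            columns=[f"s{j}" for j in range(n)])
        surv = sim_survival(rng, q, beta=0.8)
        surv.index = expr.columns
        res = run_itb(expr, list(expr.index), surv)
        assert res.cutpoint is not None
        assert set(res.group.unique()) == {"high", "low"}
        assert res.logrank_p < 0.05
        assert abs(np.corrcoef(res.score.to_numpy(), q)[0, 1]) > 0.7
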