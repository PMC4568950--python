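import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from srmsig import discovery
from srmsig.types import AbundanceMatrix, SignatureModel, ValidationError


def matrix_from(values: pd.DataFrame, cohort="t"):
    return AbundanceMatrix(values.astype(float),
                           pd.Series(cohort, index=values.index))


class TestImputeLOD:
    def test_direct_rule(self):
        df = pd.DataFrame({"P": [5.0, 7.0, np.nan]}, index=list("abc"))
        out = discovery.impute_lod(matrix_from(df))
        assert list(out.values["P"]) == [5.0, 7.0, 5.0]

    def test_no_missing_identity(self):
        df = pd.DataFrame({"P": [5.0, 7.0]}, index=list("ab"))
        out = discovery.impute_lod(matrix_from(df))
        pd.testing.assert_frame_equal(out.values, df)

    def test_per_cohort_minima(self):
        df = pd.DataFrame({"P": [5.0, np.nan, 9.0, np.nan]},
                          index=list("abcd"))
        cohort = pd.Series(["t", "t", "v", "v"], index=df.index)
        out = discovery.impute_lod(AbundanceMatrix(df, cohort))
        assert out.values.loc["b", "P"] == 5.0
        assert out.values.loc["d", "P"] == 9.0

    def test_entirely_missing_protein_errors(self):
        df = pd.DataFrame({"P": [np.nan, np.nan]}, index=list("ab"))
        with pytest.raises(ValidationError, match="P"):
            discovery.impute_lod(matrix_from(df))

    def test_observed_cells_unchanged_and_minima_preserved(self, rng):
        vals = rng.normal(10, 2, size=(30, 5))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        df = pd.DataFrame(vals, index=[f"s{i}" for i in range(30)],
                          columns=[f"P{j}" for j in range(5)])
        matrix = matrix_from(df)
        before_min = matrix.values.min()
        out = discovery.impute_lod(matrix)
        assert out.n_missing == 0
        observed = df.notna()
        assert np.allclose(out.values.to_numpy()[observed.to_numpy()],
                           df.to_numpy()[observed.to_numpy()])
        pd.testing.assert_series_equal(out.values.min(), before_min)


class TestFilterMissingProteins:
    def frame(self, n_missing, n=100):
        col = np.full(n, 10.0)
        col[:n_missing] = np.nan
        return pd.DataFrame({"P": col, "Q": np.full(n, 9.0)},
                            index=[f"s{i}" for i in range(n)])

    def test_41_of_100_removed(self):
        out = discovery.filter_missing_proteins(matrix_from(self.frame(41)))
        assert list(out.values.columns) == ["Q"]

    def test_exactly_40_kept(self):
        out = discovery.filter_missing_proteins(matrix_from(self.frame(40)))
        assert list(out.values.columns) == ["P", "Q"]

    def test_fully_observed_kept(self):
        out = discovery.filter_missing_proteins(matrix_from(self.frame(0)))
        assert list(out.values.columns) == ["P", "Q"]


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([0, 1] * 10, dtype=float)
        fit = discovery.fit_logistic(np.empty((20, 0)), y)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)
        assert fit.aic == pytest.approx(-2 * 20 * np.log(0.5) + 2)

    def test_separation_flagged(self):
        x = np.array([-2, -1.5, -1, 1, 1.5, 2.0])
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        fit = discovery.fit_logistic(x, y)
        assert fit.separated

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            discovery.fit_logistic(np.zeros((4, 1)), np.ones(4))

    def test_matches_grid_search_oracle(self, rng):
        x = rng.normal(0, 1, 20)
        y = (rng.random(20) < expit(0.5 + 0.8 * x)).astype(float)
        fit = discovery.fit_logistic(x, y)

        def nll(beta):
            eta = beta[0] + beta[1] * x
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        # coarse-to-fine grid search, independent of IRLS
        best = (0.0, 0.0)
        for width in (4.0, 0.5, 0.05, 0.005, 0.0005):
            b0s = np.linspace(best[0] - width, best[0] + width, 41)
            b1s = np.linspace(best[1] - width, best[1] + width, 41)
            vals = [(nll((a, b)), (a, b)) for a in b0s for b in b1s]
            best = min(vals)[1]
        assert abs(fit.coefficients[0] - best[0]) < 1e-3
        assert abs(fit.coefficients[1] - best[1]) < 1e-3

    def test_matches_scipy_optimizer(self, rng):
        X = rng.normal(0, 1, (40, 2))
        y = (rng.random(40) < expit(X @ [1.0, -0.5])).astype(float)
        fit = discovery.fit_logistic(X, y)

        def nll(beta):
            eta = beta[0] + X @ beta[1:]
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        res = minimize(nll, np.zeros(3), method="BFGS")
        assert np.allclose(fit.coefficients, res.x, atol=1e-4)


class TestStepwise:
    def test_zero_candidates_empty_set(self, rng):
        values = pd.DataFrame({"P": rng.normal(0, 1, 20)})
        y = np.array([0, 1] * 10, dtype=float)
        selected, trace = discovery.stepwise_select(values, y, candidates=[])
        assert selected == []
        assert len(trace) == 1

    def test_aic_trace_monotone(self, rng):
        n = 120
        X = pd.DataFrame(rng.normal(0, 1, (n, 6)),
                         columns=[f"P{j}" for j in range(6)])
        y = (rng.random(n) < expit(1.2 * X["P0"])).astype(float)
        _, trace = discovery.stepwise_select(X, y)
        assert all(b < a for a, b in zip(trace, trace[1:]))

    def test_planted_protein_recovered(self):
        # one predictive protein among 9 noise; n=400; 20 seeds; >= 19 hits
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(0, 1, (400, 10)),
                             columns=[f"P{j}" for j in range(10)])
            y = (rng.random(400) < expit(1.0 * X["P3"])).astype(float)
            selected, _ = discovery.stepwise_select(X, y)
            hits += "P3" in selected
        assert hits >= 19


class TestPredictProbability:
    def test_zero_model_gives_half(self):
        model = SignatureModel(["P"], [0.0], 0.0, 0.5)
        df = pd.DataFrame({"P": [1.0, -3.0, 7.0]}, index=list("abc"))
        probs = discovery.predict_probability(model, matrix_from(df))
        assert np.allclose(probs, 0.5)

    def test_monotone_in_abundance(self):
        model = SignatureModel(["P"], [1.0], 0.0, 0.5)
        df = pd.DataFrame({"P": np.linspace(-5, 5, 11)},
                          index=[f"s{i}" for i in range(11)])
        probs = discovery.predict_probability(model, matrix_from(df))
        assert probs.iloc[5] == pytest.approx(0.5)
        assert (np.diff(probs) > 0).all()
        assert probs.iloc[-1] > 0.99

    def test_closed_form(self):
        model = SignatureModel(["P"], [2.0], -1.0, 0.5)
        df = pd.DataFrame({"P": [1.0]}, index=["a"])
        probs = discovery.predict_probability(model, matrix_from(df))
        assert probs.iloc[0] == pytest.approx(1 / (1 + np.exp(-1)))

    def test_missing_protein_errors(self):
        model = SignatureModel(["P", "Q"], [1.0, 1.0], 0.0, 0.5)
        df = pd.DataFrame({"P": [1.0]}, index=["a"])
        with pytest.raises(ValidationError, match="Q"):
            discovery.predict_probability(model, matrix_from(df))


class TestChooseThreshold:
    def test_enumerated_midpoint(self):
        t = discovery.choose_threshold(
            np.array([0.1, 0.4, 0.6, 0.9]), np.array([0, 0, 1, 1]))
        assert t == pytest.approx(0.5)

    def test_perfectly_inverted_scores(self):
        probs = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([0, 0, 1, 1])
        t = discovery.choose_threshold(probs, labels)
        # best achievable accuracy is the majority rate at a sentinel
        acc = np.mean((probs >= t) == labels)
        assert acc == pytest.approx(0.5)
        assert t in (0.0, 1.0)

    def test_all_equal_probabilities(self):
        probs = np.full(6, 0.4)
        labels = np.array([0, 0, 0, 0, 1, 1])
        t = discovery.choose_threshold(probs, labels)
        acc = np.mean((probs >= t) == labels)
        assert acc == pytest.approx(4 / 6)

    def test_optimality_against_enumeration(self, rng):
        for _ in range(20):
            probs = rng.random(15)
            labels = (rng.random(15) < 0.5).astype(float)
            if len(np.unique(labels)) < 2:
                continue
            t = discovery.choose_threshold(probs, labels)
            best = max(np.mean((probs >= c) == labels)
                       for c in np.concatenate([[0, 1], probs]))
            assert np.mean((probs >= t) == labels) == pytest.approx(best)


class TestAssignFolds:
    def test_fold_arithmetic_200_subjects(self):
        ids = [f"s{i:03d}" for i in range(200)]
        labels = pd.Series(["CRC"] * 100 + ["healthy"] * 100, index=ids)
        folds = discovery.assign_folds(labels, k=10, seed=0)
        counts = pd.Series(folds).value_counts()
        assert (counts == 20).all()
        for f in range(10):
            members = [s for s, ff in folds.items() if ff == f]
            cases = sum(labels[m] == "CRC" for m in members)
            assert cases == 10

    def test_order_independent(self):
        ids = [f"s{i}" for i in range(40)]
        labels = pd.Series(["CRC"] * 20 + ["healthy"] * 20, index=ids)
        shuffled = labels.sample(frac=1.0, random_state=3)
        assert discovery.assign_folds(labels, 5, seed=7) == \
            discovery.assign_folds(shuffled, 5, seed=7)


class TestConsensusCV:
    def test_requires_imputed_matrix(self):
        df = pd.DataFrame({"P": [1.0, np.nan, 2.0, 1.5]}, index=list("abcd"))
        labels = pd.Series(["CRC", "CRC", "healthy", "healthy"],
                           index=list("abcd"))
        with pytest.raises(ValidationError):
            discovery.consensus_cv(matrix_from(df), labels, k=2)

    def test_recovers_planted_and_null(self, small_cohort):
        from conftest import discover_signature

        _, quant, meta, truth = small_cohort
        report, model = discover_signature(quant, meta, seed=11)
        assert set(report.consensus) & set(truth.marker_ids)
        assert model.protein_ids == report.consensus
        assert 0.0 <= model.threshold <= 1.0

    def test_deterministic_given_seed(self, small_matrix):
        matrix, labels = small_matrix
        matrix = discovery.impute_lod(
            discovery.filter_missing_proteins(matrix))
        r1, m1 = discovery.consensus_cv(matrix, labels, seed=4)
        r2, m2 = discovery.consensus_cv(matrix, labels, seed=4)
        assert r1.consensus == r2.consensus
        assert m1.to_json() == m2.to_json()

    def test_row_permutation_invariant(self, small_matrix):
        matrix, labels = small_matrix
        matrix = discovery.impute_lod(
            discovery.filter_missing_proteins(matrix))
        r1, _ = discovery.consensus_cv(matrix, labels, seed=4)
        perm = matrix.values.sample(frac=1.0, random_state=9)
        shuffled = AbundanceMatrix(perm, matrix.cohort.reindex(perm.index))
        r2, _ = discovery.consensus_cv(shuffled, labels, seed=4)
        assert r1.consensus == r2.consensus

    def test_empty_consensus_is_explicit(self, rng):
        # pure-noise data: expect a no-signature result, not an exception
        ids = [f"s{i}" for i in range(60)]
        df = pd.DataFrame(rng.normal(0, 1, (60, 5)),
                          columns=[f"P{j}" for j in range(5)], index=ids)
        labels = pd.Series(["CRC"] * 30 + ["healthy"] * 30, index=ids)
        report, model = discovery.consensus_cv(matrix_from(df), labels,
                                               k=5, seed=0)
        assert isinstance(model, SignatureModel)
        if not report.consensus:
            assert model.protein_ids == []


class TestExhaustiveSearch:
    def test_model_counts(self):
        assert discovery.n_subset_models(3, 2) == 6
        assert discovery.n_subset_models(5, 5) == 31
        for p in (4, 8, 12):
            for k in (1, 3, 5):
                expected = sum(math.comb(p, kk)
                               for kk in range(1, min(k, p) + 1))
                assert discovery.n_subset_models(p, k) == expected

    def test_enumeration_count_matches(self, rng):
        ids = [f"s{i}" for i in range(40)]
        df = pd.DataFrame(rng.normal(0, 1, (40, 5)),
                          columns=[f"P{j}" for j in range(5)], index=ids)
        labels = pd.Series(["CRC"] * 20 + ["healthy"] * 20, index=ids)
        res = discovery.exhaustive_search(matrix_from(df), labels,
                                          max_size=5, B=5, seed=0)
        assert res.n_models == 31

    def test_large_pool_refused_with_count(self, rng):
        ids = [f"s{i}" for i in range(20)]
        df = pd.DataFrame(rng.normal(0, 1, (20, 16)),
                          columns=[f"P{j}" for j in range(16)], index=ids)
        labels = pd.Series(["CRC"] * 10 + ["healthy"] * 10, index=ids)
        expected = discovery.n_subset_models(16, 5)
        with pytest.raises(ValidationError, match=str(expected)):
            discovery.exhaustive_search(matrix_from(df), labels, max_size=5)

    def test_dominant_marker_ranks_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 120
            ids = [f"s{i}" for i in range(n)]
            X = pd.DataFrame(rng.normal(0, 1, (n, 8)),
                             columns=[f"P{j}" for j in range(8)], index=ids)
            y = (rng.random(n) < expit(2.0 * X["P2"])).astype(float)
            labels = pd.Series(np.where(y == 1, "CRC", "healthy"), index=ids)
            res = discovery.exhaustive_search(
                matrix_from(X), labels, max_size=2, B=20, seed=seed)
            if res.protein_frequency.index[0] == "P2":
                hits += 1
        assert hits >= 9

    def test_no_bias_toward_larger_nested_model_on_noise(self):
        # out-of-bag evaluation should not systematically prefer {A, B}
        # over {A} on pure-noise data
        larger_wins = 0
        total = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            n = 80
            ids = [f"s{i}" for i in range(n)]
            X = pd.DataFrame(rng.normal(0, 1, (n, 2)), columns=["A", "B"],
                             index=ids)
            labels = pd.Series(["CRC"] * 40 + ["healthy"] * 40, index=ids)
            res = discovery.exhaustive_search(
                matrix_from(X), labels, max_size=2, B=100, seed=seed)
            med = res.models.set_index("proteins")["median_auc"]
            if med[("A", "B")] > med[("A",)]:
                larger_wins += 1
            total += 1
        assert larger_wins <= 7  # no significant bias at 10 replicates

    def test_seed_deterministic(self, rng):
        ids = [f"s{i}" for i in range(30)]
        df = pd.DataFrame(rng.normal(0, 1, (30, 4)),
                          columns=list("ABCD"), index=ids)
        labels = pd.Series(["CRC"] * 15 + ["healthy"] * 15, index=ids)
        r1 = discovery.exhaustive_search(matrix_from(df), labels, max_size=2,
                                         B=10, seed=5)
        r2 = discovery.exhaustive_search(matrix_from(df), labels, max_size=2,
                                         B=10, seed=5)
        pd.testing.assert_frame_equal(r1.models, r2.models)
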