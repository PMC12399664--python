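"""Variable prefiltering, forward stepwise selection, LOOCV, model p-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from canopydiv.regression import (
    SelectionConfig,
    correlation_prefilter,
    fit_diversity_model,
    forward_stepwise,
    loocv_evaluate,
    model_p_value,
    variance_inflation,
)


def df_from(arrs: dict) -> pd.DataFrame:
    return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in arrs.items()})


class TestPrefilter:
    def test_identical_columns_keep_better_correlated(self, rng):
        x = rng.normal(size=20)
        z = rng.normal(size=20)
        y = pd.Series(x + 0.1 * rng.normal(size=20))
        feats = df_from({"a_dup": x, "b_dup": x, "noise": z})
        kept, dropped = correlation_prefilter(feats, y)
        # exactly one of the duplicates survives
        assert sum(c in kept.columns for c in ("a_dup", "b_dup")) == 1
        assert "noise" in kept.columns

    def test_tie_broken_lexicographically(self, rng):
        x = rng.normal(size=15)
        y = pd.Series(rng.normal(size=15))
        feats = df_from({"b": x, "a": x})  # identical → identical response corr
        kept, dropped = correlation_prefilter(feats, y)
        assert list(kept.columns) == ["a"] and dropped == ["b"]

    def test_uncorrelated_table_unchanged(self, rng):
        feats = df_from({f"v{i}": rng.normal(size=40) for i in range(5)})
        y = pd.Series(rng.normal(size=40))
        kept, dropped = correlation_prefilter(feats, y)
        assert dropped == [] and list(kept.columns) == sorted(feats.columns)

    def test_constant_variable_dropped_first(self, rng):
        feats = df_from({"flat": np.ones(10), "x": rng.normal(size=10)})
        with pytest.warns(UserWarning, match="constant"):
            kept, dropped = correlation_prefilter(feats, pd.Series(rng.normal(size=10)))
        assert dropped == ["flat"]

    def test_matches_hand_enumerated_greedy_elimination(self):
        """5-variable toy built from orthogonal Hadamard vectors so the greedy
        pass is exactly derivable by hand.

        corr(v1,v2) = corr(v3,v4) = 1/sqrt(1.01) ≈ 0.995, all other pairs
        ≈ 0. y = e1 + 0.5 e3 + 0.2 e4, so |r(y,·)|: v2 > v1 and v3 > v4.
        Elimination: (v1,v2) → drop v1; (v3,v4) → drop v4. Survivors
        {v2, v3, v5}.
        """
        from scipy.linalg import hadamard

        Hm = hadamard(8).astype(float)
        e1, e2, e3, e4 = Hm[1], Hm[2], Hm[3], Hm[4]
        v1 = e1 + 0.1 * e2
        v2 = e1
        v3 = e3 + 0.1 * e4
        v4 = e3
        v5 = e4
        y = pd.Series(e1 + 0.5 * e3 + 0.2 * e4)
        feats = df_from({"v1": v1, "v2": v2, "v3": v3, "v4": v4, "v5": v5})
        corr = feats.corr().abs()
        assert corr.loc["v1", "v2"] > 0.8 and corr.loc["v3", "v4"] > 0.8
        assert corr.loc["v2", "v4"] < 0.8
        kept, dropped = correlation_prefilter(feats, y)
        assert set(kept.columns) == {"v2", "v3", "v5"}
        assert set(dropped) == {"v1", "v4"}

    def test_column_order_irrelevant(self, rng):
        cols = {f"v{i}": rng.normal(size=25) for i in range(6)}
        cols["v1"] = cols["v0"] * 0.95 + 0.05 * rng.normal(size=25)
        y = pd.Series(rng.normal(size=25))
        feats = df_from(cols)
        kept1, _ = correlation_prefilter(feats, y)
        kept2, _ = correlation_prefilter(feats[list(reversed(feats.columns))], y)
        assert list(kept1.columns) == list(kept2.columns)


class TestStepwise:
    def test_exact_linear_response(self, rng):
        x1 = rng.normal(size=20)
        x2 = rng.normal(size=20)
        feats = df_from({"x1": x1, "x2": x2})
        fit = forward_stepwise(feats, pd.Series(2.0 * x1), response_name="y")
        assert fit.variables == ["x1"]
        assert fit.r2_train == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_blocked_by_vif(self, rng):
        x1 = rng.normal(size=20)
        y = pd.Series(x1 + 0.05 * rng.normal(size=20))
        feats = df_from({"x1": x1, "x1_copy": x1})
        fit = forward_stepwise(feats, y)
        assert len(fit.variables) == 1  # second entry has infinite VIF

    def test_null_model_when_nothing_qualifies(self, rng):
        feats = df_from({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        y = pd.Series(rng.normal(size=20))
        cfg = SelectionConfig(entry_alpha=1e-6)
        with pytest.warns(UserWarning, match="null model"):
            fit = forward_stepwise(feats, y, cfg)
        assert fit.null_model and fit.variables == []
        assert model_p_value(fit) == 1.0

    def test_matches_exhaustive_order_oracle(self):
        """Selected set equals the one found by exhaustively trying every
        entry order under the same partial-F + VIF criterion."""
        rng = np.random.default_rng(7)
        n = 20
        X = rng.normal(size=(n, 4))
        y = pd.Series(X[:, 0] + X[:, 2] + 0.3 * rng.normal(size=n))
        feats = pd.DataFrame(X, columns=["x1", "x2", "x3", "x4"])
        cfg = SelectionConfig()
        fit = forward_stepwise(feats, y, cfg)

        # oracle: grow the model greedily but consider candidates in every
        # possible order; the entry criterion itself decides membership
        import itertools
        import statsmodels.api as sm

        def qualifies(current, cand):
            trial = current + [cand]
            res = sm.OLS(y.to_numpy(), sm.add_constant(feats[trial].to_numpy())).fit()
            if not res.pvalues[-1] < cfg.entry_alpha:
                return False
            return not (variance_inflation(feats[trial]) > cfg.vif_limit).any()

        best_sets = set()
        for order in itertools.permutations(feats.columns):
            current: list = []
            changed = True
            while changed:
                changed = False
                for cand in order:
                    if cand not in current and qualifies(current, cand):
                        current.append(cand)
                        changed = True
                        break
            best_sets.add(frozenset(current))
        assert frozenset(fit.variables) in best_sets

    def test_degrees_of_freedom_guard(self, rng):
        n = 6
        feats = df_from({f"x{i}": rng.normal(size=n) for i in range(5)})
        y = pd.Series(feats.sum(axis=1) + 0.01 * rng.normal(size=n))
        fit = forward_stepwise(feats, y)
        assert len(fit.variables) <= n - 3

    def test_training_r2_monotone_in_selection(self, rng):
        n = 24
        X = rng.normal(size=(n, 5))
        y = pd.Series(X[:, 0] + 0.5 * X[:, 1] + 0.2 * rng.normal(size=n))
        feats = pd.DataFrame(X, columns=[f"x{i}" for i in range(5)])
        import statsmodels.api as sm

        fit = forward_stepwise(feats, y)
        r2_path = []
        for k in range(1, len(fit.variables) + 1):
            res = sm.OLS(
                y.to_numpy(), sm.add_constant(feats[fit.variables[:k]].to_numpy())
            ).fit()
            r2_path.append(res.rsquared)
        assert all(b >= a - 1e-12 for a, b in zip(r2_path, r2_path[1:]))

    def test_support_recovery_rate(self):
        """y = x1 + x3 + noise with one pure-noise candidate, n=20, SNR >= 3:
        the exact support {x1, x3} is recovered in >= 90% of 200 replicates."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            n = 20
            X = rng.normal(size=(n, 3))
            signal = X[:, 0] + X[:, 2]
            noise_sd = signal.std() / 3.0  # SNR 3
            y = pd.Series(signal + noise_sd * rng.normal(size=n))
            feats = pd.DataFrame(X, columns=["x1", "x2", "x3"])
            fit = forward_stepwise(feats, y)
            hits += set(fit.variables) == {"x1", "x3"}
        assert hits / n_rep >= 0.9


class TestLoocv:
    def test_exact_linear_noise_free(self, rng):
        n = 15
        X = rng.normal(size=(n, 2))
        y = pd.Series(3.0 + X[:, 0] - 2.0 * X[:, 1])
        feats = pd.DataFrame(X, columns=["a", "b"])
        r2, rmse, mae, nd = loocv_evaluate(["a", "b"], feats, y)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert rmse == pytest.approx(0.0, abs=1e-9)
        assert mae == pytest.approx(0.0, abs=1e-9)
        assert nd == 0

    def test_press_hat_matrix_identity(self, rng):
        """Held-out squared-error sum equals PRESS via e_i/(1-h_ii)."""
        n = 18
        X = rng.normal(size=(n, 3))
        y = pd.Series(X @ [1.0, -0.5, 0.2] + rng.normal(size=n))
        feats = pd.DataFrame(X, columns=["a", "b", "c"])
        r2, rmse, _, _ = loocv_evaluate(["a", "b", "c"], feats, y)
        A = np.column_stack([np.ones(n), X])
        H = A @ np.linalg.solve(A.T @ A, A.T)
        resid = y.to_numpy() - H @ y.to_numpy()
        press = np.sum((resid / (1 - np.diag(H))) ** 2)
        assert rmse**2 * n == pytest.approx(press, rel=1e-9)
        sst = np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(1 - press / sst, rel=1e-9)

    def test_intercept_only_shrinkage(self, rng):
        """Intercept-only LOOCV R² = 1 − (n/(n−1))² < 0."""
        n = 12
        y = pd.Series(rng.normal(size=n))
        feats = pd.DataFrame(index=range(n))
        r2, *_ = loocv_evaluate([], feats, y)
        assert r2 == pytest.approx(1 - (n / (n - 1)) ** 2, rel=1e-9)
        assert r2 < 0

    def test_mae_not_above_rmse(self, rng):
        n = 20
        X = rng.normal(size=(n, 2))
        y = pd.Series(X[:, 0] + rng.normal(size=n))
        feats = pd.DataFrame(X, columns=["a", "b"])
        _, rmse, mae, _ = loocv_evaluate(["a"], feats, y)
        assert 0 <= mae <= rmse


class TestModelPValue:
    def test_perfect_fit_p_near_zero(self, rng):
        n = 20
        x = rng.normal(size=n)
        fit = forward_stepwise(df_from({"x": x}), pd.Series(5 * x))
        assert fit.p_value < 1e-12

    def test_single_predictor_f_equals_squared_t(self, rng):
        import statsmodels.api as sm

        n = 20
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.f_pvalue == pytest.approx(res.pvalues[1], rel=1e-9)
        assert res.fvalue == pytest.approx(res.tvalues[1] ** 2, rel=1e-9)

    def test_null_p_values_uniform(self):
        """Overall F-test p-values under a pure-noise response are uniform
        (KS test, alpha = 0.01, 1000 simulations)."""
        rng = np.random.default_rng(42)
        n = 15
        X = rng.normal(size=(n, 2))
        feats = pd.DataFrame(X, columns=["a", "b"])
        import statsmodels.api as sm

        A = sm.add_constant(X)
        pvals = []
        for _ in range(1000):
            y = rng.normal(size=n)
            pvals.append(sm.OLS(y, A).fit().f_pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFullPipelineFit:
    def test_fit_diversity_model_end_to_end(self, rng):
        n = 20
        x1 = rng.normal(size=n)
        x2 = x1 * 0.97 + 0.03 * rng.normal(size=n)  # collinear pair
        x3 = rng.normal(size=n)
        y = pd.Series(2 * x1 + 0.2 * rng.normal(size=n))
        feats = df_from({"x1": x1, "x2": x2, "x3": x3})
        fit = fit_diversity_model(feats, y, response_name="S")
        assert fit.response == "S"
        assert "x1" in fit.variables or "x2" in fit.variables
        assert fit.loocv_r2 > 0.8
        assert fit.loocv_mae <= fit.loocv_rmse
        # deterministic: same inputs, same fit
        fit2 = fit_diversity_model(feats, y, response_name="S")
        assert fit2.to_dict() == fit.to_dict()
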