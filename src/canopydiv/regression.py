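"""Variable selection, stepwise regression, and leave-one-out validation.

The modelling recipe used for every date/resolution scenario:

1. drop one member of every highly correlated variable pair (|r| > 0.8),
   keeping the member better correlated with the diversity response;
2. forward stepwise OLS over the survivors, candidates ranked by |r| with
   the response; a candidate enters only if its partial-F p-value is below
   ``entry_alpha`` and no retained predictor's VIF exceeds ``vif_limit``;
3. leave-one-out cross-validation of the selected model, reporting
   R² = 1 − PRESS/SST, RMSE and MAE of the held-out predictions, plus the
   full-model F-test p-value.

Selection is performed once on the full sample; LOOCV refits only the
coefficients, so its R² carries the usual selection optimism.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "ModelFit",
    "correlation_prefilter",
    "forward_stepwise",
    "loocv_evaluate",
    "model_p_value",
    "fit_diversity_model",
    "variance_inflation",
]


@dataclass
class SelectionConfig:
    pairwise_r_threshold: float = 0.8
    vif_limit: float = 10.0
    entry_alpha: float = 0.05
    max_predictors: int | None = None
    loocv_r2_definition: str = "press"  # or "corr" (squared prediction correlation)

    def __post_init__(self) -> None:
        if self.pairwise_r_threshold <= 0 or self.vif_limit <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.entry_alpha < 1.0:
            raise ValueError("entry_alpha must be in (0, 1)")


@dataclass
class ModelFit:
    response: str
    variables: list[str]
    coefficients: dict[str, float]
    intercept: float
    r2_train: float
    p_value: float
    n: int
    loocv_r2: float = float("nan")
    loocv_rmse: float = float("nan")
    loocv_mae: float = float("nan")
    n_dropped_folds: int = 0
    null_model: bool = False
    dropped_by_prefilter: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "variables": list(self.variables),
            "coefficients": dict(self.coefficients),
            "intercept": self.intercept,
            "r2_train": self.r2_train,
            "p_value": self.p_value,
            "n": self.n,
            "loocv_r2": self.loocv_r2,
            "loocv_rmse": self.loocv_rmse,
            "loocv_mae": self.loocv_mae,
            "n_dropped_folds": self.n_dropped_folds,
            "null_model": self.null_model,
        }


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    """R² of an intercept OLS fit via lstsq (rank-deficiency tolerant)."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        return 0.0
    return float(1.0 - np.sum(resid**2) / sst)


def variance_inflation(X: pd.DataFrame) -> pd.Series:
    """VIF_k = 1/(1 − R²) of predictor k regressed on the other predictors."""
    out = {}
    cols = list(X.columns)
    for k in cols:
        others = [c for c in cols if c != k]
        if not others:
            out[k] = 1.0
            continue
        r2 = _ols_r2(X[others].to_numpy(), X[k].to_numpy(dtype=float))
        out[k] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def correlation_prefilter(
    features: pd.DataFrame,
    response: pd.Series,
    config: SelectionConfig | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Greedy elimination of highly correlated variable pairs.

    Pairs are visited in decreasing |pairwise Pearson r|; while any pair
    exceeds the threshold, the member with the smaller |r| against the
    response is dropped (lexicographic name as tie-break). Constant
    variables are dropped first. The result is independent of input column
    order. Returns (filtered table, dropped variable names).
    """
    config = config or SelectionConfig()
    if len(features) < 3:
        raise ValueError("prefilter requires at least three plots")
    features = features[sorted(features.columns)]
    y = response.loc[features.index].to_numpy(dtype=float)
    dropped: list[str] = []
    constant = [c for c in features.columns if features[c].std() == 0]
    if constant:
        warnings.warn(f"constant variables dropped: {constant}", stacklevel=2)
        dropped.extend(constant)
        features = features.drop(columns=constant)
    cols = list(features.columns)
    resp_corr = {c: _abs_corr(features[c].to_numpy(dtype=float), y) for c in cols}
    corr = features.corr().abs()
    alive = set(cols)
    while True:
        best_pair, best_r = None, config.pairwise_r_threshold
        for i, a in enumerate(cols):
            if a not in alive:
                continue
            for b in cols[i + 1 :]:
                if b not in alive:
                    continue
                r = corr.loc[a, b]
                if r > best_r:  # strict: pairs exactly at the threshold survive
                    best_pair, best_r = (a, b), r
        if best_pair is None:
            break
        a, b = best_pair
        if resp_corr[a] > resp_corr[b]:
            loser = b
        elif resp_corr[b] > resp_corr[a]:
            loser = a
        else:
            loser = max(a, b)  # lexicographic tie-break: keep the smaller name
        alive.remove(loser)
        dropped.append(loser)
    kept = [c for c in cols if c in alive]
    return features[kept], dropped


def forward_stepwise(
    features: pd.DataFrame,
    response: pd.Series,
    config: SelectionConfig | None = None,
    response_name: str = "y",
) -> ModelFit:
    """Forward stepwise OLS with a partial-F entry test and VIF control.

    Candidates are considered in decreasing |Pearson r| with the response;
    at each step the highest-ranked candidate whose partial-F p-value is
    below ``entry_alpha`` and whose entry keeps every VIF within
    ``vif_limit`` enters. Stops when no candidate qualifies, the predictor
    cap is hit, or degrees of freedom run out (entry refused once
    n ≤ k + 3). Returns an intercept-only fit flagged ``null_model`` when
    nothing enters.
    """
    config = config or SelectionConfig()
    y = response.loc[features.index].to_numpy(dtype=float)
    n = len(y)
    order = sorted(
        features.columns,
        key=lambda c: (-_abs_corr(features[c].to_numpy(dtype=float), y), c),
    )
    selected: list[str] = []
    cap = config.max_predictors if config.max_predictors is not None else len(order)
    while len(selected) < cap:
        if n <= len(selected) + 3:
            logger.info("stepwise: degrees-of-freedom guard reached at k=%d", len(selected))
            break
        entered = None
        for cand in order:
            if cand in selected:
                continue
            trial = selected + [cand]
            X = sm.add_constant(features[trial].to_numpy(dtype=float))
            try:
                res = sm.OLS(y, X).fit()
            except Exception:  # pragma: no cover - singular design
                continue
            p_cand = res.pvalues[-1]
            if not np.isfinite(p_cand) or p_cand >= config.entry_alpha:
                continue
            if len(trial) > 1:
                vifs = variance_inflation(features[trial])
                if (vifs > config.vif_limit).any():
                    continue
            entered = cand
            break
        if entered is None:
            break
        selected.append(entered)
    if not selected:
        warnings.warn("no variable met the entry criterion; returning null model", stacklevel=2)
        return ModelFit(
            response=response_name,
            variables=[],
            coefficients={},
            intercept=float(np.mean(y)),
            r2_train=0.0,
            p_value=1.0,
            n=n,
            null_model=True,
        )
    X = sm.add_constant(features[selected].to_numpy(dtype=float))
    res = sm.OLS(y, X).fit()
    return ModelFit(
        response=response_name,
        variables=selected,
        coefficients={v: float(c) for v, c in zip(selected, res.params[1:])},
        intercept=float(res.params[0]),
        r2_train=float(res.rsquared),
        p_value=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 0.0,
        n=n,
    )


def loocv_evaluate(
    variables: list[str],
    features: pd.DataFrame,
    response: pd.Series,
    r2_definition: str = "press",
) -> tuple[float, float, float, int]:
    """Leave-one-out validation of a fixed variable set.

    Coefficients are refit without each plot and the held-out value
    predicted. Returns (R², RMSE, MAE, dropped folds). By default
    R² = 1 − PRESS/SST; ``r2_definition='corr'`` reports the squared Pearson
    correlation between predictions and observations instead. Singular
    folds are dropped with a warning.
    """
    y = response.loc[features.index].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV requires at least three plots")
    X = features[variables].to_numpy(dtype=float) if variables else np.empty((n, 0))
    A = np.column_stack([np.ones(n), X])
    preds = np.full(n, np.nan)
    dropped = 0
    for i in range(n):
        idx = np.arange(n) != i
        Ai = A[idx]
        try:
            coef, _, rank, _ = np.linalg.lstsq(Ai, y[idx], rcond=None)
        except np.linalg.LinAlgError:
            rank = -1
        if rank < A.shape[1]:
            dropped += 1
            warnings.warn(f"fold {i} singular; dropped from LOOCV", stacklevel=2)
            continue
        preds[i] = A[i] @ coef
    ok = np.isfinite(preds)
    if ok.sum() < 2:
        raise ValueError("too few LOOCV folds evaluated")
    resid = y[ok] - preds[ok]
    sst = np.sum((y[ok] - y[ok].mean()) ** 2)
    if r2_definition == "corr":
        r2 = float(np.corrcoef(y[ok], preds[ok])[0, 1] ** 2) if preds[ok].std() > 0 else 0.0
    else:
        r2 = float(1.0 - np.sum(resid**2) / sst) if sst > 0 else float("nan")
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    return r2, rmse, mae, dropped


def model_p_value(fit: ModelFit) -> float:
    """Overall F-test p-value of the fitted model (1.0 for the null model)."""
    return 1.0 if fit.null_model else fit.p_value


def fit_diversity_model(
    features: pd.DataFrame,
    response: pd.Series,
    config: SelectionConfig | None = None,
    response_name: str = "y",
) -> ModelFit:
    """Prefilter → forward stepwise → LOOCV, returning a complete ModelFit."""
    config = config or SelectionConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered, dropped = correlation_prefilter(features, response, config)
        fit = forward_stepwise(filtered, response, config, response_name=response_name)
    fit.dropped_by_prefilter = dropped
    if not fit.null_model:
        r2, rmse, mae, nd = loocv_evaluate(
            fit.variables, features, response, config.loocv_r2_definition
        )
        fit.loocv_r2, fit.loocv_rmse, fit.loocv_mae, fit.n_dropped_folds = r2, rmse, mae, nd
    return fit
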