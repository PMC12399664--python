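"""Hierarchical partitioning of explained variance.

Decomposes a fitted linear model's R² into one non-negative independent
contribution I_k per predictor: the average, over all orderings in which the
predictors could enter the model, of the R² increment contributed by
predictor k (the Shapley/LMG decomposition). The increments telescope, so
Σ I_k equals the full-model R² exactly. Contributions are aggregated to the
four heterogeneity-metric families and summarized across a set of models
(e.g. the six dates of a phenology sweep), including the coefficient of
variation of each family's share across models.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .metrics import FAMILIES

__all__ = ["PartitionTable", "hierarchical_partition", "family_aggregate"]

MAX_PREDICTORS = 15


@dataclass
class PartitionTable:
    """Per-variable independent contributions for one fitted model."""

    table: pd.DataFrame  # index variable; columns independent_r2, percent, family
    model_label: str
    response: str
    full_r2: float


def _subset_r2(X: np.ndarray, y: np.ndarray) -> dict[frozenset, float]:
    """OLS R² of every predictor subset (with intercept)."""
    n, k = X.shape
    sst = float(np.sum((y - y.mean()) ** 2))
    r2: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, k + 1):
        for subset in combinations(range(k), size):
            A = np.column_stack([np.ones(n), X[:, subset]])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ coef
            r2[frozenset(subset)] = 0.0 if sst == 0 else float(1.0 - np.sum(resid**2) / sst)
    return r2


def hierarchical_partition(
    features: pd.DataFrame,
    response: pd.Series,
    families: dict[str, str] | None = None,
    model_label: str = "",
    response_name: str = "y",
) -> PartitionTable:
    """Independent contribution of each selected variable to the model R².

    Enumerates OLS R² over all 2^k predictor subsets and averages each
    variable's R² increment with the LMG subset-size weights
    w(s) = s!(k−1−s)!/k!, which equals the average over all k! entry
    orderings. Percentages are shares of Σ I_k (= full-model R²).
    """
    cols = list(features.columns)
    k = len(cols)
    if k == 0:
        raise ValueError("no predictors to partition")
    if k > MAX_PREDICTORS:
        raise ValueError(
            f"{k} predictors would require 2^{k} subset fits; reduce the model "
            f"(limit {MAX_PREDICTORS})"
        )
    X = features.to_numpy(dtype=float)
    y = response.loc[features.index].to_numpy(dtype=float)
    r2 = _subset_r2(X, y)
    kfact = factorial(k)
    contrib = np.zeros(k)
    for j in range(k):
        others = [i for i in range(k) if i != j]
        for size in range(0, k):
            w = factorial(size) * factorial(k - 1 - size) / kfact
            for subset in combinations(others, size):
                s = frozenset(subset)
                contrib[j] += w * (r2[s | {j}] - r2[s])
    contrib = np.where(np.abs(contrib) < 1e-12, np.maximum(contrib, 0.0), contrib)
    total = contrib.sum()
    percent = contrib / total * 100.0 if total > 0 else np.zeros(k)
    table = pd.DataFrame(
        {
            "independent_r2": contrib,
            "percent": percent,
            "family": [families.get(c, "") if families else "" for c in cols],
        },
        index=pd.Index(cols, name="variable"),
    )
    return PartitionTable(
        table=table,
        model_label=model_label,
        response=response_name,
        full_r2=r2[frozenset(range(k))],
    )


def family_aggregate(
    partitions: list[PartitionTable],
    families: tuple[str, ...] = FAMILIES,
) -> pd.DataFrame:
    """Family-level shares across a set of models.

    Per model, a family's share is the sum of its members' percentages (0
    when absent). Across models the summary reports the mean share and the
    coefficient of variation (sample sd / mean) of the per-model shares; a
    single-model set gets CV 0 with ``cv_defined=False``.
    """
    if not partitions:
        raise ValueError("no partitions to aggregate")
    share_rows = []
    for pt in partitions:
        shares = {f: 0.0 for f in families}
        for _, row in pt.table.iterrows():
            fam = row["family"]
            if fam in shares:
                shares[fam] += float(row["percent"])
        shares["model_label"] = pt.model_label
        share_rows.append(shares)
    per_model = pd.DataFrame(share_rows).set_index("model_label")
    mean_share = per_model.mean(axis=0)
    single = len(per_model) < 2
    if single:
        cv = pd.Series(0.0, index=per_model.columns)
    else:
        sd = per_model.std(axis=0, ddof=1)
        cv = pd.Series(
            np.where(mean_share > 0, sd / mean_share.replace(0, np.nan), 0.0),
            index=per_model.columns,
        ).fillna(0.0)
    out = pd.DataFrame(
        {"mean_share": mean_share, "cv_across_models": cv, "cv_defined": not single}
    )
    out.index.name = "family"
    return out
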