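"""Spearman association of TERs and delays with operon covariates.

Reproduces the structure of a rank-correlation table: each response
(TER, delay) against each covariate column (expression levels, sequence
features, binary regulator/sigma-factor flags).  Correlations use
average ranks (tie-corrected); p-values are exact by full permutation
enumeration for small samples and use the asymptotic t approximation
otherwise.  No multiple-testing correction is applied; significance is
marked at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "spearman", "feature_correlations",
           "EXACT_P_MAX_N"]

EXACT_P_MAX_N = 8  # full enumeration up to 8! = 40320 permutations


class ConstantInputError(ValueError):
    """Spearman's rho is undefined when an input vector is constant."""


@dataclass(frozen=True)
class CorrelationResult:
    response: str
    feature: str
    rho: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all permutations of y's ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    n = x.size
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]
    sd = ry.std()
    rhos = (ry_perm - ry.mean()) @ rx / (n * sd)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rho with a two-sided p-value.

    p is exact (full permutation enumeration) for n <= 8, asymptotic
    (t approximation) otherwise.  Raises :class:`ConstantInputError`
    for constant inputs, where rho is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("constant input: rho undefined")
    rho, p_asym = stats.spearmanr(x, y)
    if x.size <= EXACT_P_MAX_N:
        return float(rho), _exact_permutation_p(x, y, float(rho))
    return float(rho), float(p_asym)


def feature_correlations(ters: pd.DataFrame,
                         features: pd.DataFrame,
                         responses: tuple[str, ...] = ("ter_nt_s", "delay_s"),
                         feature_cols: Sequence[str] | None = None,
                         ) -> pd.DataFrame:
    """Correlate each response with each feature column, joined on operon.

    Boolean covariates are encoded 0/1.  Rows with missing values in a
    pair are dropped pairwise.  Returns a table with response, feature,
    rho, p_value, n and a significance flag at p < 0.05; undefined
    correlations (constant columns) are flagged with NaN rho.
    """
    merged = ters.merge(features, on="operon", how="inner")
    if merged.empty:
        raise ValueError("no operons shared between TER results and features")
    if feature_cols is None:
        feature_cols = [c for c in features.columns
                        if c != "operon"
                        and (pd.api.types.is_numeric_dtype(features[c])
                             or pd.api.types.is_bool_dtype(features[c]))]
    rows = []
    for resp in responses:
        for feat in feature_cols:
            pair = merged[[resp, feat]].astype(float).dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 joined rows for {resp} ~ {feat}")
            try:
                rho, p = spearman(pair[resp].values, pair[feat].values)
                flag = ""
            except ConstantInputError:
                rho, p, flag = float("nan"), float("nan"), "constant_input"
            rows.append({"response": resp, "feature": feat, "rho": rho,
                         "p_value": p, "n": len(pair),
                         "significant": bool(p < 0.05) if np.isfinite(p) else False,
                         "flag": flag})
    return pd.DataFrame(rows)
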