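"""Attribution of corrected turnover to its candidate drivers.

A standardized linear regression explains per-cell corrected turnover
(``pbeta_simC``) from three drivers - distance to refugia (DistRef),
climate-change velocity (Vocc) and mean range size (RangeS), with
climate stability (ClimStab) substitutable for DistRef - each entering
with a linear and a quadratic term.  Relative importance uses the LMG
(Shapley) decomposition of R^2 at the level of variable groups: a
variable's linear+quadratic pair enters or leaves the model as a unit,
and its contribution is the increment in R^2 averaged over all orderings
of the three groups.  The three group contributions sum exactly to the
full-model R^2 and are rescaled to proportions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ImportanceResult",
    "build_driver_stack",
    "fit_driver_model",
    "lmg_importance",
    "predictor_correlations",
]


def build_driver_stack(turnover: pd.DataFrame, dist_ref: np.ndarray,
                       vocc_final: np.ndarray, clim_stab: np.ndarray,
                       range_size: np.ndarray,
                       site_ids: np.ndarray) -> pd.DataFrame:
    """Per-cell driver table aligned on site ids, complete cases only.

    ``dist_ref``/``range_size`` are aligned with ``site_ids`` (the
    community rows); ``vocc_final``/``clim_stab`` are full rasters indexed
    by flat cell id.
    """
    pos = {sid: i for i, sid in enumerate(site_ids)}
    rows = turnover["site_id"].to_numpy()
    idx = np.array([pos[s] for s in rows])
    df = pd.DataFrame({
        "site_id": rows,
        "pbeta_simC": turnover["pbeta_simC"].to_numpy(),
        "DistRef": dist_ref[idx],
        "Vocc": vocc_final.ravel()[rows],
        "ClimStab": clim_stab.ravel()[rows],
        "RangeS": range_size[idx],
    })
    n0 = len(df)
    df = df.dropna().reset_index(drop=True)
    if len(df) < n0:
        logger.warning("build_driver_stack: dropped %d incomplete cells", n0 - len(df))
    return df


def _design(df: pd.DataFrame, variables: list[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Standardized response and 6-term design (z and standardized z^2)."""
    y = df["pbeta_simC"].to_numpy(dtype=float)
    y = (y - y.mean()) / y.std(ddof=0)
    cols, names = [], []
    for v in variables:
        x = df[v].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"driver {v!r} is constant")
        z = (x - x.mean()) / sd
        z2 = z**2
        z2 = (z2 - z2.mean()) / z2.std(ddof=0)
        cols += [z, z2]
        names += [v, f"{v}^2"]
    return y, np.column_stack(cols), names


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of an OLS with intercept (y and X already centered/standardized)."""
    if X.shape[1] == 0:
        return 0.0
    Xc = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    return 1.0 - float(resid @ resid) / float(y @ y)


def fit_driver_model(stack: pd.DataFrame, use_climstab: bool = False
                     ) -> tuple[pd.Series, float]:
    """OLS of standardized turnover residuals on the 6 standardized terms.

    Returns the coefficient series (intercept + 6 terms) and the model
    R^2.  Rank-deficient designs raise, naming the collinear columns.
    """
    variables = ["ClimStab" if use_climstab else "DistRef", "Vocc", "RangeS"]
    if len(stack) < 8:
        raise ValueError("need at least 8 complete-case cells")
    y, X, names = _design(stack, variables)
    Xc = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        bad = [
            f"{names[i]}~{names[j]}"
            for i, j in itertools.combinations(range(len(names)), 2)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or names}")
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    r2 = 1.0 - float(resid @ resid) / float(y @ y)
    return pd.Series(beta, index=["intercept"] + names), r2


@dataclass
class ImportanceResult:
    """LMG decomposition of the driver model's R^2."""

    variant: str                      # "DistRef" or "ClimStab"
    variables: list[str]
    r2: float
    contributions: np.ndarray         # unrescaled, sums to r2
    importances: np.ndarray           # rescaled to sum to 1
    coefficients: pd.Series = field(repr=False)
    level: str = "group"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.variables,
            "importance": self.importances,
            "contribution": self.contributions,
            "R2": self.r2,
            "model_variant": self.variant,
            "lmg_level": self.level,
        })


def _shapley_r2(y: np.ndarray, X: np.ndarray, groups: list[list[int]]
                ) -> np.ndarray:
    """Shapley (LMG) share of R^2 per group, by exhaustive subset enumeration."""
    k = len(groups)
    r2_cache: dict[frozenset, float] = {}
    for r in range(k + 1):
        for subset in itertools.combinations(range(k), r):
            cols = [c for g in subset for c in groups[g]]
            r2_cache[frozenset(subset)] = _r2(y, X[:, cols])
    shares = np.zeros(k)
    for g in range(k):
        total = 0.0
        for r in range(k):
            for subset in itertools.combinations([i for i in range(k) if i != g], r):
                w = math.factorial(r) * math.factorial(k - r - 1) / math.factorial(k)
                total += w * (r2_cache[frozenset(subset) | {g}]
                              - r2_cache[frozenset(subset)])
        shares[g] = total
    return shares


def lmg_importance(stack: pd.DataFrame, use_climstab: bool = False,
                   level: str = "group") -> ImportanceResult:
    """Relative importance of the three drivers by the LMG method.

    ``level="group"`` (default) treats each driver's linear+quadratic
    pair as one unit in the ordering average; ``level="term"`` runs the
    decomposition over all 6 terms and then sums the shares of each
    driver's two terms.  Both rescale the three contributions to
    proportions of 1; unrescaled contributions sum to the full-model R^2.
    """
    variables = ["ClimStab" if use_climstab else "DistRef", "Vocc", "RangeS"]
    coef, r2 = fit_driver_model(stack, use_climstab=use_climstab)
    y, X, _ = _design(stack, variables)
    if level == "group":
        groups = [[0, 1], [2, 3], [4, 5]]
        shares = _shapley_r2(y, X, groups)
    elif level == "term":
        term_shares = _shapley_r2(y, X, [[i] for i in range(6)])
        shares = term_shares.reshape(3, 2).sum(axis=1)
    else:
        raise ValueError("level must be 'group' or 'term'")
    total = shares.sum()
    importances = shares / total if total > 0 else np.full(3, 1 / 3)
    return ImportanceResult(variant=variables[0], variables=variables, r2=r2,
                            contributions=shares, importances=importances,
                            coefficients=coef, level=level)


def predictor_correlations(stack: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix among the four candidate drivers."""
    cols = ["DistRef", "Vocc", "ClimStab", "RangeS"]
    return stack[cols].corr()
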