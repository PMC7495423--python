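"""Glacial-refugia inference by suitability hindcasting and simulated spread.

For each species:

1. fit a binomial GLM (logit link) of present occurrence on climate,
   with linear and quadratic terms per variable and case weights that
   give presences and absences equal total mass (prevalence 0.5);
2. hindcast suitability for every 1000-year slice back to the LGM;
3. from every LGM-suitable cell (suitability > 0.5), simulate range
   expansion to the present with a 3x3-neighborhood automaton running
   ``m`` iterations per slice interval, colonization/persistence driven
   by squared suitability;
4. retain an origin cell as potential refugium if adding its
   accessibility map (reached-by-present, 0/1) to the GLM raises the
   explained deviance D2 with a positive coefficient;
5. pick the migration rate ``m*`` in 1..10 whose accessibility explains
   current occurrences best, and keep the origins retained at that rate.

Downstream surfaces: per-cell mean distance to the nearest inferred
refugium over the species present (DistRef) and mean range size (RangeS).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .grid import SiteGrid
from .io import ClimateStack, CommunityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NicheModel",
    "RefugiaSet",
    "fit_niche_glm",
    "hindcast_suitability",
    "kissmig_spread",
    "deterministic_spread_many",
    "detect_refugia",
    "distance_to_refugia",
    "mean_range_size",
    "migration_budget",
    "derive_seed",
]

#: deterministic-mode threshold applied to squared suitability
P_DET = 0.5
#: ridge penalty of the stabilized fallback fit
RIDGE_FALLBACK = 1e-6


def derive_seed(*parts) -> int:
    """Stable sub-seed (< 2^31) from arbitrary hashable parts."""
    h = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ----------------------------------------------------------------------
# weighted logistic regression (IRLS)
# ----------------------------------------------------------------------
def _standardize_columns(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (raw - mu) / sd, mu, sd


def _irls(X: np.ndarray, y: np.ndarray, w: np.ndarray, ridge: float = 0.0,
          max_iter: int = 40, tol: float = 1e-9) -> tuple[np.ndarray, bool]:
    """Iteratively reweighted least squares for a weighted binomial GLM.

    Convergence is declared on the relative deviance change (the usual
    GLM criterion), with step halving on deviance increase; this stays
    well behaved under quasi-separation, where coefficients may be large
    but the deviance plateaus.
    """
    n, p = X.shape
    beta = np.zeros(p)
    pen = ridge * np.eye(p)
    pen[0, 0] = 0.0  # never penalize the intercept
    dev = _weighted_deviance(X, y, w, beta)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        v = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / v
        W = w * v
        XtW = X.T * W
        try:
            new = np.linalg.solve(XtW @ X + pen, XtW @ z)
        except np.linalg.LinAlgError:
            return beta, False
        if not np.all(np.isfinite(new)):
            return beta, False
        new_dev = _weighted_deviance(X, y, w, new)
        halvings = 0
        while new_dev > dev + 1e-12 and halvings < 8:
            new = (new + beta) / 2.0
            new_dev = _weighted_deviance(X, y, w, new)
            halvings += 1
        if new_dev > dev + 1e-12:  # could not improve
            return beta, True
        converged = abs(dev - new_dev) / (abs(new_dev) + 0.1) < tol
        beta, dev = new, new_dev
        if converged:
            return beta, True
    return beta, False


def _weighted_deviance(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                       beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -30, 30)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))


@dataclass
class NicheModel:
    """Quadratic-logistic climate niche of one species.

    Coefficients refer to internally standardized term columns
    (``v, v^2`` per variable); ``col_means``/``col_sds`` map raw terms to
    that space, so predictions on new climate reproduce the fit exactly.
    ``d2`` is the explained deviance 1 - dev/null_dev under the
    prevalence-0.5 weights.
    """

    variables: list[str]
    coef: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    d2: float
    weights: np.ndarray = field(repr=False)
    converged: bool = True
    ridge_used: float = 0.0

    def raw_terms(self, values: np.ndarray) -> np.ndarray:
        """``[v, v^2]`` per variable from ``(n, n_vars)`` climate values."""
        cols = []
        for j in range(values.shape[1]):
            cols += [values[:, j], values[:, j] ** 2]
        return np.column_stack(cols)

    def linear_predictor(self, values: np.ndarray) -> np.ndarray:
        Z = (self.raw_terms(values) - self.col_means) / self.col_sds
        return self.coef[0] + Z @ self.coef[1:]

    def suitability(self, values: np.ndarray) -> np.ndarray:
        eta = np.clip(self.linear_predictor(values), -30, 30)
        return 1.0 / (1.0 + np.exp(-eta))


def _prevalence_weights(y: np.ndarray) -> np.ndarray:
    """Case weights giving presences and absences equal total mass.

    Total weight equals n; weighted presence mass = weighted absence
    mass = n/2 (prevalence 0.5 by weighting).
    """
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one presence and one absence")
    w = np.where(y > 0, n / (2.0 * n1), n / (2.0 * n0))
    return w


def fit_niche_glm(presence: np.ndarray, climate_values: np.ndarray,
                  variables: list[str]) -> NicheModel:
    """Fit the prevalence-weighted quadratic-logistic niche model.

    ``presence`` is a 0/1 vector over analysis cells, ``climate_values``
    the matching ``(n, n_vars)`` present-day climate.  On non-convergence
    (e.g. complete separation) the fit falls back to a ridge-stabilized
    IRLS (penalty 1e-6), logged.
    """
    y = np.asarray(presence, dtype=float)
    V = np.asarray(climate_values, dtype=float)
    if V.ndim != 2 or V.shape[0] != len(y):
        raise ValueError("climate_values must be (n_cells, n_vars)")
    w = _prevalence_weights(y)
    raw = np.column_stack([c for j in range(V.shape[1]) for c in (V[:, j], V[:, j] ** 2)])
    Z, mu, sd = _standardize_columns(raw)
    X = np.column_stack([np.ones(len(y)), Z])
    beta, ok = _irls(X, y, w)
    ridge = 0.0
    if not ok:
        beta, ok = _irls(X, y, w, ridge=RIDGE_FALLBACK)
        ridge = RIDGE_FALLBACK
        logger.warning("fit_niche_glm: plain IRLS did not converge; "
                       "ridge-stabilized fit used (penalty %g)", ridge)
    dev = _weighted_deviance(X, y, w, beta)
    null_beta, _ = _irls(np.ones((len(y), 1)), y, w)
    null_dev = _weighted_deviance(np.ones((len(y), 1)), y, w, null_beta)
    d2 = 1.0 - dev / null_dev if null_dev > 0 else 0.0
    return NicheModel(variables=list(variables), coef=beta, col_means=mu,
                      col_sds=sd, d2=float(d2), weights=w, converged=ok,
                      ridge_used=ridge)


# ----------------------------------------------------------------------
# hindcasting
# ----------------------------------------------------------------------
def hindcast_suitability(model: NicheModel, stack: ClimateStack) -> np.ndarray:
    """Per-slice suitability rasters ``(n_slices, n_y, n_x)``, NaN off-mask."""
    missing = set(model.variables) - set(stack.variables)
    if missing:
        raise ValueError(f"stack lacks model variables: {sorted(missing)}")
    grid = stack.grid
    ids = grid.masked_ids
    out = np.full((stack.n_slices, grid.n_y, grid.n_x), np.nan)
    for t in range(stack.n_slices):
        vals = np.column_stack(
            [stack.data[v][t].ravel()[ids] for v in model.variables]
        )
        out[t] = grid.raster_from_masked(model.suitability(vals))
    return out


def lgm_candidates(suit_stack: np.ndarray, grid: SiteGrid,
                   threshold: float = 0.5) -> np.ndarray:
    """Flat ids of cells strictly above the suitability threshold at LGM."""
    h0 = suit_stack[0].ravel()
    ids = grid.masked_ids
    return ids[h0[ids] > threshold]


# ----------------------------------------------------------------------
# 3x3 spread automaton
# ----------------------------------------------------------------------
def _dilate8(occ: np.ndarray) -> np.ndarray:
    """8-neighbor dilation (self included) along the last two axes."""
    out = occ.copy()
    out[..., 1:, :] |= occ[..., :-1, :]
    out[..., :-1, :] |= occ[..., 1:, :]
    out[..., :, 1:] |= occ[..., :, :-1]
    out[..., :, :-1] |= occ[..., :, 1:]
    out[..., 1:, 1:] |= occ[..., :-1, :-1]
    out[..., 1:, :-1] |= occ[..., :-1, 1:]
    out[..., :-1, 1:] |= occ[..., 1:, :-1]
    out[..., :-1, :-1] |= occ[..., 1:, 1:]
    return out


def _interval_suitability(suit_stack: np.ndarray) -> np.ndarray:
    """Suitability used for each slice interval: the older slice's map."""
    return suit_stack[:-1] if suit_stack.shape[0] > 1 else suit_stack


def deterministic_spread_many(suit_stack: np.ndarray, grid: SiteGrid,
                              origin_ids: np.ndarray, m: int,
                              p_det: float = P_DET) -> np.ndarray:
    """Deterministic spread from many origins at once.

    A cell is habitable in an interval iff ``h^2 > p_det`` for that
    interval's suitability; per iteration an occupied cell persists and
    colonizes its 8 neighbors within the habitable set.  Returns a
    ``(n_origins, n_y, n_x)`` boolean array of cells reached by the
    present.  Equivalent to breadth-first reachability with a per-interval
    step budget of ``m``.
    """
    if not 1 <= m <= 10:
        raise ValueError("iterations per step m must be in [1, 10]")
    origin_ids = np.atleast_1d(np.asarray(origin_ids, dtype=int))
    if not np.isin(origin_ids, grid.masked_ids).all():
        raise ValueError("origin off mask")
    S = _interval_suitability(suit_stack) ** 2 > p_det
    S &= grid.mask
    occ = np.zeros((len(origin_ids), grid.n_y, grid.n_x), dtype=bool)
    ox, oy = grid.cell_xy(origin_ids)
    occ[np.arange(len(origin_ids)), oy, ox] = True
    if suit_stack.shape[0] == 1:
        return occ & S[0]
    for t in range(S.shape[0]):
        for _ in range(m):
            occ = _dilate8(occ) & S[t]
            if not occ.any():
                return occ
    return occ


def kissmig_spread(suit_stack: np.ndarray, grid: SiteGrid, origin: int, m: int,
                   mode: str = "deterministic", n_reps: int = 30,
                   occ_threshold: float = 0.5, p_det: float = P_DET,
                   seed: int = 0) -> np.ndarray:
    """Accessibility map from one origin under the 3x3 automaton.

    Deterministic mode thresholds squared suitability at ``p_det``.
    Stochastic mode: per iteration each cell that is occupied, or
    unoccupied with an occupied 8-neighbor, stays/becomes occupied with
    probability ``h^2`` (one Bernoulli event per cell per iteration:
    colonization and persistence share the squared-suitability rate);
    the returned map flags cells occupied at the present in at least
    ``occ_threshold`` of ``n_reps`` replicates.
    """
    if mode == "deterministic":
        return deterministic_spread_many(suit_stack, grid, [origin], m,
                                         p_det=p_det)[0]
    if mode != "stochastic":
        raise ValueError("mode must be 'deterministic' or 'stochastic'")
    if not 1 <= m <= 10:
        raise ValueError("iterations per step m must be in [1, 10]")
    rng = np.random.default_rng(seed)
    S = _interval_suitability(suit_stack)
    prob = np.nan_to_num(S**2) * grid.mask
    occ = np.zeros((n_reps, grid.n_y, grid.n_x), dtype=bool)
    ox, oy = grid.cell_xy(np.asarray([origin]))
    occ[:, oy[0], ox[0]] = True
    if suit_stack.shape[0] == 1:
        occ &= rng.random(occ.shape) < prob[0]
    else:
        for t in range(S.shape[0]):
            for _ in range(m):
                event = rng.random(occ.shape) < prob[t]
                occ = _dilate8(occ) & event
    return occ.mean(axis=0) >= occ_threshold


def migration_budget(n_intervals: int = 21, m_range: tuple[int, int] = (1, 10),
                     cell_km: float = 18.6, step_years: float = 1000.0) -> dict:
    """Iteration totals and implied maximum migration rates of the automaton.

    With one automaton iteration moving at most one cell, ``m`` iterations
    per ``step_years`` over ``n_intervals`` intervals give
    ``n_intervals * m`` total iterations and a maximum migration rate of
    ``m * cell_km * 1000 / step_years`` meters per year.
    """
    lo, hi = m_range
    rate = lambda m: m * cell_km * 1000.0 / step_years
    return {
        "iterations_min": n_intervals * lo,
        "iterations_max": n_intervals * hi,
        "rate_min_m_per_yr": rate(lo),
        "rate_max_m_per_yr": rate(hi),
    }


# ----------------------------------------------------------------------
# refugia detection
# ----------------------------------------------------------------------
@dataclass
class RefugiaSet:
    """Inferred refugial origins of one species."""

    species: str
    m_star: int | None
    retained: np.ndarray                 # flat cell ids at m_star
    d2_initial: float
    d2_access: np.ndarray                # per retained origin at m_star
    retained_by_m: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    n_candidates: int = 0

    @property
    def found(self) -> bool:
        return self.m_star is not None and len(self.retained) > 0


def _fit_with_access_batch(base_Z: np.ndarray, y: np.ndarray, w: np.ndarray,
                           A: np.ndarray, null_dev: float,
                           max_iter: int = 40, tol: float = 1e-9
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Refit the niche GLM with one accessibility column per row of ``A``.

    Batched IRLS over origins (same responses and weights, designs
    differing only in the standardized accessibility column).  Returns
    ``(d2, access_coef, valid)`` arrays over origins; origins whose
    accessibility has no variation are invalid.
    """
    n_o, n = A.shape
    sd = A.std(axis=1)
    valid = sd > 0
    Astd = np.zeros_like(A, dtype=float)
    Astd[valid] = (A[valid] - A[valid].mean(axis=1, keepdims=True)) / sd[valid, None]
    p = base_Z.shape[1] + 2
    X = np.empty((n_o, n, p))
    X[:, :, 0] = 1.0
    X[:, :, 1:-1] = base_Z[None, :, :]
    X[:, :, -1] = Astd
    beta = np.zeros((n_o, p))
    dev = np.full(n_o, null_dev)
    active = valid.copy()

    wy, wc = w * y, w * (1 - y)

    def batch_dev(Xa: np.ndarray, b: np.ndarray) -> np.ndarray:
        eta = np.clip((Xa @ b[..., None])[..., 0], -30, 30)
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        return -2.0 * (np.log(mu) @ wy + np.log(1 - mu) @ wc)

    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        Xa, ba = X[idx], beta[idx]
        eta = np.clip((Xa @ ba[..., None])[..., 0], -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        v = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y[None, :] - mu) / v
        W = w[None, :] * v
        XtW = Xa.transpose(0, 2, 1) * W[:, None, :]
        XtWX = XtW @ Xa
        XtWz = (XtW @ z[..., None])[..., 0]
        new = ba.copy()
        try:
            new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            for k in range(len(idx)):
                try:
                    new[k] = np.linalg.solve(XtWX[k], XtWz[k])
                except np.linalg.LinAlgError:
                    valid[idx[k]] = False
                    active[idx[k]] = False
        bad = ~np.isfinite(new).all(axis=1)
        new[bad] = ba[bad]
        new_dev = batch_dev(Xa, new)
        # step-halve origins whose deviance rose
        for _h in range(8):
            worse = new_dev > dev[idx] + 1e-12
            if not worse.any():
                break
            new[worse] = (new[worse] + ba[worse]) / 2.0
            new_dev[worse] = batch_dev(Xa[worse], new[worse])
        improved = new_dev <= dev[idx] + 1e-12
        converged = improved & (np.abs(dev[idx] - new_dev)
                                / (np.abs(new_dev) + 0.1) < tol)
        take = idx[improved]
        beta[take] = new[improved]
        dev[take] = new_dev[improved]
        active[idx[converged]] = False
        active[idx[~improved]] = False
    d2 = 1.0 - dev / null_dev if null_dev > 0 else np.zeros(n_o)
    return d2, beta[:, -1], valid


def _fit_with_access(base_Z: np.ndarray, y: np.ndarray, w: np.ndarray,
                     access: np.ndarray) -> tuple[float, float] | None:
    """Refit the niche GLM with a standardized accessibility column.

    Returns ``(d2, access_coef)`` or None when accessibility has no
    variation (inestimable) or the fit fails even with ridge.
    """
    sd = access.std()
    if sd == 0:
        return None
    a = (access - access.mean()) / sd
    X = np.column_stack([np.ones(len(y)), base_Z, a])
    beta, ok = _irls(X, y, w)
    if not ok:
        beta, ok = _irls(X, y, w, ridge=RIDGE_FALLBACK)
        if not ok:
            return None
    dev = _weighted_deviance(X, y, w, beta)
    null_beta, _ = _irls(np.ones((len(y), 1)), y, w)
    null_dev = _weighted_deviance(np.ones((len(y), 1)), y, w, null_beta)
    return 1.0 - dev / null_dev, float(beta[-1])


def detect_refugia(species: str, presence: np.ndarray, stack: ClimateStack,
                   model: NicheModel | None = None,
                   m_range: range = range(1, 11), mode: str = "deterministic",
                   p_det: float = P_DET, n_reps: int = 30,
                   occ_threshold: float = 0.5, seed: int = 0,
                   rate_selection: str = "mean") -> RefugiaSet:
    """Infer a species' refugial cells by the accessibility/D2 criterion.

    ``presence`` is aligned with the stack grid's masked cells.  For each
    migration rate ``m`` and each LGM-suitable candidate origin, the
    accessibility map is simulated and added to the niche GLM; the origin
    is retained iff D2 strictly increases and the accessibility
    coefficient is positive.  ``m*`` maximizes the mean (or, with
    ``rate_selection="max"``, the maximum) D2-with-accessibility over
    retained origins; ties prefer the slower rate.
    """
    grid = stack.grid
    ids = grid.masked_ids
    y = np.asarray(presence, dtype=float)
    if len(y) != len(ids):
        raise ValueError("presence must align with masked cells")
    clim = np.column_stack([stack.data[v][-1].ravel()[ids] for v in stack.variables])
    if model is None:
        model = fit_niche_glm(y, clim, stack.variables)
    suit = hindcast_suitability(model, stack)
    candidates = lgm_candidates(suit, grid)
    raw = model.raw_terms(clim)
    base_Z = (raw - model.col_means) / model.col_sds
    w = model.weights
    null_beta, _ = _irls(np.ones((len(y), 1)), y, w)
    null_dev = _weighted_deviance(np.ones((len(y), 1)), y, w, null_beta)

    retained_by_m: dict[int, np.ndarray] = {}
    d2_by_m: dict[int, np.ndarray] = {}
    score_by_m: dict[int, float] = {}
    for m in m_range:
        if len(candidates) == 0:
            break
        if mode == "deterministic":
            reach = deterministic_spread_many(suit, grid, candidates, m,
                                              p_det=p_det)
        else:
            reach = np.stack([
                kissmig_spread(suit, grid, o, m, mode="stochastic",
                               n_reps=n_reps, occ_threshold=occ_threshold,
                               p_det=p_det,
                               seed=derive_seed(seed, species, int(o), m))
                for o in candidates
            ])
        A = reach.reshape(len(candidates), -1)[:, ids].astype(float)
        d2a, coef, valid = _fit_with_access_batch(base_Z, y, w, A, null_dev)
        keep = valid & (d2a > model.d2) & (coef > 0)
        if keep.any():
            retained_by_m[m] = candidates[keep].astype(int)
            d2_by_m[m] = d2a[keep]
            score_by_m[m] = float(np.mean(d2a[keep]) if rate_selection == "mean"
                                  else np.max(d2a[keep]))
    if not score_by_m:
        logger.warning("detect_refugia: no inferred refugium for %s "
                       "(%d candidates tried)", species, len(candidates))
        return RefugiaSet(species=species, m_star=None,
                          retained=np.empty(0, int), d2_initial=model.d2,
                          d2_access=np.empty(0), retained_by_m=retained_by_m,
                          n_candidates=len(candidates))
    m_star = min(score_by_m, key=lambda m: (-score_by_m[m], m))
    return RefugiaSet(species=species, m_star=m_star,
                      retained=retained_by_m[m_star],
                      d2_initial=model.d2, d2_access=d2_by_m[m_star],
                      retained_by_m=retained_by_m,
                      n_candidates=len(candidates))


# ----------------------------------------------------------------------
# driver surfaces
# ----------------------------------------------------------------------
def distance_to_refugia(refugia: dict[str, np.ndarray],
                        community: CommunityMatrix, grid: SiteGrid
                        ) -> np.ndarray:
    """Per-site mean distance (km) to the nearest refugium over species present.

    Species without inferred refugia are excluded from the mean (logged);
    sites whose species all lack refugia are NaN.
    """
    coords_all = grid.coords
    site_xy = community.coords
    n = community.n_sites
    have = [s for s in community.species_ids if len(refugia.get(s, ())) > 0]
    lacking = len(community.species_ids) - len(have)
    if lacking:
        logger.warning("distance_to_refugia: %d species without refugia "
                       "excluded from averaging", lacking)
    dist_sum = np.zeros(n)
    count = np.zeros(n)
    for s in have:
        j = community.species_ids.index(s)
        pres = community.presence[:, j]
        if not pres.any():
            continue
        d = cdist(site_xy, coords_all[np.asarray(refugia[s], int)]).min(axis=1)
        dist_sum[pres] += d[pres]
        count[pres] += 1
    out = np.full(n, np.nan)
    ok = count > 0
    out[ok] = dist_sum[ok] / count[ok]
    return out


def mean_range_size(community: CommunityMatrix) -> np.ndarray:
    """Per-site mean occupied-cell count over the species present (NaN if empty)."""
    sizes = community.range_sizes.astype(float)
    rich = community.richness
    out = np.full(community.n_sites, np.nan)
    ok = rich > 0
    out[ok] = (community.presence[ok] @ sizes) / rich[ok]
    return out
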