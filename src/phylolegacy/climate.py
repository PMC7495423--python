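"""Gradient-based climate-change velocity and climate stability.

Velocity (km/yr) of a climate variable is the ratio of its local temporal
trend *s* (units/yr, per 1000-year step) to its local spatial gradient
magnitude *g* (units/km, 3x3 neighborhood): ``v = s / g``.  Per-step
absolute velocities are averaged over all steps from the oldest slice to
the present, the per-cell maximum is taken across variables, extreme
values are reset to the 99.5th percentile, the field is log-transformed
and finally smoothed with a 5x5 masked mean filter (velocity is dominated
by local topographic gradients at scales finer than the community data).

Stability is the inverse of temporal variability (standard deviation of
consecutive-slice differences per cell), rescaled to [0, 1] per variable
by its maximum, combined multiplicatively across variables and rescaled
once more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d

from .io import ClimateStack

logger = logging.getLogger(__name__)

__all__ = [
    "VelocityField",
    "StabilityField",
    "temporal_trend_step",
    "spatial_gradient",
    "vocc",
    "climate_stability",
    "low_pass",
]

#: floor on the spatial gradient (units/km): avoids division blow-ups on
#: flat fields; extreme velocities are additionally percentile-clamped.
G_MIN = 1e-4
#: floor on velocity (km/yr) before the log transform.
V_MIN = 1e-6
#: floor on temporal variability before inversion to stability.
VAR_FLOOR = 1e-9


@dataclass
class VelocityField:
    """Climate-change velocity surfaces at each processing stage."""

    per_variable: dict[str, np.ndarray]  # mean |s/g| per step, per variable
    v_raw: np.ndarray = field(repr=False)      # max across variables, pre-clamp
    v_clamped: np.ndarray = field(repr=False)
    v_final: np.ndarray = field(repr=False)    # log + 5x5 low-pass
    clamp_value: float = np.nan
    n_clamped: int = 0


@dataclass
class StabilityField:
    variability: dict[str, np.ndarray]
    stability: dict[str, np.ndarray]       # per variable, rescaled to [0,1]
    combined: np.ndarray = field(repr=False)  # product, rescaled to [0,1]
    n_floored: int = 0


# ----------------------------------------------------------------------
def temporal_trend_step(stack: ClimateStack, var: str, t: int) -> np.ndarray:
    """Per-cell temporal trend (units/yr) between slices t and t+1.

    The two-point slope equals the OLS slope for two points.  Off-mask
    cells are NaN.
    """
    if not 0 <= t < stack.n_slices - 1:
        raise ValueError(f"step {t} out of range for {stack.n_slices} slices")
    dt_years = stack.ages[t] - stack.ages[t + 1]
    s = (stack.data[var][t + 1] - stack.data[var][t]) / dt_years
    s[~stack.grid.mask] = np.nan
    return s


def spatial_gradient(stack: ClimateStack, var: str, t: int,
                     g_min: float = G_MIN) -> np.ndarray:
    """Gradient magnitude (units/km) of slice t over 3x3 neighborhoods.

    Interior cells use central differences, edge and mask-boundary cells
    one-sided differences; cells with no masked neighbor on either axis
    are NaN.  The magnitude is floored at ``g_min``.
    """
    if stack.grid.n_x < 3 or stack.grid.n_y < 3:
        raise ValueError("spatial gradient needs a grid of at least 3x3")
    v = stack.data[var][t].copy()
    v[~stack.grid.mask] = np.nan
    d = stack.grid.cell_size

    def axis_slope(arr: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
        plus = np.roll(arr, -1, axis=axis)
        minus = np.roll(arr, 1, axis=axis)
        # roll wraps around; invalidate the wrapped border
        idx = [slice(None)] * arr.ndim
        idx[axis] = -1
        plus[tuple(idx)] = np.nan
        idx[axis] = 0
        minus[tuple(idx)] = np.nan
        has_p, has_m = np.isfinite(plus), np.isfinite(minus)
        slope = np.zeros_like(arr)
        both = has_p & has_m
        slope[both] = (plus[both] - minus[both]) / (2 * d)
        only_p = has_p & ~has_m
        slope[only_p] = (plus[only_p] - arr[only_p]) / d
        only_m = has_m & ~has_p
        slope[only_m] = (arr[only_m] - minus[only_m]) / d
        return slope, has_p | has_m

    gx, ok_x = axis_slope(v, axis=1)
    gy, ok_y = axis_slope(v, axis=0)
    g = np.hypot(np.where(ok_x, gx, 0.0), np.where(ok_y, gy, 0.0))
    g = np.maximum(g, g_min)
    g[~stack.grid.mask | ~(ok_x | ok_y)] = np.nan
    return g


def low_pass(values: np.ndarray, mask: np.ndarray, size: int = 5) -> np.ndarray:
    """Mean filter over a size x size window restricted to masked cells.

    No padding: near edges the mean runs over however many masked cells
    the window contains.  A uniform field is a fixed point.
    """
    valid = mask & np.isfinite(values)
    kern = np.ones((size, size))
    num = convolve2d(np.where(valid, values, 0.0), kern, mode="same")
    den = convolve2d(valid.astype(float), kern, mode="same")
    out = np.full(values.shape, np.nan)
    ok = mask & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def vocc(stack: ClimateStack, variables: list[str] | None = None,
         g_min: float = G_MIN, clamp_percentile: float = 99.5,
         filter_size: int = 5, v_min: float = V_MIN) -> VelocityField:
    """Climate-change velocity from the oldest slice to the present.

    Per variable and per 1000-year step, ``|s/g|`` with the gradient taken
    from the older slice of the step (state at the start of the
    interval); the per-step velocities are averaged.  The per-cell
    maximum across variables is clamped above its ``clamp_percentile``
    over masked cells, floored at ``v_min``, natural-log transformed and
    smoothed with a masked mean filter.
    """
    if stack.n_slices < 2:
        raise ValueError("velocity needs at least 2 slices")
    variables = variables or stack.variables
    mask = stack.grid.mask
    per_var: dict[str, np.ndarray] = {}
    for var in variables:
        acc = np.zeros((stack.grid.n_y, stack.grid.n_x))
        for t in range(stack.n_slices - 1):
            s = temporal_trend_step(stack, var, t)
            g = spatial_gradient(stack, var, t, g_min=g_min)
            acc += np.abs(s / g)
        per_var[var] = acc / (stack.n_slices - 1)
    v_raw = np.nanmax(np.stack([per_var[v] for v in variables]), axis=0)
    v_raw[~mask] = np.nan
    vals = v_raw[mask]
    if not np.isfinite(vals).any():
        raise ValueError("velocity field is all-NA")
    clamp = float(np.nanpercentile(vals, clamp_percentile))
    n_clamped = int(np.nansum(vals > clamp))
    v_clamped = np.minimum(v_raw, clamp)
    logger.info("vocc: clamped %d of %d cells at the %.1fth percentile (%.4g)",
                n_clamped, mask.sum(), clamp_percentile, clamp)
    v_final = low_pass(np.log(np.maximum(v_clamped, v_min)), mask, size=filter_size)
    return VelocityField(per_variable=per_var, v_raw=v_raw, v_clamped=v_clamped,
                         v_final=v_final, clamp_value=clamp, n_clamped=n_clamped)


def climate_stability(stack: ClimateStack, variables: list[str] | None = None,
                      mode: str = "sd", var_floor: float = VAR_FLOOR
                      ) -> StabilityField:
    """Combined climate stability in [0, 1] from temporal variability.

    Variability per cell and variable is the standard deviation
    (``mode="sd"``, default) or the mean absolute value (``mode="mad"``)
    of consecutive-slice differences.  Stability is its inverse (zero
    variability floored at ``var_floor``, flagged); per-variable maps are
    rescaled by their masked maximum, multiplied together, and the
    product rescaled once more so the masked maximum is exactly 1.
    """
    if stack.n_slices < 3:
        raise ValueError("stability needs at least 3 slices")
    if mode not in ("sd", "mad"):
        raise ValueError("mode must be 'sd' or 'mad'")
    variables = variables or stack.variables
    mask = stack.grid.mask
    variability: dict[str, np.ndarray] = {}
    stability: dict[str, np.ndarray] = {}
    n_floored = 0
    for var in variables:
        diffs = np.diff(stack.data[var], axis=0)
        if mode == "sd":
            v = diffs.std(axis=0, ddof=1)
        else:
            v = np.abs(diffs).mean(axis=0)
        v[~mask] = np.nan
        n_floored += int(np.nansum(v < var_floor))
        s = 1.0 / np.maximum(v, var_floor)
        s = s / np.nanmax(s[mask])
        variability[var] = v
        stability[var] = s
    if n_floored:
        logger.warning("climate_stability: %d cell-variable values had ~zero "
                       "variability; stability capped", n_floored)
    combined = np.prod(np.stack([stability[v] for v in variables]), axis=0)
    combined = combined / np.nanmax(combined[mask])
    combined[~mask] = np.nan
    return StabilityField(variability=variability, stability=stability,
                          combined=combined, n_floored=n_floored)
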