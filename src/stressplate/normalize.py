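"""Plate normalization: scaling, spline resampling, quantile normalization.

Raw well curves from different plates differ in intensity range, total
imaging time and acquisition grid.  The stage makes them comparable by

1. min–max scaling each plate × reporter group to [0, 1] (or computing the
   unscaled GFP-positive cell fraction instead, for assays that use it);
2. regressing each well curve on a natural cubic spline basis in time with
   6 degrees of freedom and sampling the fit at 24 equidistant time points
   spanning a common duration — the natural-spline linearity constraint
   beyond the boundary knots gives stable extrapolation when a plate was
   imaged for a shorter time than the common span;
3. quantile normalization across plates to equalize the value
   distributions plate by plate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synthetic import CURVE_COLUMNS

logger = logging.getLogger(__name__)

#: Number of equidistant resampled time points per condition.
N_RESAMPLED = 24

#: Keys identifying one curve within a run.
CURVE_KEYS = ["plate", "well", "reporter", "treatment", "concentration", "replicate", "feature"]


class NormalizeError(ValueError):
    """Raised on inputs the normalization stage cannot handle."""


# ---------------------------------------------------------------------------
# scaling


def minmax_scale(values: np.ndarray) -> np.ndarray:
    """Scale a group to [0, 1]: (x - min) / (max - min).

    A constant group maps to all zeros (guarded division), preserving order
    in every case.  Missing values pass through untouched.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        out = np.zeros_like(x)
        out[np.isnan(x)] = np.nan
        return out
    return (x - lo) / (hi - lo)


def gfp_positive_fraction(cell_values: np.ndarray, dmso_background: float) -> float:
    """Fraction of cells at or above twice the DMSO-control background.

    A GFP-positive cell is defined as reaching minimally twice the matched
    DMSO background level, so the 2× boundary itself counts as positive.
    """
    if dmso_background <= 0:
        raise NormalizeError("DMSO background must be positive")
    x = np.asarray(cell_values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise NormalizeError("no cell values to classify")
    return float(np.mean(x >= 2.0 * dmso_background))


# ---------------------------------------------------------------------------
# natural cubic spline regression


def natural_spline_basis(
    x: np.ndarray, interior_knots: np.ndarray, boundary: tuple[float, float]
) -> np.ndarray:
    """Natural cubic spline design matrix (intercept included).

    Truncated-power construction with the natural constraint: the basis is
    {1, x, d_k(x) - d_{K-1}(x)} over the ordered knots (boundary plus
    interior), which is cubic between knots and exactly linear outside the
    boundary knots — including analytic extrapolation.  Column count is
    ``len(interior_knots) + 2``.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = boundary
    knots = np.concatenate([[lo], np.sort(np.asarray(interior_knots, float)), [hi]])
    if np.any(np.diff(knots) <= 0):
        raise NormalizeError("spline knots must be strictly increasing")
    last, second_last = knots[-1], knots[-2]

    def d(k: float) -> np.ndarray:
        return (
            np.clip(x - k, 0, None) ** 3 - np.clip(x - last, 0, None) ** 3
        ) / (last - k)

    cols = [np.ones_like(x), x]
    d_last = d(second_last)
    for k in knots[:-2]:
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


def fit_resample_curve(
    time_h: np.ndarray,
    values: np.ndarray,
    df: int = 6,
    n_out: int = N_RESAMPLED,
    common_duration: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Least-squares natural-spline fit and equidistant resampling.

    ``df`` degrees of freedom put ``df - 1`` interior knots at the
    quantiles of the observed times, with boundary knots at the observed
    extremes.  The fit is evaluated at ``n_out`` equidistant points on
    [0, common_duration] (default: the last observed time); beyond the
    boundary knots the prediction continues linearly.

    Returns ``(times_out, predictions, rss, n_obs)`` where ``rss`` is the
    residual sum of squares at the observed times, needed later for the
    regression residual standard error.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = ~np.isnan(y)
    t, y = t[keep], y[keep]
    if len(t) < df + 1:
        raise NormalizeError(
            f"curve has {len(t)} non-missing points; a {df}-df spline fit needs "
            f"at least {df + 1}"
        )
    interior = np.quantile(t, np.linspace(0, 1, df + 1)[1:-1])
    basis = natural_spline_basis(t, interior, (t.min(), t.max()))
    beta, *_ = np.linalg.lstsq(basis, y, rcond=None)
    rss = float(np.sum((basis @ beta - y) ** 2))
    duration = float(common_duration) if common_duration is not None else float(t.max())
    t_out = np.linspace(0.0, duration, n_out)
    pred = natural_spline_basis(t_out, interior, (t.min(), t.max())) @ beta
    return t_out, pred, rss, len(t)


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(values_by_plate: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Classic quantile normalization of pooled per-plate value vectors.

    The reference is the mean of the plates' sorted vectors (equal-length
    case); each value is replaced by the reference at its rank, tied values
    sharing the mean reference value.  Plates of unequal length are handled
    by linear interpolation of the reference quantile function.  A single
    plate is returned unchanged.
    """
    if any(len(v) == 0 for v in values_by_plate.values()):
        empty = [k for k, v in values_by_plate.items() if len(v) == 0]
        raise NormalizeError(f"plates with no values cannot be normalized: {empty}")
    if len(values_by_plate) < 2:
        return {k: np.asarray(v, dtype=float).copy() for k, v in values_by_plate.items()}
    sizes = {len(v) for v in values_by_plate.values()}
    n_ref = max(sizes)
    grid = np.linspace(0.0, 1.0, n_ref)
    ref = np.mean(
        [np.quantile(np.asarray(v, float), grid) for v in values_by_plate.values()],
        axis=0,
    )
    out = {}
    for plate, v in values_by_plate.items():
        v = np.asarray(v, dtype=float)
        n = len(v)
        # mean rank per value (ties averaged), mapped onto the reference
        pos = (rankdata(v, method="average") - 1.0) / max(n - 1, 1)
        out[plate] = np.interp(pos, grid, ref)
    return out


# ---------------------------------------------------------------------------
# stage driver


def _matched_background(
    cells: pd.DataFrame, plate: str, reporter: str, time_h: float
) -> float:
    """Mean per-cell value over DMSO wells of the same plate/reporter/time."""
    sel = cells[
        (cells["plate"] == plate)
        & (cells["reporter"] == reporter)
        & (cells["time_h"] == time_h)
        & (cells["is_dmso"])
    ]
    if sel.empty:
        raise NormalizeError(
            f"no matched DMSO cells for plate {plate!r} reporter {reporter!r} t={time_h}"
        )
    return float(sel["value"].mean())


def normalize_curves(
    curves: pd.DataFrame,
    df: int = 6,
    n_out: int = N_RESAMPLED,
    scaling: str = "minmax",
    quantile: bool = True,
    common_duration: float | None = None,
    qn_grouping: str = "plate",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full normalization stage on a tidy curve table.

    Order of operations: per plate × reporter × feature min–max scaling
    (``scaling='minmax'``; ``'none'`` skips it — e.g. for GFP-positive
    fractions, which are never scaled), then the 6-df natural-spline
    resampling of every well curve to ``n_out`` equidistant points on the
    common duration (default: the longest observed time across plates),
    then quantile normalization across plates within reporter × feature
    (``qn_grouping='plate'``; ``'plate_well'`` equalizes well-wise instead).

    Returns ``(normalized_curves, fit_info)``; ``fit_info`` has one row per
    curve with the residual sum of squares and observation count of its
    spline regression, consumed by the statistics stage.
    """
    if scaling not in ("minmax", "none"):
        raise NormalizeError("scaling must be 'minmax' or 'none'")
    if qn_grouping not in ("plate", "plate_well"):
        raise NormalizeError("qn_grouping must be 'plate' or 'plate_well'")
    data = curves.copy()
    missing = [c for c in CURVE_COLUMNS if c not in data.columns]
    if missing:
        raise NormalizeError(f"curve table is missing columns: {missing}")
    if scaling == "minmax":
        data["value"] = data.groupby(["plate", "reporter", "feature"])["value"].transform(
            lambda v: minmax_scale(v.to_numpy())
        )
    if common_duration is None:
        common_duration = float(data["time_h"].max())

    fitted_rows = []
    info_rows = []
    for keys, grp in data.groupby(CURVE_KEYS, sort=True):
        grp = grp.sort_values("time_h")
        try:
            t_out, pred, rss, n_obs = fit_resample_curve(
                grp["time_h"].to_numpy(),
                grp["value"].to_numpy(),
                df=df,
                n_out=n_out,
                common_duration=common_duration,
            )
        except NormalizeError as err:
            raise NormalizeError(f"curve {dict(zip(CURVE_KEYS, keys))}: {err}") from err
        meta = dict(zip(CURVE_KEYS, keys))
        fitted_rows.append(pd.DataFrame({**meta, "time_h": t_out, "value": pred}))
        info_rows.append({**meta, "rss": rss, "n_obs": n_obs})
    fitted = pd.concat(fitted_rows, ignore_index=True)[CURVE_COLUMNS]
    fit_info = pd.DataFrame(info_rows)

    if quantile:
        norm_parts = []
        for (rp, feat), grp in fitted.groupby(["reporter", "feature"], sort=True):
            if qn_grouping == "plate":
                pooled = {p: sub["value"].to_numpy() for p, sub in grp.groupby("plate")}
                eq = quantile_normalize(pooled)
                pieces = []
                for p, sub in grp.groupby("plate"):
                    sub = sub.copy()
                    sub["value"] = eq[p]
                    pieces.append(sub)
                norm_parts.append(pd.concat(pieces))
            else:
                pooled = {
                    (p, w): sub["value"].to_numpy()
                    for (p, w), sub in grp.groupby(["plate", "well"])
                }
                eq = quantile_normalize(pooled)
                pieces = []
                for key, sub in grp.groupby(["plate", "well"]):
                    sub = sub.copy()
                    sub["value"] = eq[key]
                    pieces.append(sub)
                norm_parts.append(pd.concat(pieces))
        fitted = pd.concat(norm_parts, ignore_index=True)[CURVE_COLUMNS]
    logger.info(
        "normalized %d curves to %d equidistant points (scaling=%s, quantile=%s)",
        len(fit_info),
        n_out,
        scaling,
        quantile,
    )
    return fitted, fit_info
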