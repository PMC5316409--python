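"""Significance machinery for reporter responses against DMSO controls.

For each reporter rp and resampled time point tp, the replicate-mean DMSO
baseline is

    x̄_DMSO(rp, tp) = (1/repl) Σ_r x_DMSO(rp, tp)

and each treatment replicate's curve is converted to a standardized
difference

    x_diff = (x − x̄_DMSO) / sqrt(σ²_DMSO + σ²_DMSO,resid + σ²_tr + σ²_tr,resid)

where σ_DMSO and σ_tr are the standard deviations over DMSO and treatment
replicates at that time point, and the two residual terms are regression
residual standard errors, σ_resid = sqrt(Σ resid² / (df_tp − 1)) with
df_tp the 24 resampled time points — these carry the raw-data variance
absorbed by the spline fit into the statistic.  The DMSO residual term is
the root mean residual variance over DMSO replicates; the treatment term is
the replicate's own.

The time-average of x_diff (meanDiff) summarizes each replicate, and a
two-sample one-sided Student's t-test (treatment > DMSO; pooled variance by
default) between treatment and matched DMSO meanDiff values gives the
p value, which is multiplied by 2 — compensating the one-sided choice — and
capped at 1.  Stars: * p<0.05, ** p<0.01, *** p<0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .layout import DMSO
from .normalize import N_RESAMPLED

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    """Raised on inputs the statistics stage cannot handle."""


@dataclass
class BaselineTable:
    """DMSO baseline per reporter: per-time-point mean/SD and residual SEs.

    ``per_time`` has columns reporter, time_h, mean, sd; ``resid_se`` has
    one row per DMSO replicate curve with its regression residual standard
    error; ``resid_rms`` maps reporter -> root mean residual variance over
    its DMSO replicates (the σ_DMSO,resid entering every x_diff).
    """

    per_time: pd.DataFrame
    resid_se: pd.DataFrame
    resid_rms: dict[str, float]


def residual_se(rss: float, df_tp: int = N_RESAMPLED) -> float:
    """Regression residual standard error: sqrt(rss / (df_tp - 1))."""
    if df_tp < 2:
        raise StatsError("df_tp must be at least 2")
    return float(np.sqrt(rss / (df_tp - 1)))


def compute_baseline(
    dmso_curves: pd.DataFrame, fit_info: pd.DataFrame, df_tp: int = N_RESAMPLED
) -> BaselineTable:
    """Baseline mean/SD over DMSO replicates and their residual SEs.

    ``dmso_curves`` are normalized DMSO curves (tidy, 24 time points per
    replicate); ``fit_info`` the per-curve regression info from the
    normalization stage.  Requires ≥2 DMSO replicates per reporter (a
    standard deviation over one replicate is undefined).
    """
    per_time_rows = []
    for (rp, tp), grp in dmso_curves.groupby(["reporter", "time_h"], sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise StatsError(
                f"reporter {rp!r} has {len(vals)} DMSO replicate(s) at t={tp}; "
                "need at least 2"
            )
        per_time_rows.append(
            {"reporter": rp, "time_h": tp, "mean": vals.mean(), "sd": vals.std(ddof=1)}
        )
    per_time = pd.DataFrame(per_time_rows)
    dmso_info = fit_info.copy()
    dmso_info["resid_se"] = [residual_se(r, df_tp) for r in dmso_info["rss"]]
    resid_rms = {
        rp: float(np.sqrt(np.mean(grp["resid_se"].to_numpy() ** 2)))
        for rp, grp in dmso_info.groupby("reporter")
    }
    return BaselineTable(per_time=per_time, resid_se=dmso_info, resid_rms=resid_rms)


def diff_statistic(
    values: np.ndarray,
    baseline_mean: np.ndarray,
    sigma_dmso: np.ndarray,
    sigma_dmso_resid: float,
    sigma_tr: np.ndarray,
    sigma_tr_resid: float,
) -> np.ndarray:
    """Standardized difference x_diff at each time point.

    Element-wise over the resampled grid.  Time points where the pooled
    denominator vanishes yield a missing value with a logged warning rather
    than an exception.
    """
    x = np.asarray(values, dtype=float)
    denom = np.sqrt(
        np.asarray(sigma_dmso, float) ** 2
        + float(sigma_dmso_resid) ** 2
        + np.asarray(sigma_tr, float) ** 2
        + float(sigma_tr_resid) ** 2
    )
    out = np.full_like(x, np.nan)
    ok = denom > 0
    if not ok.all():
        logger.warning(
            "x_diff: %d of %d time points have a zero denominator; set to missing",
            int((~ok).sum()),
            len(denom),
        )
    out[ok] = (x[ok] - np.asarray(baseline_mean, float)[ok]) / denom[ok]
    return out


def mean_diff(x_diff: np.ndarray) -> float:
    """Time-average of x_diff, ignoring missing time points."""
    x = np.asarray(x_diff, dtype=float)
    finite = x[~np.isnan(x)]
    if finite.size == 0:
        raise StatsError("meanDiff undefined: all time points are missing")
    dropped = x.size - finite.size
    if dropped:
        logger.info("meanDiff: %d missing time point(s) dropped", dropped)
    return float(finite.mean())


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def significance_test(
    treatment_meandiffs: np.ndarray,
    dmso_meandiffs: np.ndarray,
    variant: str = "pooled",
) -> tuple[float, float, str]:
    """Doubled one-sided two-sample t-test of treatment vs DMSO meanDiffs.

    One-sided alternative "treatment > DMSO" (only positive responses are
    of interest); the one-sided p is multiplied by 2 and capped at 1.
    ``variant`` selects the pooled-variance Student test (default) or
    Welch.  Returns ``(t_statistic, reported_p, stars)``.
    """
    tr = np.asarray(treatment_meandiffs, dtype=float)
    ct = np.asarray(dmso_meandiffs, dtype=float)
    if len(tr) < 2 or len(ct) < 2:
        raise StatsError(
            f"need at least 2 replicates per group (got {len(tr)} treatment, "
            f"{len(ct)} DMSO)"
        )
    if variant not in ("pooled", "welch"):
        raise StatsError("variant must be 'pooled' or 'welch'")
    res = sps.ttest_ind(tr, ct, equal_var=(variant == "pooled"), alternative="greater")
    p = min(1.0, 2.0 * float(res.pvalue))
    return float(res.statistic), p, stars(p)


# ---------------------------------------------------------------------------
# stage driver


def stat_table(
    normalized: pd.DataFrame,
    fit_info: pd.DataFrame,
    variant: str = "pooled",
    df_tp: int = N_RESAMPLED,
    meandiff_on: str = "x_diff",
) -> pd.DataFrame:
    """Per reporter × treatment × concentration significance table.

    DMSO wells (treatment ``DMSO``) provide the baseline; every other
    (treatment, concentration) group is scored against it.  DMSO replicates
    themselves are pushed through the same x_diff/meanDiff computation to
    provide the matched control group of the t-test.  ``meandiff_on``
    selects whether meanDiff averages the standardized difference
    (``'x_diff'``, default) or the raw normalized values (``'raw'``).
    """
    if meandiff_on not in ("x_diff", "raw"):
        raise StatsError("meandiff_on must be 'x_diff' or 'raw'")
    if normalized[normalized["treatment"] == DMSO].empty:
        raise StatsError("no DMSO control curves in the normalized table")

    def _meandiffs(
        group: pd.DataFrame, rp: str, info: pd.DataFrame, baseline: BaselineTable
    ) -> list[float]:
        """meanDiff per replicate of one (reporter, treatment, conc) group."""
        base = baseline.per_time[baseline.per_time["reporter"] == rp].sort_values("time_h")
        wide = group.pivot_table(
            index="time_h", columns="replicate", values="value", sort=True
        )
        sigma_tr = wide.std(axis=1, ddof=1).to_numpy()
        out = []
        for repl in wide.columns:
            sub_info = info[info["replicate"] == repl]
            if sub_info.empty:
                raise StatsError(f"no regression info for replicate {repl}")
            se_tr = residual_se(float(sub_info["rss"].iloc[0]), df_tp)
            if meandiff_on == "x_diff":
                xd = diff_statistic(
                    wide[repl].to_numpy(),
                    base["mean"].to_numpy(),
                    base["sd"].to_numpy(),
                    baseline.resid_rms[rp],
                    sigma_tr,
                    se_tr,
                )
                out.append(mean_diff(xd))
            else:
                out.append(mean_diff(wide[repl].to_numpy()))
        return out

    rows = []
    for (rp, feat), rp_grp in normalized.groupby(["reporter", "feature"], sort=True):
        dmso_grp = rp_grp[rp_grp["treatment"] == DMSO]
        if dmso_grp.empty:
            raise StatsError(f"reporter {rp!r} feature {feat!r} has no DMSO curves")
        dmso_info = fit_info[
            (fit_info["treatment"] == DMSO)
            & (fit_info["reporter"] == rp)
            & (fit_info["feature"] == feat)
        ]
        baseline = compute_baseline(dmso_grp, dmso_info, df_tp=df_tp)
        dmso_md = _meandiffs(dmso_grp, rp, dmso_info, baseline)
        for (tr, conc), grp in rp_grp[rp_grp["treatment"] != DMSO].groupby(
            ["treatment", "concentration"], sort=True
        ):
            info = fit_info[
                (fit_info["reporter"] == rp)
                & (fit_info["feature"] == feat)
                & (fit_info["treatment"] == tr)
                & (fit_info["concentration"] == conc)
            ]
            md = _meandiffs(grp, rp, info, baseline)
            t_stat, p, sig = significance_test(md, dmso_md, variant=variant)
            row = {
                "reporter": rp,
                "feature": feat,
                "treatment": tr,
                "concentration": conc,
                "n_replicates": len(md),
                "t_statistic": t_stat,
                "p_value": p,
                "significance": sig,
            }
            for i, v in enumerate(md, start=1):
                row[f"meanDiff_r{i}"] = v
            rows.append(row)
    out = pd.DataFrame(rows)
    logger.info("stat_table: %d reporter × treatment × concentration rows", len(out))
    return out
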