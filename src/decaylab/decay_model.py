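"""Gene-wise exponential-decay fitting by log-linear (mixed) regression.

Under first-order kinetics, C(t) = C_first · exp(-kd·dT), so the log of
the decay-factor-normalized fractional abundance is linear in time with
slope -kd, and t1/2 = ln2 / kd.  Each gene × condition series is fitted
with time (minutes since the first harvest) as a fixed effect and, when
the design has ≥2 batches, a random intercept per experimental batch
(statsmodels MixedLM, REML).  Degenerate random-effect variance falls
back to ordinary least squares, recorded in ``fit_method``.

Model vetting: the Wald t-test on the time coefficient (residual
degrees of freedom), the conditional R² by the variance-partition
formula (fixed + random) / (fixed + random + residual), and the
kinetic filters kd > 0 and t1/2 ≤ 1440 min (one day).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("decaylab")

__all__ = [
    "DecayFit",
    "SensitivityReport",
    "fit_decay",
    "fit_all",
    "adjust_pvalues",
    "timepoint_sensitivity",
]

FIT_COLUMNS = [
    "gene_id", "condition", "kd", "halflife_min", "slope_se",
    "conditional_r2", "f_stat", "p_value", "p_adj", "n_obs",
    "fit_method", "passed_filters", "fail_reason",
]


@dataclass
class DecayFit:
    """Per-gene, per-condition decay parameters and fit diagnostics."""

    gene_id: str
    condition: str
    kd: float = np.nan
    halflife_min: float = np.nan
    slope_se: float = np.nan
    conditional_r2: float = np.nan
    f_stat: float = np.nan
    p_value: float = np.nan
    p_adj: float = np.nan
    n_obs: int = 0
    fit_method: str = "none"
    passed_filters: bool = False
    fail_reason: str = ""


@dataclass
class SensitivityReport:
    """Comparison of full vs timepoint-omitted half-life estimates."""

    omitted_timepoints: Tuple[float, ...]
    n_modelled_full: int
    n_modelled_omitted: int
    n_common: int
    pearson_r: float
    r_squared: float


# ---------------------------------------------------------------------------
# single-series fit
# ---------------------------------------------------------------------------

def _ols_line(x: np.ndarray, y: np.ndarray):
    """Closed-form simple linear regression; returns slope, se, r2, df."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    df = n - 2
    s2 = float((resid**2).sum()) / df if df > 0 else np.nan
    se = np.sqrt(s2 / sxx)
    sst = float(((y - ym) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 1.0
    return slope, se, r2, df


def _fit_mixed(x: np.ndarray, y: np.ndarray, batch: np.ndarray):
    """Random-intercept-per-batch fit; returns None on failure/singularity."""
    import statsmodels.api as sm

    exog = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, exog, groups=batch)
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        except Exception:
            return None
    var_r = float(np.asarray(res.cov_re).ravel()[0])
    var_e = float(res.scale)
    if not np.isfinite(var_r) or not np.isfinite(var_e) or var_r <= 1e-10 * max(var_e, 1e-12):
        return None  # singular random effect -> caller falls back to OLS
    slope = float(res.params[1])
    se = float(res.bse[1])
    var_f = float(np.var(slope * x))
    r2c = (var_f + var_r) / (var_f + var_r + var_e)
    return slope, se, r2c


def fit_decay(
    values: Sequence[float],
    timepoints_min: Sequence[float],
    batches: Optional[Sequence] = None,
    gene_id: str = "",
    condition: str = "",
    alpha: float = 0.05,
    max_halflife: float = 1440.0,
    max_zero_frac: float = 0.5,
) -> DecayFit:
    """Fit one gene × condition series of normalized fractional
    abundances observed at ``timepoints_min`` (absolute minutes; the
    series' first timepoint is the time origin).

    Zero observations are dropped from the log response; a series with
    more than ``max_zero_frac`` zeros is skipped (reason ``sparse``), and
    fewer than 3 usable points or fewer than 2 distinct timepoints skips
    the fit (reason ``too_few_points``).
    """
    v = np.asarray(values, float)
    t = np.asarray(timepoints_min, float)
    fit = DecayFit(gene_id=gene_id, condition=condition)
    if len(v) and (v <= 0).mean() > max_zero_frac:
        fit.fail_reason = "sparse"
        return fit
    ok = v > 0
    v, t = v[ok], t[ok]
    b = np.asarray(batches)[ok] if batches is not None else None
    if len(v) < 3 or len(np.unique(t)) < 2:
        fit.fail_reason = "too_few_points"
        return fit

    x = t - t.min()
    y = np.log(v)
    fit.n_obs = len(y)

    mixed = None
    if b is not None and len(np.unique(b)) >= 2:
        mixed = _fit_mixed(x, y, b)
    if mixed is not None:
        slope, se, r2 = mixed
        fit.fit_method = "mixed"
    else:
        slope, se, r2, _ = _ols_line(x, y)
        fit.fit_method = "ols"
    df = fit.n_obs - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = slope / se if se > 0 else np.inf * np.sign(slope or 1)
    p = 2.0 * stats.t.sf(abs(tval), df) if df > 0 else np.nan
    p = min(max(float(p), np.finfo(float).tiny), 1.0)

    fit.kd = -slope
    fit.halflife_min = np.log(2.0) / fit.kd if fit.kd > 0 else np.inf
    fit.slope_se = se
    fit.conditional_r2 = float(np.clip(r2, 0.0, 1.0))
    fit.f_stat = float(tval**2)
    fit.p_value = p
    fit.passed_filters = bool(
        (p < alpha) and (fit.kd > 0) and (fit.halflife_min <= max_halflife)
    )
    if not fit.passed_filters:
        if not p < alpha:
            fit.fail_reason = "not_significant"
        elif not fit.kd > 0:
            fit.fail_reason = "negative_kd"
        else:
            fit.fail_reason = "halflife_gt_max"
    return fit


# ---------------------------------------------------------------------------
# table-level fitting
# ---------------------------------------------------------------------------

def fit_all(
    fractional,
    alpha: float = 0.05,
    max_halflife: float = 1440.0,
    conditions: Optional[Iterable[str]] = None,
    omit_timepoints: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Fit every gene in every condition of a
    :class:`~decaylab.decay_normalization.FractionalAbundance`;
    one row per (gene, condition), with per-gene failures recorded in
    ``fail_reason`` rather than raised.
    """
    sheet = fractional.sheet
    conditions = list(conditions) if conditions else list(sheet["condition"].unique())
    omit = {float(t) for t in (omit_timepoints or [])}
    rows = []
    for cond in conditions:
        ids = sheet.index[sheet["condition"] == cond]
        sub_sheet = sheet.loc[ids]
        if omit:
            keep_ids = sub_sheet.index[
                ~sub_sheet["timepoint_min"].astype(float).isin(omit)
            ]
            sub_sheet = sub_sheet.loc[keep_ids]
        if sub_sheet["timepoint_min"].nunique() < 2:
            raise ValueError(
                f"condition {cond}: fewer than 2 timepoints remain after omission"
            )
        tvec = sub_sheet["timepoint_min"].to_numpy(float)
        bvec = sub_sheet["batch"].to_numpy()
        mat = fractional.values[list(sub_sheet.index)].to_numpy(float)
        for i, gene in enumerate(fractional.values.index):
            rows.append(
                fit_decay(mat[i], tvec, bvec, gene_id=gene, condition=cond,
                          alpha=alpha, max_halflife=max_halflife)
            )
    table = pd.DataFrame([f.__dict__ for f in rows])[FIT_COLUMNS]
    for cond in conditions:
        sub = table[table["condition"] == cond]
        logger.info(
            "fit_all[%s]: %d genes, %d fitted, %d passed filters (%s)",
            cond, len(sub), int((sub["fit_method"] != "none").sum()),
            int(sub["passed_filters"].sum()),
            ", ".join(f"{k}={v}" for k, v in
                      sub["fail_reason"].value_counts().items() if k),
        )
    return table


def adjust_pvalues(fits: pd.DataFrame, method: str = "fdr_bh") -> pd.DataFrame:
    """Benjamini–Hochberg (or other statsmodels method) adjustment of the
    per-gene model p-values; returns a copy with ``p_adj`` filled."""
    from statsmodels.stats.multitest import multipletests

    if fits.empty:
        raise ValueError("empty fit table")
    out = fits.copy()
    mask = out["p_value"].notna()
    if mask.any():
        out.loc[mask, "p_adj"] = multipletests(
            out.loc[mask, "p_value"].to_numpy(), method=method
        )[1]
    return out


# ---------------------------------------------------------------------------
# timepoint-omission sensitivity
# ---------------------------------------------------------------------------

def timepoint_sensitivity(
    fractional,
    omit: Sequence[float],
    alpha: float = 0.05,
    max_halflife: float = 1440.0,
    conditions: Optional[Iterable[str]] = None,
) -> SensitivityReport:
    """Refit the course with the given timepoints omitted and compare
    half-lives of genes modelled (passing all filters) in both designs.

    Correlation is computed on log2 half-lives, one value per
    (gene, condition) pair present in both fits.
    """
    full = fit_all(fractional, alpha=alpha, max_halflife=max_halflife,
                   conditions=conditions)
    omitted = fit_all(fractional, alpha=alpha, max_halflife=max_halflife,
                      conditions=conditions, omit_timepoints=omit)
    fp = full[full["passed_filters"]].set_index(["gene_id", "condition"])
    op = omitted[omitted["passed_filters"]].set_index(["gene_id", "condition"])
    common = fp.index.intersection(op.index)
    if len(common) >= 3:
        a = np.log2(fp.loc[common, "halflife_min"].to_numpy(float))
        b = np.log2(op.loc[common, "halflife_min"].to_numpy(float))
        if np.std(a) > 0 and np.std(b) > 0:
            r = float(np.corrcoef(a, b)[0, 1])
        else:
            r = 1.0 if np.allclose(a, b) else np.nan
    else:
        r = np.nan
    return SensitivityReport(
        omitted_timepoints=tuple(float(t) for t in omit),
        n_modelled_full=len(fp),
        n_modelled_omitted=len(op),
        n_common=len(common),
        pearson_r=r,
        r_squared=r**2 if np.isfinite(r) else np.nan,
    )
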