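"""Relative polysome loading (RPL) and translation-state analysis.

RPL is the per-gene ratio of polysome-associated to total mRNA
abundance (RPKM or any library-size-scaled unit), a proxy for
translational propensity: RPL = 1 means the transcript is represented
in the polysomal pool proportionally to its total abundance.

This module computes per-replicate RPL, classifies genes on the
3 × 3 fold-change grid (total mRNA × RPL, up/unchanged/down at a
1.5-fold threshold), assigns stress-induced genes to rapid-recovery
downregulation (RRGD) categories by when their induced mRNA declines,
compares RPL fold changes between categories with rank-sum tests, and
provides the percent-attenuation arithmetic used for inhibitor-efficacy
qPCR summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .abundance_io import AbundanceMatrix

logger = logging.getLogger("decaylab")

__all__ = [
    "RPLTable",
    "QuadrantSummary",
    "compute_rpl",
    "fold_changes",
    "quadrant_classify",
    "rrgd_classify",
    "category_rpl_shift",
    "attenuation_percent",
    "correlate_fold_changes",
]

FC_LEVELS = ("up", "unchanged", "down")
# pseudocount on the denominator abundance scale when forming fold changes
FC_PSEUDOCOUNT = 0.01


@dataclass
class QuadrantSummary:
    """Proportions over the 3×3 grid of total-mRNA FC × RPL FC calls."""

    period: str
    proportions: pd.DataFrame  # index: total FC level, columns: RPL FC level
    frac_changed_total: float
    frac_changed_rpl: float
    ratio_rpl_to_total: float
    n_genes: int

    @property
    def ratio_str(self) -> str:
        return f"{self.ratio_rpl_to_total:.1f}:1"


RPLTable = pd.DataFrame  # columns: gene_id, condition, timepoint_min, replicate, rpl


def compute_rpl(
    total: AbundanceMatrix,
    polysome: AbundanceMatrix,
    total_sheet: pd.DataFrame,
    polysome_sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Per-replicate RPL records, pairing samples on
    (condition, timepoint, replicate).

    Genes with zero total abundance in a replicate are omitted for that
    replicate (RPL undefined).  Unpairable samples raise an error that
    lists them.
    """
    key_cols = ["condition", "timepoint_min", "replicate"]
    tkeys = {tuple(r): s for s, r in total_sheet[key_cols].iterrows()}
    pkeys = {tuple(r): s for s, r in polysome_sheet[key_cols].iterrows()}
    only_t = sorted(set(tkeys) - set(pkeys))
    only_p = sorted(set(pkeys) - set(tkeys))
    if only_t or only_p:
        raise ValueError(
            "unpairable samples; total-only keys: "
            f"{only_t[:5]}; polysome-only keys: {only_p[:5]}"
        )
    genes = total.values.index.intersection(polysome.values.index)
    records = []
    for key in tkeys:
        cond, t, rep = key
        tv = total.values.loc[genes, tkeys[key]]
        pv = polysome.values.loc[genes, pkeys[key]]
        ok = tv > 0
        rpl = pv[ok] / tv[ok]
        records.append(pd.DataFrame({
            "gene_id": rpl.index,
            "condition": cond,
            "timepoint_min": float(t),
            "replicate": rep,
            "rpl": rpl.to_numpy(float),
        }))
    return pd.concat(records, ignore_index=True)


def fold_changes(
    abundance: AbundanceMatrix,
    sheet: pd.DataFrame,
    numerator: Tuple[str, float],
    denominator: Tuple[str, float],
    pseudocount: float = FC_PSEUDOCOUNT,
) -> pd.Series:
    """Per-gene fold change of replicate-mean abundance between two
    (condition, timepoint) states, with a pseudocount on the
    denominator scale to avoid division by zero."""
    def _mean(state):
        cond, t = state
        ids = sheet.index[(sheet["condition"] == cond)
                          & (np.isclose(sheet["timepoint_min"].astype(float), float(t)))]
        if len(ids) == 0:
            raise ValueError(f"no samples for state {state}")
        return abundance.values[list(ids)].mean(axis=1)

    num, den = _mean(numerator), _mean(denominator)
    return (num + pseudocount) / (den + pseudocount)


def rpl_fold_changes(
    rpl: pd.DataFrame,
    numerator: Tuple[str, float],
    denominator: Tuple[str, float],
    pseudocount: float = FC_PSEUDOCOUNT,
) -> pd.Series:
    """Per-gene fold change of replicate-mean RPL between two states."""
    def _mean(state):
        cond, t = state
        sub = rpl[(rpl["condition"] == cond)
                  & (np.isclose(rpl["timepoint_min"].astype(float), float(t)))]
        if sub.empty:
            raise ValueError(f"no RPL records for state {state}")
        return sub.groupby("gene_id")["rpl"].mean()

    num, den = _mean(numerator), _mean(denominator)
    common = num.index.intersection(den.index)
    return (num.loc[common] + pseudocount) / (den.loc[common] + pseudocount)


def _fc_level(fc: np.ndarray, threshold: float) -> np.ndarray:
    return np.where(fc >= threshold, "up",
                    np.where(fc <= 1.0 / threshold, "down", "unchanged"))


def quadrant_classify(
    fc_total: pd.Series,
    fc_rpl: pd.Series,
    threshold: float = 1.5,
    period: str = "",
) -> QuadrantSummary:
    """Assign each gene to the 3×3 grid of total-mRNA × RPL fold-change
    calls (up: FC ≥ threshold; down: FC ≤ 1/threshold) and summarise the
    grid proportions, the changed marginals and their ratio."""
    common = fc_total.index.intersection(fc_rpl.index)
    ft = fc_total.loc[common].astype(float)
    fr = fc_rpl.loc[common].astype(float)
    ok = np.isfinite(ft) & np.isfinite(fr)
    ft, fr = ft[ok], fr[ok]
    lt = _fc_level(ft.to_numpy(), threshold)
    lr = _fc_level(fr.to_numpy(), threshold)
    grid = pd.DataFrame(0.0, index=list(FC_LEVELS), columns=list(FC_LEVELS))
    for a in FC_LEVELS:
        for b in FC_LEVELS:
            grid.loc[a, b] = float(np.mean((lt == a) & (lr == b)))
    frac_total = float(np.mean(lt != "unchanged"))
    frac_rpl = float(np.mean(lr != "unchanged"))
    ratio = frac_rpl / frac_total if frac_total > 0 else np.inf
    return QuadrantSummary(
        period=period, proportions=grid,
        frac_changed_total=frac_total, frac_changed_rpl=frac_rpl,
        ratio_rpl_to_total=float(round(ratio, 1)), n_genes=int(ok.sum()),
    )


# ---------------------------------------------------------------------------
# RRGD categories
# ---------------------------------------------------------------------------

def rrgd_classify(
    total_series: pd.DataFrame,
    induction_threshold: float = 3.0,
    decline_threshold: float = 1.5,
    pseudocount: float = FC_PSEUDOCOUNT,
) -> pd.Series:
    """Assign RRGD categories from a per-gene total-mRNA time course.

    ``total_series`` is a gene × state matrix with MultiIndex columns
    (condition, timepoint_min) containing at least (HL, 0), (HL, 30),
    (HL, 60) and one REC timepoint.  Genes induced ≥
    ``induction_threshold``-fold at 30 min HL are RRGD; among those,
    genes declining ≥ ``decline_threshold``-fold from 30 to 60 min HL
    are category 3, genes declining only between 60 min HL and the last
    REC timepoint are category 2, and the rest remain up (category 1).
    """
    cols = {(c, float(t)) for c, t in total_series.columns}
    needed = {("HL", 0.0), ("HL", 30.0), ("HL", 60.0)}
    rec_tps = sorted(t for c, t in cols if c == "REC")
    if not needed <= cols or not rec_tps:
        raise ValueError(
            "rrgd_classify needs HL timepoints 0/30/60 min and >=1 REC "
            f"timepoint; got {sorted(cols)}"
        )
    a = total_series.astype(float) + pseudocount
    fc30 = a[("HL", 30.0)] / a[("HL", 0.0)]
    fc_30_60 = a[("HL", 60.0)] / a[("HL", 30.0)]
    fc_rec = a[("REC", rec_tps[-1])] / a[("HL", 60.0)]
    out = pd.Series("none", index=total_series.index, name="rrgd_category")
    rrgd = fc30 >= induction_threshold
    down = 1.0 / decline_threshold
    out[rrgd & (fc_30_60 <= down)] = "cat3"
    out[rrgd & (fc_30_60 > down) & (fc_rec <= down)] = "cat2"
    out[rrgd & (fc_30_60 > down) & (fc_rec > down)] = "cat1"
    return out


def ranksum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum p-value: exact enumeration for small samples
    (n < 8), tie-corrected normal approximation otherwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if min(x.size, y.size) < 8:
        pooled = np.concatenate([x, y])
        if np.unique(pooled).size == pooled.size:  # no ties: exact U distribution
            return float(stats.mannwhitneyu(x, y, method="exact").pvalue)
        res = stats.permutation_test(
            (x, y),
            lambda a, b: stats.mannwhitneyu(a, b, method="asymptotic").statistic,
            permutation_type="independent", n_resamples=100_000, random_state=0,
        )
        return float(res.pvalue)
    return float(stats.mannwhitneyu(x, y, method="asymptotic").pvalue)


def category_rpl_shift(
    rpl_fc: pd.Series,
    categories: pd.Series,
    groups: Optional[Sequence[str]] = None,
    min_group: int = 2,
) -> pd.DataFrame:
    """Median RPL fold change per RRGD category plus pairwise two-sided
    rank-sum p-values between categories.

    Returns one row per ordered category pair with both group medians,
    sizes and the p-value (NaN, flagged ``skipped``, when a group is
    smaller than ``min_group``).
    """
    common = rpl_fc.index.intersection(categories.index)
    fc = rpl_fc.loc[common].astype(float)
    cat = categories.loc[common]
    groups = list(groups) if groups else sorted(cat.unique())
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            va = fc[cat == ga].to_numpy()
            vb = fc[cat == gb].to_numpy()
            skipped = min(va.size, vb.size) < min_group
            rows.append({
                "group_a": ga, "group_b": gb,
                "n_a": va.size, "n_b": vb.size,
                "median_a": float(np.median(va)) if va.size else np.nan,
                "median_b": float(np.median(vb)) if vb.size else np.nan,
                "p_value": np.nan if skipped else ranksum_test(va, vb),
                "skipped": skipped,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inhibitor-efficacy arithmetic
# ---------------------------------------------------------------------------

def attenuation_percent(fc_control: float, fc_treated: float,
                        digits: Optional[int] = 1) -> float:
    """Percent attenuation of an induction response under an inhibitor:
    100 × (1 − fc_treated / fc_control).  ``digits=None`` skips
    rounding; ``digits=0`` gives the nearest-integer convention."""
    if fc_control <= 0:
        raise ValueError("fc_control must be positive")
    pct = 100.0 * (1.0 - fc_treated / fc_control)
    return float(round(pct, digits)) if digits is not None else float(pct)


def correlate_fold_changes(fc_a: pd.Series, fc_b: pd.Series) -> float:
    """Pearson correlation of log2 fold changes over genes finite and
    positive in both series; NaN when undefined (zero variance)."""
    common = fc_a.index.intersection(fc_b.index)
    a = fc_a.loc[common].astype(float)
    b = fc_b.loc[common].astype(float)
    ok = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
    if ok.sum() < 3:
        raise ValueError("need >= 3 genes with finite positive fold changes")
    la, lb = np.log2(a[ok]), np.log2(b[ok])
    if np.std(la) == 0 or np.std(lb) == 0:
        logger.warning("correlate_fold_changes: zero variance; r undefined")
        return float("nan")
    return float(np.corrcoef(la, lb)[0, 1])
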