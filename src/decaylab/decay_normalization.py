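"""Decay-factor normalization of transcription-inhibition time courses.

When transcription is inhibited, the total mRNA pool shrinks while
sequencing measures only *relative* abundance, so stable transcripts
appear induced.  The correction used here: pick reference genes that are
highly expressed and low-variance across mock-treated samples, take
their mean fold increase at each (condition, timepoint) of the
inhibitor-treated samples as the pool-shrinkage factor, and divide the
per-gene fractional decreases by that factor.

Fractional abundance of gene g in sample s is
``C(g,s) / mean C(g, first timepoint of the condition)``; after dividing
by the decay factor, a perfectly stable gene sits at 1 at every
timepoint and a first-order decaying gene follows exp(-kd·dT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .abundance_io import AbundanceMatrix

logger = logging.getLogger("decaylab")

__all__ = [
    "NormalizationFactors",
    "FractionalAbundance",
    "select_reference_genes",
    "compute_decay_factors",
    "normalize_fractional",
    "exclude_induced",
]


@dataclass
class NormalizationFactors:
    """Per-(condition, timepoint) decay factors.

    ``table`` columns: condition, timepoint_min, factor.  The factor at
    the first timepoint of each condition is 1 by construction.
    """

    table: pd.DataFrame
    reference_genes: List[str]

    def factor(self, condition: str, timepoint_min: float) -> float:
        t = self.table
        row = t[(t["condition"] == condition)
                & (np.isclose(t["timepoint_min"].astype(float), float(timepoint_min)))]
        if row.empty:
            raise KeyError(f"no decay factor for ({condition}, {timepoint_min})")
        return float(row["factor"].iloc[0])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class FractionalAbundance:
    """Normalized C/C_first ratios over inhibitor-treated samples.

    ``values``: gene × sample matrix of decay-factor-normalized
    fractional abundances; ``sheet``: the matching sample-sheet rows;
    ``baseline``: per-gene replicate-mean abundance at the first
    timepoint, per condition (genes with zero baseline are dropped).
    """

    values: pd.DataFrame
    sheet: pd.DataFrame
    baseline: pd.DataFrame  # genes × conditions

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def condition_slice(self, condition: str) -> Tuple[pd.DataFrame, pd.DataFrame]:
        ids = self.sheet.index[self.sheet["condition"] == condition]
        return self.values[list(ids)], self.sheet.loc[ids]


# ---------------------------------------------------------------------------

def select_reference_genes(
    mock_abundance: AbundanceMatrix,
    abundance_pct: float = 95.0,
    cv_pct: float = 25.0,
) -> List[str]:
    """Reference genes: mean log2(CPM + 0.01) at or above the
    ``abundance_pct`` percentile AND coefficient of variation of CPM at
    or below the ``cv_pct`` percentile, across mock-treated samples.

    Percentiles use linear-interpolation quantiles; genes tied with the
    boundary value are retained.
    """
    vals = mock_abundance.values
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 mock samples to compute a CV")
    log_ab = np.log2(vals + 0.01).mean(axis=1)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)
    cv = pd.Series(cv, index=vals.index)
    ab_thresh = np.percentile(log_ab, abundance_pct)
    cv_thresh = np.percentile(cv[np.isfinite(cv)], cv_pct)
    keep = (log_ab >= ab_thresh) & (cv <= cv_thresh)
    refs = list(vals.index[keep])
    if not refs:
        raise ValueError(
            "no gene passed both the abundance and CV cuts; "
            f"relax abundance_pct (now {abundance_pct}) or cv_pct (now {cv_pct})"
        )
    logger.info("selected %d reference genes (abundance>=p%g, CV<=p%g)",
                len(refs), abundance_pct, cv_pct)
    return refs


def _mean_abundance_by_timepoint(vals: pd.DataFrame, sheet: pd.DataFrame):
    """Replicate-mean abundance per (condition, timepoint)."""
    out = {}
    for (cond, t), ids in sheet.groupby(["condition", "timepoint_min"]).groups.items():
        out[(cond, float(t))] = vals[list(ids)].mean(axis=1)
    return out


def compute_decay_factors(
    cord_abundance: AbundanceMatrix,
    refs: Sequence[str],
    sheet: pd.DataFrame,
    geometric: bool = False,
) -> NormalizationFactors:
    """Mean fold increase of the reference genes at each (condition,
    timepoint) of the inhibitor-treated samples, relative to the first
    timepoint of that condition.  ``geometric=True`` swaps the
    arithmetic mean across reference genes for a geometric one.
    """
    refs = list(refs)
    if not refs:
        raise ValueError("reference gene list is empty")
    missing = [g for g in refs if g not in cord_abundance.values.index]
    if missing:
        raise ValueError(f"reference genes absent from matrix: {missing[:5]}")
    vals = cord_abundance.values.loc[refs]
    sheet = sheet.loc[[s for s in sheet.index if s in vals.columns]]
    means = _mean_abundance_by_timepoint(vals, sheet)

    rows = []
    for cond in sheet["condition"].unique():
        tps = sorted({float(t) for c, t in means if c == cond})
        t_first = tps[0]
        base = means[(cond, t_first)]
        if (base <= 0).any():
            raise ValueError("reference gene with zero abundance at first timepoint")
        for t in tps:
            fold = means[(cond, t)] / base
            factor = float(np.exp(np.log(fold).mean())) if geometric else float(fold.mean())
            rows.append((cond, t, factor))
    table = pd.DataFrame(rows, columns=["condition", "timepoint_min", "factor"])
    return NormalizationFactors(table=table, reference_genes=refs)


def normalize_fractional(
    cord_abundance: AbundanceMatrix,
    factors: NormalizationFactors,
    sheet: pd.DataFrame,
) -> FractionalAbundance:
    """Fractional abundances divided by the decay factor of their
    (condition, timepoint).

    The per-gene baseline is the replicate-mean abundance at the first
    timepoint of each condition; genes with zero baseline in any
    analysed condition are dropped (their count is logged).
    """
    vals = cord_abundance.values
    sheet = sheet.loc[[s for s in sheet.index if s in vals.columns]]
    means = _mean_abundance_by_timepoint(vals, sheet)

    conditions = list(sheet["condition"].unique())
    baseline = pd.DataFrame(index=vals.index, columns=conditions, dtype=float)
    for cond in conditions:
        tps = sorted({float(t) for c, t in means if c == cond})
        baseline[cond] = means[(cond, tps[0])]
    keep = (baseline > 0).all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("normalize_fractional: dropped %d genes with zero baseline", n_drop)
    vals = vals.loc[keep]
    baseline = baseline.loc[keep]

    out = pd.DataFrame(index=vals.index, columns=sheet.index, dtype=float)
    for sid, row in sheet.iterrows():
        cond, t = row["condition"], float(row["timepoint_min"])
        f = factors.factor(cond, t)
        out[sid] = vals[sid] / baseline[cond] / f
    return FractionalAbundance(values=out, sheet=sheet, baseline=baseline)


def exclude_induced(
    fractional: FractionalAbundance,
    threshold: float = 1.5,
) -> Tuple[FractionalAbundance, pd.DataFrame]:
    """Drop genes still showing a normalized fold increase ≥ ``threshold``
    at any post-baseline timepoint (replicate-mean per timepoint), i.e.
    residual induction that decay-factor normalization did not remove.

    Returns the retained FractionalAbundance and an exclusion report
    (gene, condition, timepoint, mean normalized value) for the dropped
    genes.
    """
    vals, sheet = fractional.values, fractional.sheet
    means = _mean_abundance_by_timepoint(vals, sheet)
    first_tp = {c: min(float(t) for cc, t in means if cc == c)
                for c in sheet["condition"].unique()}
    excluded = {}
    for (cond, t), m in means.items():
        if t == first_tp[cond]:
            continue
        hits = m[m >= threshold]
        for g, v in hits.items():
            excluded.setdefault(g, []).append((cond, t, float(v)))
    report = pd.DataFrame(
        [(g, c, t, v) for g, lst in excluded.items() for c, t, v in lst],
        columns=["gene_id", "condition", "timepoint_min", "mean_normalized"],
    )
    keep = [g for g in vals.index if g not in excluded]
    logger.info("exclude_induced: removed %d genes (fold >= %g), %d retained",
                len(excluded), threshold, len(keep))
    kept = FractionalAbundance(
        values=vals.loc[keep], sheet=sheet, baseline=fractional.baseline.loc[keep]
    )
    return kept, report
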