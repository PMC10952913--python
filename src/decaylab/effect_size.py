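"""Paired estimation statistics for half-life contrasts.

Instead of hypothesis tests, condition contrasts (e.g. high light vs
unstressed) are summarised by effect sizes over gene-aligned half-life
vectors: the paired mean difference θ, the paired median difference
μ1/2, and Cliff's delta δ (the probability that a value from one group
exceeds one from the other, minus the reverse), each with a bootstrap
confidence interval obtained by resampling gene pairs jointly.

Also here: the rule-based destabilised/stabilised classification (a
gene is destabilised when its half-life drop exceeds the median
difference across transcripts in magnitude) and the cross-study
comparison collating genes consistently less stable than in external
half-life datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("decaylab")

__all__ = [
    "EffectSizeResult",
    "cliffs_delta",
    "paired_difference",
    "bootstrap_effect",
    "classify_stability",
    "cross_study_compare",
]

STATISTICS = ("mean_diff", "median_diff", "cliffs_delta")


@dataclass
class EffectSizeResult:
    statistic: str
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_pairs: int
    seed: Optional[int] = None


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """δ = [#(x_i > y_j) − #(x_i < y_j)] / (|x|·|y|); ties contribute 0.

    Computed via the rank-sum identity δ = 2·U1/(n·m) − 1 (with the
    midrank convention, tied pairs count one half), which is O((n+m)
    log(n+m)) rather than O(n·m).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires non-empty inputs")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    return float(2.0 * u1 / (x.size * y.size) - 1.0)


def paired_difference(x: Sequence[float], y: Sequence[float],
                      statistic: str = "mean_diff") -> float:
    """Paired mean or median of x − y over gene-aligned vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    d = x - y
    if statistic == "mean_diff":
        return float(d.mean())
    if statistic == "median_diff":
        return float(np.median(d))
    raise ValueError(f"unknown statistic {statistic!r}")


def _statistic(x: np.ndarray, y: np.ndarray, statistic: str) -> float:
    if statistic == "cliffs_delta":
        return cliffs_delta(x, y)
    return paired_difference(x, y, statistic)


def bootstrap_effect(
    x: Sequence[float],
    y: Sequence[float],
    statistic: str = "median_diff",
    n_boot: int = 10_000,
    ci: float = 0.95,
    seed: Optional[int] = None,
) -> EffectSizeResult:
    """Point estimate on the original pairing plus a percentile bootstrap
    CI from ``n_boot`` resamples of gene pairs (drawn jointly, keeping
    the pairing intact)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 5:
        raise ValueError("bootstrap_effect requires at least 5 pairs")
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    est = _statistic(x, y, statistic)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    if statistic == "cliffs_delta":
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            boots[b] = cliffs_delta(x[idx], y[idx])
    else:
        idx = rng.integers(0, n, (n_boot, n))
        d = (x - y)[idx]
        boots = d.mean(axis=1) if statistic == "mean_diff" else np.median(d, axis=1)
    lo, hi = np.quantile(boots, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return EffectSizeResult(
        statistic=statistic, estimate=est, ci_low=float(lo), ci_high=float(hi),
        n_boot=n_boot, n_pairs=n, seed=seed,
    )


# ---------------------------------------------------------------------------
# stability classification
# ---------------------------------------------------------------------------

def classify_stability(
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
    contrast: str = "A_vs_B",
) -> pd.DataFrame:
    """Call each common gene destabilised / stabilised / unchanged in
    condition A relative to B.

    Both tables are restricted to filter-passing fits; the threshold is
    the absolute median of the paired half-life differences (a − b, in
    minutes), and calls are strict: a gene is destabilised only when its
    drop exceeds the threshold in magnitude (boundary ties → unchanged).
    """
    a = fits_a[fits_a["passed_filters"]].set_index("gene_id")["halflife_min"]
    b = fits_b[fits_b["passed_filters"]].set_index("gene_id")["halflife_min"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no common filter-passing genes between the two fits")
    d = (a.loc[common] - b.loc[common]).astype(float)
    threshold = abs(float(np.median(d)))
    call = np.where(d < -threshold, "destabilised",
                    np.where(d > threshold, "stabilised", "unchanged"))
    out = pd.DataFrame({
        "gene_id": common,
        "contrast": contrast,
        "delta_halflife_min": d.to_numpy(),
        "call": call,
    })
    logger.info("classify_stability[%s]: threshold %.3g min; %d destabilised, "
                "%d stabilised, %d unchanged", contrast, threshold,
                (call == "destabilised").sum(), (call == "stabilised").sum(),
                (call == "unchanged").sum())
    out.attrs["threshold_min"] = threshold
    return out


def cross_study_compare(
    fits: pd.DataFrame,
    external: Mapping[str, pd.Series],
    min_datasets: int = 3,
) -> Tuple[pd.Index, pd.DataFrame]:
    """Collate genes consistently less stable here than in external
    half-life tables (gene → half-life in minutes).

    For each dataset, the paired difference (external − internal) is
    computed over common filter-passing genes; genes whose half-life is
    lower by at least the dataset's median difference (and strictly
    lower at all) are flagged.  Returns the set flagged in at least
    ``min_datasets`` datasets plus a per-dataset effect-size table.
    """
    internal = fits[fits["passed_filters"]].set_index("gene_id")["halflife_min"]
    flags: Dict[str, int] = {}
    rows = []
    for name, table in external.items():
        table = pd.Series(table).astype(float)
        common = internal.index.intersection(table.index)
        if len(common) == 0:
            logger.warning("cross_study_compare: no common genes with %s; skipped", name)
            continue
        diff = table.loc[common] - internal.loc[common]  # >0: external longer
        med = float(np.median(diff))
        flagged = common[(diff >= med) & (diff > 0)]
        for g in flagged:
            flags[g] = flags.get(g, 0) + 1
        rows.append({
            "dataset": name,
            "n_common": len(common),
            "median_diff_min": med,
            "mean_diff_min": float(diff.mean()),
            "cliffs_delta": cliffs_delta(table.loc[common], internal.loc[common]),
            "n_flagged": len(flagged),
        })
    per_dataset = pd.DataFrame(rows)
    reduced = pd.Index(sorted(g for g, k in flags.items() if k >= min_datasets),
                       name="gene_id")
    logger.info("cross_study_compare: %d genes flagged in >= %d datasets",
                len(reduced), min_datasets)
    return reduced, per_dataset
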