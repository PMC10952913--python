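"""Synthetic transcription-inhibition time courses with known ground truth.

The generator emulates the statistical structure of a cordycepin decay
experiment in plant leaves:

* gene-wise first-order exponential decay after inhibition, with
  condition-dependent half-life shifts (a configurable subpopulation of
  genes is destabilised under high light);
* a set of highly expressed, effectively stable reference genes;
* the compositional artifact — per-sample relative abundances are
  renormalised to sum to one *before* count sampling, so stable genes
  appear induced as the decaying RNA pool shrinks;
* negative-binomial counting noise around log-normal library sizes;
* multiplicative log-normal batch effects (per gene × batch);
* stress-induced ("RRGD") mock-arm trajectories in three categories,
  distinguished by when the induced transcripts decline;
* paired total / polysome-associated courses with a per-gene true
  relative polysome loading (RPL) trajectory that decouples from total
  abundance late in stress and relaxes back during recovery.

All randomness flows from ``SimulationConfig.seed`` through spawned
`numpy` seed sequences, so each generator op is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .abundance_io import TimeCourseExperiment

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "generate_truth",
    "simulate_decay_course",
    "simulate_polysome_course",
]

# half-life assigned to "effectively stable" reference genes (minutes);
# anything ≥ 1440 min behaves as non-decaying on a 30-min course
REFERENCE_HALFLIFE_MIN = 20_000.0

DECAY_CLASSES = ("rapid", "fast", "slow", "stable")
RRGD_CATEGORIES = ("cat1", "cat2", "cat3")


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable parameters of the simulated experiment.

    Defaults mirror the real design: three post-infiltration harvests at
    10-min intervals (first sample 10 min after inhibitor infiltration),
    four biological replicates split over two batches, and a polysome
    course sampled at 0/30/60 min of high light and 7.5/15/30 min of
    recovery.
    """

    n_genes: int = 2000
    timepoints_min: Tuple[float, ...] = (10.0, 20.0, 30.0)
    n_replicates: int = 4
    n_batches: int = 2
    nb_dispersion: float = 0.05
    batch_sd: float = 0.1
    library_size_mean: float = 2_000_000.0
    library_size_cv: float = 0.2
    halflife_log_range: Tuple[float, float] = (5.0, 200.0)
    frac_reference: float = 0.05
    frac_rrgd: float = 0.05
    hl_destab_shift: float = 0.7
    frac_hl_destab: float = 0.6
    lag_min: float = 0.0
    conditions: Tuple[str, ...] = ("US", "HL", "REC")
    poly_timepoints_hl: Tuple[float, ...] = (0.0, 30.0, 60.0)
    poly_timepoints_rec: Tuple[float, ...] = (7.5, 15.0, 30.0)
    rpl_late_sd: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        tp = list(self.timepoints_min)
        if not tp:
            raise ValueError("timepoints_min must be non-empty")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints_min must be strictly increasing")
        for name in ("frac_reference", "frac_rrgd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_reference + self.frac_rrgd > 1.0:
            raise ValueError("frac_reference + frac_rrgd must not exceed 1")
        if not 0.0 <= self.frac_hl_destab <= 1.0:
            raise ValueError("frac_hl_destab must lie in [0, 1]")
        lo, hi = self.halflife_log_range
        if lo <= 0 or hi <= lo:
            raise ValueError("halflife_log_range must satisfy 0 < lo < hi")
        if self.nb_dispersion < 0 or self.batch_sd < 0 or self.library_size_cv < 0:
            raise ValueError("dispersion/SD parameters must be non-negative")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class TruthTable:
    """Ground truth of a simulated experiment.

    ``per_condition`` has one row per (gene, condition) with the true
    half-life, the expected baseline abundance (arbitrary TPM-like
    units, expected at the first harvest) and the gene's decay class and
    RRGD category.  ``rpl`` holds the true relative-polysome-loading
    trajectory (genes × (condition, timepoint)).
    """

    per_condition: pd.DataFrame
    rpl: pd.DataFrame
    config: SimulationConfig

    @property
    def genes(self) -> pd.Index:
        return self.rpl.index

    def halflives(self, condition: str) -> pd.Series:
        sub = self.per_condition[self.per_condition["condition"] == condition]
        return sub.set_index("gene_id")["true_halflife_min"]

    def gene_info(self) -> pd.DataFrame:
        """One row per gene (condition-invariant columns)."""
        first = self.per_condition.drop_duplicates("gene_id").set_index("gene_id")
        return first[["decay_class", "rrgd_category"]]

    def write(self, path) -> None:
        self.per_condition.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _rngs(config: SimulationConfig, n: int, stream: int):
    """Spawn ``n`` independent generators for operation ``stream``."""
    ss = np.random.SeedSequence([int(config.seed) % (2**31), stream])
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def generate_truth(config: SimulationConfig) -> TruthTable:
    """Draw per-gene, per-condition ground truth.

    Unstressed half-lives are log-uniform over ``halflife_log_range``.
    A ``frac_hl_destab`` subset of non-reference genes has its HL
    half-life multiplied by ``hl_destab_shift`` (< 1 destabilises);
    recovery half-lives equal unstressed ones.  Reference genes are
    effectively stable in every condition.  Decay classes are half-life
    quartiles of the non-reference genes (rapid/fast/slow/stable).
    """
    config.validate()
    (rng,) = _rngs(config, 1, stream=0)
    n = config.n_genes
    genes = pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")

    n_ref = int(round(config.frac_reference * n))
    n_rrgd = int(round(config.frac_rrgd * n))
    is_ref = np.zeros(n, bool)
    is_ref[:n_ref] = True
    rrgd_cat = np.array(["none"] * n, object)
    rrgd_idx = np.arange(n_ref, n_ref + n_rrgd)
    rrgd_cat[rrgd_idx] = [RRGD_CATEGORIES[i % 3] for i in range(n_rrgd)]

    lo, hi = config.halflife_log_range
    hl_us = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    hl_us[is_ref] = REFERENCE_HALFLIFE_MIN

    destab = np.zeros(n, bool)
    nonref = np.where(~is_ref)[0]
    n_destab = int(round(config.frac_hl_destab * len(nonref)))
    destab[rng.choice(nonref, size=n_destab, replace=False)] = True
    hl_hl = np.where(destab, hl_us * config.hl_destab_shift, hl_us)
    hl_hl[is_ref] = REFERENCE_HALFLIFE_MIN
    hl_rec = hl_us.copy()

    # baseline abundances: reference genes sit in the high-abundance tail
    baseline = np.exp(rng.normal(np.log(10.0), 1.5, n))
    baseline[is_ref] = np.exp(rng.normal(np.log(600.0), 0.25, n_ref))

    # RRGD induction folds (≥ 3-fold by construction)
    induction = np.ones(n)
    induction[rrgd_idx] = 3.0 * np.exp(rng.uniform(0.0, np.log(3.0), n_rrgd))

    # decay classes from half-life quartiles of non-reference genes
    decay_class = np.array(["reference"] * n, object)
    qs = np.quantile(hl_us[~is_ref], [0.25, 0.5, 0.75])
    decay_class[~is_ref] = np.array(DECAY_CLASSES, object)[
        np.searchsorted(qs, hl_us[~is_ref])
    ]

    # per-condition rows; under HL/REC the RRGD genes start their course
    # already induced (the stress window precedes the first harvest)
    rows = []
    for cond in config.conditions:
        hl = {"US": hl_us, "HL": hl_hl, "REC": hl_rec}[cond]
        base = baseline.copy()
        if cond in ("HL", "REC"):
            base = base * induction
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "condition": cond,
                    "true_halflife_min": hl,
                    "baseline_abundance": base,
                    "decay_class": decay_class,
                    "rrgd_category": rrgd_cat,
                    "hl_destabilised": destab,
                }
            )
        )
    per_condition = pd.concat(rows, ignore_index=True)

    rpl = _true_rpl(config, rng, genes, baseline * induction)
    return TruthTable(per_condition=per_condition, rpl=rpl, config=config)


def _true_rpl(config, rng, genes, weights) -> pd.DataFrame:
    """True RPL trajectory: unity early in stress, log-normal scatter at
    60 min HL, geometric relaxation back to unity over recovery.  The
    trajectory is centred so the abundance-weighted mean RPL stays 1
    (the overall polysome-associated pool is approximately conserved).
    """
    cols = pd.MultiIndex.from_tuples(
        [("HL", t) for t in config.poly_timepoints_hl]
        + [("REC", t) for t in config.poly_timepoints_rec],
        names=["condition", "timepoint_min"],
    )
    late = np.exp(rng.normal(0.0, config.rpl_late_sd, len(genes)))
    # relaxation exponents for REC timepoints (fraction of late log-RPL kept)
    rec_keep = [0.67, 0.4, 0.1][: len(config.poly_timepoints_rec)]
    data = {}
    for t in config.poly_timepoints_hl[:-1]:
        data[("HL", t)] = np.ones(len(genes))
    data[("HL", config.poly_timepoints_hl[-1])] = late
    for t, k in zip(config.poly_timepoints_rec, rec_keep):
        data[("REC", t)] = late**k
    rpl = pd.DataFrame(data, index=genes)[cols]
    w = np.asarray(weights, float)
    w = w / w.sum()
    rpl = rpl / (rpl.mul(w, axis=0).sum(axis=0))  # weighted mean -> 1
    return rpl


# ---------------------------------------------------------------------------
# count sampling machinery
# ---------------------------------------------------------------------------

def _library_sizes(rng, n: int, mean: float, cv: float) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(sigma2), n))


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma–Poisson mixing; Poisson at dispersion 0."""
    mean = np.clip(mean, 0.0, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _sample_counts(rng, expected_abund: np.ndarray, batch_factor: np.ndarray,
                   libsize: float, dispersion: float) -> np.ndarray:
    """Renormalise expected abundances to relative fractions (this is the
    compositional step), then draw NB counts around libsize × fraction."""
    a = expected_abund * batch_factor
    rel = a / a.sum()
    return _nb_counts(rng, libsize * rel, dispersion)


def _batch_factors(rng, n_genes: int, n_batches: int, sd: float) -> np.ndarray:
    if sd == 0:
        return np.ones((n_batches, n_genes))
    return np.exp(rng.normal(0.0, sd, (n_batches, n_genes)))


# mock-arm decline multiplier for RRGD genes that fall during the course
def _decline_multiplier(t, t_first, t_last, floor=0.25) -> float:
    if t_last == t_first:
        return 1.0
    frac = (t - t_first) / (t_last - t_first)
    return floor**frac


# ---------------------------------------------------------------------------
# decay course
# ---------------------------------------------------------------------------

def _expected_decay_abundance(truth: TruthTable, cond: str, t: float,
                              treatment: str, config: SimulationConfig) -> np.ndarray:
    sub = truth.per_condition[truth.per_condition["condition"] == cond]
    sub = sub.set_index("gene_id").loc[truth.genes]
    base = sub["baseline_abundance"].to_numpy(float)
    t_first = config.timepoints_min[0]
    t_last = config.timepoints_min[-1]
    if treatment == "cordycepin":
        hl = sub["true_halflife_min"].to_numpy(float)
        dt = np.maximum(t - t_first - config.lag_min, 0.0)
        return base * np.exp(-np.log(2.0) / hl * dt)
    # mock arm: flat, except RRGD genes that decline within the window
    mult = np.ones(len(sub))
    cat = sub["rrgd_category"].to_numpy(object)
    if cond == "HL":
        declining = cat == "cat3"
    elif cond == "REC":
        declining = (cat == "cat2") | (cat == "cat3")
    else:
        declining = np.zeros(len(sub), bool)
    mult[declining] = _decline_multiplier(t, t_first, t_last)
    return base * mult


def simulate_decay_course(truth: TruthTable,
                          config: Optional[SimulationConfig] = None) -> TimeCourseExperiment:
    """Simulate mock and cordycepin arms of the decay time course.

    Sample IDs encode condition, treatment, timepoint and replicate.
    Replicates are assigned round-robin to batches.  In the cordycepin
    arm, expected abundance decays exponentially from the first harvest;
    per-sample fractions are renormalised before NB sampling, producing
    the compositional artifact that decay-factor normalization corrects.
    """
    config = config or truth.config
    config.validate()
    rng_bf, rng_lib, rng_counts = _rngs(config, 3, stream=1)
    bf = _batch_factors(rng_bf, len(truth.genes), config.n_batches, config.batch_sd)

    sample_ids, rows, count_cols = [], [], []
    for cond in config.conditions:
        for treatment in ("mock", "cordycepin"):
            for t in config.timepoints_min:
                expected = _expected_decay_abundance(truth, cond, t, treatment, config)
                for rep in range(1, config.n_replicates + 1):
                    batch = (rep - 1) % config.n_batches
                    sid = f"{cond}_{treatment}_t{t:g}_r{rep}"
                    lib = _library_sizes(rng_lib, 1, config.library_size_mean,
                                         config.library_size_cv)[0]
                    counts = _sample_counts(rng_counts, expected, bf[batch],
                                            lib, config.nb_dispersion)
                    sample_ids.append(sid)
                    count_cols.append(counts)
                    rows.append((cond, treatment, t, batch + 1, rep))
    counts = pd.DataFrame(
        np.column_stack(count_cols), index=truth.genes, columns=sample_ids
    )
    sheet = pd.DataFrame(
        rows,
        columns=["condition", "treatment", "timepoint_min", "batch", "replicate"],
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return TimeCourseExperiment(counts, sheet)


# ---------------------------------------------------------------------------
# polysome course
# ---------------------------------------------------------------------------

def _expected_poly_total(truth: TruthTable, cond: str, t: float,
                         config: SimulationConfig) -> np.ndarray:
    """Expected *total* abundance in the polysome course (no inhibitor).

    Non-RRGD genes are flat at their unstressed baseline; RRGD genes
    follow their category profile: induced by 30 min HL, with cat3
    declining after 30 min HL, cat2 declining only during recovery and
    cat1 staying up throughout.
    """
    us = truth.per_condition[truth.per_condition["condition"] == "US"]
    us = us.set_index("gene_id").loc[truth.genes]
    base = us["baseline_abundance"].to_numpy(float)
    hlrow = truth.per_condition[truth.per_condition["condition"] == "HL"]
    hlrow = hlrow.set_index("gene_id").loc[truth.genes]
    induction = (hlrow["baseline_abundance"] / us["baseline_abundance"]).to_numpy(float)
    cat = us["rrgd_category"].to_numpy(object)

    mult = np.ones(len(base))
    rrgd = cat != "none"
    if cond == "HL":
        if t == 0:
            pass  # unstressed baseline
        elif t <= 30:
            mult[rrgd] = induction[rrgd]
        else:  # after 30 min HL: cat3 declines 2.5-fold, others stay up
            mult[rrgd] = induction[rrgd]
            mult[cat == "cat3"] = induction[cat == "cat3"] / 2.5
    else:  # REC timepoints follow 60 min of HL
        rec_frac = {7.5: 0.55, 15.0: 0.3, 30.0: 0.15}.get(float(t), 0.15)
        mult[cat == "cat1"] = induction[cat == "cat1"]
        mult[cat == "cat2"] = induction[cat == "cat2"] * rec_frac
        mult[cat == "cat3"] = induction[cat == "cat3"] / 2.5 * (0.4 + rec_frac)
    return base * mult


def simulate_polysome_course(
    truth: TruthTable, config: Optional[SimulationConfig] = None
) -> Tuple[TimeCourseExperiment, TimeCourseExperiment]:
    """Simulate paired total and polysome-associated count matrices.

    Polysome expected abundance = total expected abundance × true RPL at
    that (condition, timepoint); both arms then go through the same
    renormalise-and-sample machinery as the decay course.  Returns
    ``(total, polysome)`` experiments with matching sample layouts.
    """
    config = config or truth.config
    config.validate()
    if truth.rpl is None or truth.rpl.empty:
        raise ValueError("truth table lacks true_rpl trajectories")
    rng_bf, rng_lib, rng_counts = _rngs(config, 3, stream=2)
    bf = _batch_factors(rng_bf, len(truth.genes), config.n_batches, config.batch_sd)

    design = [("HL", t) for t in config.poly_timepoints_hl] + [
        ("REC", t) for t in config.poly_timepoints_rec
    ]
    mats = {"total": ([], [], []), "polysome": ([], [], [])}
    for cond, t in design:
        total_exp = _expected_poly_total(truth, cond, t, config)
        rpl = truth.rpl[(cond, t)].to_numpy(float)
        for arm, expected in (("total", total_exp), ("polysome", total_exp * rpl)):
            ids, cols, rows = mats[arm]
            for rep in range(1, config.n_replicates + 1):
                batch = (rep - 1) % config.n_batches
                sid = f"{arm}_{cond}_t{t:g}_r{rep}"
                lib = _library_sizes(rng_lib, 1, config.library_size_mean,
                                     config.library_size_cv)[0]
                counts = _sample_counts(rng_counts, expected, bf[batch],
                                        lib, config.nb_dispersion)
                ids.append(sid)
                cols.append(counts)
                rows.append((cond, "mock", t, batch + 1, rep))

    out = []
    for arm in ("total", "polysome"):
        ids, cols, rows = mats[arm]
        counts = pd.DataFrame(np.column_stack(cols), index=truth.genes, columns=ids)
        sheet = pd.DataFrame(
            rows,
            columns=["condition", "treatment", "timepoint_min", "batch", "replicate"],
            index=pd.Index(ids, name="sample_id"),
        )
        out.append(TimeCourseExperiment(counts, sheet))
    return out[0], out[1]
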