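# Methods

## Kinetic model

Transcript abundance after transcription inhibition is modelled as
first-order exponential decay, `C(t) = C_first · exp(−kd · dT)`, with
`dT` the minutes elapsed since the first post-infiltration harvest and
`t1/2 = ln 2 / kd`. The log of the decay-factor-normalized fractional
abundance is therefore linear in time, and `kd` is minus the fitted slope.
First-order kinetics is an assumption, not a finding: plateauing or
biphasic decay is outside this package's scope and will surface as a poor
fit (low conditional R², non-significant slope) rather than a biased
half-life.

## Decay-factor normalization

Relative-abundance units (CPM) conflate decay with pool shrinkage: as
unstable transcripts disappear, stable ones gain library share. Reference
genes — mean log2(CPM + 0.01) at or above the 95th percentile and CPM
coefficient of variation at or below the 25th percentile, computed across
mock-treated samples — are taken to be effectively non-decaying on the
course's timescale, so their mean fold increase at each (condition,
timepoint) of the inhibitor-treated samples estimates the inverse pool
size. Fractional abundances (per-gene ratio to the replicate-mean at the
condition's first timepoint) are divided by this factor.

Choices where the procedure is genuinely open:

* Percentiles are linear-interpolation quantiles with inclusive
  boundaries (ties at the threshold are retained), so the selection is
  reproducible on data with ties.
* "Mean fold increase" is the arithmetic mean of per-gene fold changes of
  replicate-mean abundances; a geometric-mean variant is available
  (`geometric=True`) since the arithmetic/geometric choice is a convention.
* Genes still showing a normalized fold increase ≥ 1.5 at *any*
  post-baseline timepoint (replicate-mean) are excluded — the most
  conservative reading of "any residual induction".
* When factors and fractional abundances come from the same matrix, the
  reference-gene mean trajectory equals 1 exactly at every (condition,
  timepoint); this identity is used as a correctness test.
* Zero abundances at post-baseline timepoints are kept as zeros and
  handled at the regression stage (dropped from the log response), not
  floored: flooring would bias kd upward for low-abundance genes.

## Regression, vetting and filters

Each gene × condition series is fitted with time as the fixed effect and,
when the design has ≥ 2 batches, a random intercept per batch
(statsmodels `MixedLM`, REML). A singular or non-finite random-effect
variance triggers an automatic ordinary-least-squares fallback, recorded
in `fit_method`. Baseline samples enter as ordinary observations at
dT = 0; the baseline-mean normalization makes their expected log response
zero without double-counting.

* **p-value**: Wald t-test on the time coefficient with `n − 2` residual
  degrees of freedom. This is simpler than a Satterthwaite approximation;
  with ≥ 12 observations per series the difference is immaterial next to
  counting noise.
* **Conditional R²**: the variance-partition form
  `(fixed + random) / (fixed + random + residual)`, where the fixed
  component is the variance of the fitted time effect.
* **Filters**: p < 0.05 (unadjusted for the genome-wide screen;
  Benjamini–Hochberg adjustment is provided for small-panel analyses),
  kd > 0, and t1/2 ≤ 1440 min (one day). Series with > 50% zero
  observations are skipped as `sparse`; fewer than 3 usable points or
  fewer than 2 distinct timepoints skips the fit.

The timepoint-omission sensitivity analysis refits the course with chosen
timepoints dropped and reports modelled-gene counts and the Pearson
correlation of log2 half-lives over genes modelled in both designs (log
scale symmetrises the heavy right tail of half-life estimates).

## Estimation statistics and stability calls

Condition contrasts use paired effect sizes over gene-aligned half-life
vectors: mean difference, median difference, and Cliff's delta computed
via the rank-sum identity `δ = 2·U/(n·m) − 1` (ties count one half, which
reproduces the "ties contribute 0" pair-count definition; an exhaustive
pair-enumeration oracle checks this in the tests). Bootstrap CIs resample
gene pairs jointly (10,000 resamples by default, percentile intervals;
the point estimate is always computed on the original pairing).

`classify_stability` thresholds at the absolute median of the paired
half-life differences in minutes; "greater in magnitude" is strict, so
boundary ties are `unchanged`. The cross-study comparison flags a gene
against an external dataset when its half-life is lower and the deficit
reaches the dataset's median difference (ties at the median count as
flagged; the strictly-positive requirement keeps identical datasets from
flagging everything), then collates genes flagged in ≥ 3 datasets.

## Translation analysis

RPL is the per-replicate ratio of polysome-associated to total abundance,
paired on (condition, timepoint, replicate); replicates with zero total
abundance are omitted. Fold changes between states use replicate means
with a 0.01 pseudocount on both sides of the ratio. The 3×3 quadrant
summary calls up/down at 1.5-fold and reports the changed marginals and
their ratio rounded to one decimal ("r:1"). RRGD genes are those ≥ 3-fold
induced at 30 min of high light; category 3 declines ≥ 1.5-fold from 30
to 60 min HL, category 2 declines only between 60 min HL and the end of
recovery, category 1 stays up. The 1.5-fold decline criterion is a
configurable stand-in — the original category definitions live in prior
work and do not pin down an exact threshold. Rank-sum comparisons of RPL
fold changes between categories use the exact U distribution (or exact
permutation enumeration under ties) below n = 8 and the tie-corrected
normal approximation otherwise.

## Synthetic-data generator

The generator emulates, per condition (US/HL/REC): log-uniform true
half-lives (default 5–200 min, the range a 30-min course can resolve),
5% effectively stable reference genes placed in the high-abundance tail
(log-normal baselines so the percentile selection rule can find them), 5%
RRGD genes with ≥ 3-fold induction and category-specific mock/total
trajectories, negative-binomial counts (gamma–Poisson, dispersion 0.05 —
a conventional bulk RNA-seq value; the source experiments do not report
one) around log-normal library sizes, and per-gene × batch log-normal
factors (SD 0.1) that the mixed model absorbs as random intercepts.
Per-sample expected abundances are renormalised to sum to one *before*
sampling, which is exactly the compositional artifact the normalization
corrects.

Condition dependence: under high light a 60% subpopulation of
non-reference genes has its half-life multiplied by 0.7 (destabilised);
recovery half-lives equal unstressed ones. Modelling destabilisation as a
subpopulation rather than transcriptome-wide reflects the observed
biology — destabilisation dominates but a sizeable fraction of
transcripts is unchanged or stabilised — and it is what makes the
median-difference classification rule meaningful: if every gene shifted
identically, at most half could ever exceed the median-difference
threshold, by construction.

True RPL trajectories are 1 through early stress, acquire log-normal
scatter (SD 0.6 in log) at 60 min HL, and relax geometrically back toward
1 over recovery; they are centred so the abundance-weighted mean RPL is 1,
matching the observation that the overall polysome-associated RNA pool
stays approximately constant. An optional per-gene decay lag (`lag_min`,
default 0) can defer the onset of decay, mimicking residual transcription
immediately after infiltration; it is not part of any default study.

What the generator does **not** emulate: read-level sampling (no FASTQ,
no positional or GC bias), pre-mRNA/splicing dynamics, transcript-level
quantification uncertainty, library-preparation batch effects beyond a
single multiplicative factor, or correlated gene modules. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated noise model, not robustness to every artifact
of real libraries.

## Problem sizes and numerical choices

The recovery and destabilisation studies use 2,000 genes, harvests at
10/20/30 min, 4 replicates over 2 batches and dispersion 0.05; at this
size the full normalize → fit → classify pipeline runs in ~20 s on one
CPU, and recovery is stable across seeds (median relative half-life error
≈ 0.12–0.14, Spearman ρ ≈ 0.94–0.95 among filter-passing genes). The
omission-sensitivity study uses a denser six-timepoint course
(0–120 min), mirroring the published external time series on which that
analysis was originally performed; with only three harvests, dropping one
leaves a two-timepoint design whose estimates are too noisy for the
correlation to be informative.

Determinism: all generator randomness flows from a single seed through
spawned seed sequences (one stream per operation), so truth, decay-course
and polysome-course draws are independently reproducible; bootstrap and
test RNGs are seeded explicitly.

## Known limitations

* The detection filter operates on whatever abundance unit it is given;
  exact equivalence with transcript-level TPM aggregation from a
  pseudoaligner is not attempted.
* TMM-style composition-robust library normalization is not implemented;
  plain library-size scaling stands upstream of the decay-factor
  correction, which is itself composition-aware.
* The mixed model fits an intercept-only random effect; random slopes per
  batch are not supported.
* Dataset-scale gene counts reported for the original experiment depend
  on its deposited data and are not reproduced here; the package's claims
  are calibrated on synthetic ground truth.
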