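"""Count-matrix I/O, abundance units and detection filtering.

The central container is :class:`TimeCourseExperiment`: a gene × sample
count matrix plus a sample sheet describing the transcription-inhibition
time course (condition US/HL/REC, treatment mock/cordycepin, timepoint in
minutes post-infiltration, experimental batch, replicate).  Counts are
accepted as non-negative reals by default because upstream quantifiers
commonly emit fractional estimated counts; ``strict_int=True`` enforces
integer counts.

Abundance units follow the standard definitions:

* CPM  = 1e6 · count / library_size
* RPKM = 1e9 · count / (library_size · length_bp)
* TPM  = 1e6 · (count/length) / Σ_genes(count/length)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("decaylab")

CONDITIONS = ("US", "HL", "REC")
TREATMENTS = ("mock", "cordycepin")
SHEET_COLUMNS = ("condition", "treatment", "timepoint_min", "batch", "replicate")
ABUNDANCE_UNITS = ("CPM", "TPM", "RPKM")


@dataclass
class TimeCourseExperiment:
    """Counts plus sample metadata for a decay time course.

    Parameters
    ----------
    counts
        Gene × sample matrix; index = gene IDs, columns = sample IDs.
    sample_sheet
        One row per sample (index = sample ID) with columns
        ``condition, treatment, timepoint_min, batch, replicate``.
    gene_lengths
        Optional per-gene transcript lengths in bp (required for
        RPKM/TPM conversion).
    """

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    gene_lengths: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, strict_int: bool = False) -> None:
        counts, sheet = self.counts, self.sample_sheet
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene_id(s): {dups[:5]}")
        missing = [s for s in counts.columns if s not in sheet.index]
        extra = [s for s in sheet.index if s not in counts.columns]
        if missing or extra:
            raise ValueError(
                "sample sheet / count matrix mismatch; "
                f"samples without sheet rows: {missing[:10]}; "
                f"sheet rows without samples: {extra[:10]}"
            )
        # align sheet row order to count columns
        self.sample_sheet = sheet = sheet.loc[list(counts.columns)]
        for col in SHEET_COLUMNS:
            if col not in sheet.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        bad_cond = set(sheet["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown condition labels: {sorted(bad_cond)}")
        bad_treat = set(sheet["treatment"]) - set(TREATMENTS)
        if bad_treat:
            raise ValueError(f"unknown treatment labels: {sorted(bad_treat)}")
        if (sheet["timepoint_min"].astype(float) < 0).any():
            raise ValueError("negative timepoint_min in sample sheet")
        vals = counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative counts")
        if strict_int and not np.allclose(vals, np.round(vals)):
            raise ValueError("non-integer counts with strict_int=True")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(counts.index)
            if self.gene_lengths.isna().any():
                miss = self.gene_lengths.index[self.gene_lengths.isna()]
                raise ValueError(f"gene_lengths missing for: {list(miss[:5])}")
            if (self.gene_lengths <= 0).any():
                raise ValueError("non-positive gene lengths")

    # -- convenience -----------------------------------------------------
    def subset_samples(self, sample_ids: Sequence[str]) -> "TimeCourseExperiment":
        """Restrict to the given samples (sheet follows)."""
        return TimeCourseExperiment(
            self.counts[list(sample_ids)],
            self.sample_sheet.loc[list(sample_ids)],
            self.gene_lengths,
        )

    def samples_where(self, **criteria) -> list[str]:
        """Sample IDs matching equality criteria on sheet columns,
        e.g. ``samples_where(treatment="mock", condition="US")``."""
        mask = pd.Series(True, index=self.sample_sheet.index)
        for col, val in criteria.items():
            col_vals = self.sample_sheet[col]
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= col_vals.isin(val)
            else:
                mask &= col_vals == val
        return list(self.sample_sheet.index[mask])


@dataclass
class AbundanceMatrix:
    """Gene × sample abundance values in a declared unit (CPM/TPM/RPKM)."""

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ABUNDANCE_UNITS:
            raise ValueError(f"unknown abundance unit {self.unit!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_experiment(
    counts_path,
    sheet_path,
    lengths_path=None,
    strict_int: bool = False,
) -> TimeCourseExperiment:
    """Read a count TSV (genes × samples) and a sample-sheet TSV.

    Gzip is handled transparently by pandas based on the file suffix.
    The sheet must contain a ``sample_id`` column (or use its first
    column as the ID) matching the count-matrix header.
    """
    for p in (counts_path, sheet_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sheet_path, sep="\t")
    id_col = "sample_id" if "sample_id" in sheet.columns else sheet.columns[0]
    sheet = sheet.set_index(id_col)
    lengths = None
    if lengths_path is not None:
        if not Path(lengths_path).exists():
            raise FileNotFoundError(f"input file not found: {lengths_path}")
        ltab = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = ltab.iloc[:, 0].astype(float)
    exp = TimeCourseExperiment(counts, sheet, lengths)
    exp.validate(strict_int=strict_int)
    return exp


def write_experiment(exp: TimeCourseExperiment, counts_path, sheet_path) -> None:
    """Write counts and sample sheet as TSV (gzip if path ends in .gz)."""
    exp.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    exp.sample_sheet.to_csv(sheet_path, sep="\t", index_label="sample_id")


def read_experiment_mtx(mtx_path, genes_path, samples_path, sheet_path) -> TimeCourseExperiment:
    """Read a MatrixMarket count triple (matrix + gene/sample sidecars)."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0]
    samples = pd.read_csv(samples_path, sep="\t", header=None).iloc[:, 0]
    counts = pd.DataFrame(mat, index=genes, columns=samples)
    sheet = pd.read_csv(sheet_path, sep="\t").set_index("sample_id")
    return TimeCourseExperiment(counts, sheet)


# ---------------------------------------------------------------------------
# Abundance units
# ---------------------------------------------------------------------------

def to_abundance(exp: TimeCourseExperiment, unit: str = "CPM") -> AbundanceMatrix:
    """Convert counts to CPM, RPKM or TPM (library-size scaling)."""
    if unit not in ABUNDANCE_UNITS:
        raise ValueError(f"unknown abundance unit {unit!r}")
    counts = exp.counts.astype(float)
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        zero = list(libsize.index[libsize == 0])
        raise ValueError(f"zero column sum for sample(s): {zero}")
    if unit == "CPM":
        vals = counts.div(libsize, axis=1) * 1e6
    else:
        if exp.gene_lengths is None:
            raise ValueError(f"{unit} conversion requires gene_lengths")
        lengths = exp.gene_lengths.astype(float)
        if unit == "RPKM":
            vals = counts.div(libsize, axis=1).div(lengths, axis=0) * 1e9
        else:  # TPM
            rate = counts.div(lengths, axis=0)
            vals = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return AbundanceMatrix(vals, unit)


def detection_filter(
    abundance: AbundanceMatrix,
    min_tpm: float = 0.5,
    min_samples: int = 6,
    sample_subset: Optional[Iterable[str]] = None,
) -> pd.Index:
    """Genes detected at ≥ ``min_tpm`` in strictly more than
    ``min_samples`` of ``sample_subset`` (e.g. the first-timepoint
    samples of the course).
    """
    if sample_subset is None:
        sample_subset = list(abundance.values.columns)
    sample_subset = list(sample_subset)
    if not sample_subset:
        raise ValueError("sample_subset must be non-empty")
    sub = abundance.values[sample_subset]
    n_detected = (sub >= min_tpm).sum(axis=1)
    keep = abundance.values.index[n_detected > min_samples]
    logger.info(
        "detection_filter: %d/%d genes at >= %g in > %d of %d samples",
        len(keep), len(abundance.values), min_tpm, min_samples, len(sample_subset),
    )
    return keep
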