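import numpy as np
import pandas as pd
import pytest

from decaylab import (SimulationConfig, TimeCourseExperiment, exclude_induced,
                      compute_decay_factors, generate_truth,
                      normalize_fractional, select_reference_genes,
                      simulate_decay_course, to_abundance)


def normalize_course(exp, abundance_pct=95.0, cv_pct=25.0, exclude_fold=1.5):
    """Run the normalization stage of the pipeline on a simulated course."""
    mock = exp.samples_where(treatment="mock")
    cord = exp.samples_where(treatment="cordycepin")
    mock_cpm = to_abundance(exp.subset_samples(mock), "CPM")
    cord_cpm = to_abundance(exp.subset_samples(cord), "CPM")
    refs = select_reference_genes(mock_cpm, abundance_pct, cv_pct)
    factors = compute_decay_factors(cord_cpm, refs, exp.sample_sheet.loc[cord])
    fractional = normalize_fractional(cord_cpm, factors, exp.sample_sheet.loc[cord])
    fractional, _ = exclude_induced(fractional, exclude_fold)
    return fractional, refs, factors, cord_cpm


def exact_fractional(halflives_min, timepoints=(10.0, 20.0, 30.0),
                     n_replicates=2, condition="US"):
    """Noise-free FractionalAbundance following exact exponential decay."""
    from decaylab.decay_normalization import FractionalAbundance

    genes = pd.Index([f"G{i:05d}" for i in range(len(halflives_min))],
                     name="gene_id")
    kd = np.log(2.0) / np.asarray(halflives_min, float)
    ids, cols, rows = [], [], []
    for t in timepoints:
        for rep in range(1, n_replicates + 1):
            sid = f"{condition}_cordycepin_t{t:g}_r{rep}"
            ids.append(sid)
            cols.append(np.exp(-kd * (t - timepoints[0])))
            rows.append((condition, "cordycepin", t, 1 + (rep - 1) % 2, rep))
    values = pd.DataFrame(np.column_stack(cols), index=genes, columns=ids)
    sheet = pd.DataFrame(rows, columns=["condition", "treatment",
                                        "timepoint_min", "batch", "replicate"],
                         index=pd.Index(ids, name="sample_id"))
    baseline = pd.DataFrame({condition: np.ones(len(genes))}, index=genes)
    return FractionalAbundance(values=values, sheet=sheet, baseline=baseline)


@pytest.fixture(scope="session")
def small_truth():
    cfg = SimulationConfig(n_genes=300, seed=42)
    return generate_truth(cfg)


@pytest.fixture(scope="session")
def small_course(small_truth):
    return simulate_decay_course(small_truth)


@pytest.fixture(scope="session")
def small_fractional(small_course):
    fractional, refs, factors, cord_cpm = normalize_course(small_course)
    return fractional


@pytest.fixture(scope="session")
def recovery_pipeline():
    """The parameter-recovery study: 2,000 genes, harvests at 10/20/30
    min, 4 replicates over 2 batches, NB dispersion 0.05, true
    half-lives log-uniform on [5, 200] min (the generator defaults),
    normalized and fitted once for all downstream checks."""
    from decaylab import fit_all

    cfg = SimulationConfig(n_genes=2000, seed=11)
    truth = generate_truth(cfg)
    exp = simulate_decay_course(truth, cfg)
    fractional, refs, factors, cord_cpm = normalize_course(exp)
    fits = fit_all(fractional)
    return truth, fits
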