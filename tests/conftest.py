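import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from plastevo import (
    CountMatrix,
    SampleDesign,
    SimConfig,
    filter_by_expression,
    run_standard_contrasts,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_experiment():
    """One moderately sized simulated experiment with planted effects."""
    config = SimConfig(n_genes=2000, samples_per_cell=4, seed=7)
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def small_results(small_experiment):
    """Standard contrast tables for the shared simulated experiment."""
    counts, design, truth = small_experiment
    filtered = filter_by_expression(counts, design)
    return run_standard_contrasts(filtered, design), truth


@pytest.fixture
def toy_counts():
    """Tiny deterministic count matrix (4 genes x 4 samples)."""
    frame = pd.DataFrame(
        {
            "s1": [100, 40, 0, 860],
            "s2": [120, 35, 0, 845],
            "s3": [90, 50, 0, 860],
            "s4": [110, 45, 0, 845],
        },
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene"),
    )
    return CountMatrix(frame)


@pytest.fixture
def toy_design():
    table = pd.DataFrame(
        {
            "line_type": ["control", "control", "control", "control"],
            "treatment": ["unsprayed", "unsprayed", "sprayed", "sprayed"],
            "timepoint": [8, 8, 8, 8],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    return SampleDesign(table)


def dge_table(lfc, fdr, genes=None, contrast=None):
    """Minimal differential-expression table for classification tests."""
    lfc = np.asarray(lfc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    idx = genes if genes is not None else [f"g{i}" for i in range(len(lfc))]
    out = pd.DataFrame(
        {
            "logFC": lfc,
            "AveExpr": 0.0,
            "t": np.sign(lfc),
            "P.Value": fdr,
            "adj.P.Val": fdr,
        },
        index=pd.Index(idx, name="gene"),
    )
    if contrast is not None:
        out.attrs["contrast"] = contrast
    return out
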