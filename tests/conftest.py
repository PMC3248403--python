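import numpy as np
import pandas as pd
import pytest

from tnbcsig.expression_io import ExpressionMatrix
from tnbcsig.sam_survival import SurvivalVector, run_sam
from tnbcsig.survival_stats import combine_endpoints
from tnbcsig.synthetic_data import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The standard synthetic scenario: 5 datasets x 80 samples, G=2000."""
    return generate_cohort(GeneratorConfig())


@pytest.fixture(scope="session")
def default_sam(default_cohort):
    """SAM discovery on the default cohort's follow-up samples (B=50)."""
    matrix, records, truth = default_cohort
    efs = combine_endpoints(records)
    sample_ids = [r.sample_id for r in efs]
    surv = SurvivalVector(
        np.array([r.efs_time for r in efs]), np.array([r.efs_event for r in efs])
    )
    disc = matrix.subset_samples(sample_ids)
    return run_sam(disc, surv, B=50, seed=17)


@pytest.fixture
def toy_matrix():
    """Deterministic 4-probeset x 6-sample matrix over two datasets."""
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.normal(size=(4, 6)),
        index=[f"p{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(6)],
    )
    labels = pd.Series(["A"] * 3 + ["B"] * 3, index=vals.columns)
    return ExpressionMatrix(vals, labels)


def make_matrix(values, dataset_labels=None, probe_prefix="p", sample_prefix="s"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    G, n = values.shape
    frame = pd.DataFrame(
        values,
        index=[f"{probe_prefix}{i}" for i in range(G)],
        columns=[f"{sample_prefix}{i}" for i in range(n)],
    )
    labels = pd.Series(
        dataset_labels if dataset_labels is not None else ["D0"] * n,
        index=frame.columns,
    )
    return ExpressionMatrix(frame, labels)
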