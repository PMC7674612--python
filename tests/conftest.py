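"""Shared fixtures: synthetic cohorts at several scales.

Everything is generated programmatically; session scope keeps the
expensive default cohort (212 samples, 600 genes, 6 batches) to a single
simulation + preprocessing pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from meningrade.preprocess import MergedCohort, preprocess_cohort
from meningrade.synthetic import SynthConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition cohort: studies, metadata and ground truth."""
    return simulate_cohort(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_cohort(default_sim):
    """Fully preprocessed default cohort."""
    studies, metadata, _ = default_sim
    return preprocess_cohort(studies, metadata)


@pytest.fixture(scope="session")
def default_truth(default_sim):
    return default_sim[2]


def make_cohort(
    expression: np.ndarray,
    grades=None,
    studies=None,
    recurrence=None,
    gene_prefix: str = "G",
) -> MergedCohort:
    """Wrap a raw matrix into a MergedCohort with minimal metadata."""
    n_genes, n_samples = expression.shape
    genes = [f"{gene_prefix}{i:04d}" for i in range(n_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "study_id": studies if studies is not None else ["s1"] * n_samples,
            "who_grade": grades if grades is not None else [1] * n_samples,
            "recurrence": recurrence if recurrence is not None else ["unknown"] * n_samples,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return MergedCohort(
        expression=pd.DataFrame(expression, index=pd.Index(genes, name="gene_id"), columns=samples),
        metadata=meta,
    )


def two_block_matrix(
    rng: np.random.Generator,
    n_per_block: int = 50,
    n_samples: int = 60,
    noise_sd: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent latent factors, each driving one gene block."""
    f1 = rng.normal(size=n_samples)
    f2 = rng.normal(size=n_samples)
    X = np.empty((2 * n_per_block, n_samples))
    X[:n_per_block] = f1[None, :] + rng.normal(0, noise_sd, (n_per_block, n_samples))
    X[n_per_block:] = f2[None, :] + rng.normal(0, noise_sd, (n_per_block, n_samples))
    truth = np.repeat([1, 2], n_per_block)
    return X, truth
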