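import numpy as np
import pandas as pd
import pytest

from mbmetagene import BetaMatrix, ProbeAnnotation, SampleSheet


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    beta = rng.uniform(0, 1, size=(5, 3))
    pval = rng.uniform(0.0, 0.04, size=(5, 3))
    return BetaMatrix(
        probe_ids=[f"cg{i:05d}" for i in range(5)],
        sample_ids=["s1", "s2", "s3"],
        beta=beta,
        detection_p=pval,
    )


@pytest.fixture
def annotation_for(small_matrix):
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": small_matrix.probe_ids,
                "chromosome": ["1", "X", "2", "3", "Y"],
                "cross_reactive": [False, False, True, False, False],
                "max_maf_within_50bp": [0.0, 0.0, 0.0, 0.10, 0.0],
            }
        )
    )


@pytest.fixture
def sheet_for(small_matrix):
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": small_matrix.sample_ids,
                "label": ["WNT", "Non-classifiable", "Group3-HighRisk"],
            }
        )
    )


def random_beta_matrix(rng, n_probes, n_samples, missing_frac=0.1, with_pvals=True):
    beta = rng.uniform(0, 1, size=(n_probes, n_samples))
    if missing_frac:
        beta[rng.random(beta.shape) < missing_frac] = np.nan
    pval = rng.uniform(0, 1, size=(n_probes, n_samples)) if with_pvals else None
    return BetaMatrix(
        probe_ids=[f"cg{i:06d}" for i in range(n_probes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        beta=beta,
        detection_p=pval,
    )
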