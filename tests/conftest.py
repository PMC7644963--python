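import numpy as np
import pytest

from histomics.expression import tmm_normalize
from histomics.synthetic import generate_expression, generate_histology_cohort


@pytest.fixture(scope="session")
def signal_cohort():
    """Small image cohort with a strong texture difference between classes."""
    return generate_histology_cohort(
        n=40, prevalence=0.5, texture_shift=2.0, image_size=384, seed=11
    )


@pytest.fixture(scope="session")
def signal_expression():
    """Expression with 20 strongly differential genes among 600."""
    return generate_expression(
        n_genes=600, n_samples=150, n_de=20, lfc=1.5, n_factors=0, seed=21
    )


@pytest.fixture(scope="session")
def signal_expression_std(signal_expression):
    """Standardized log-CPM (samples x genes) of the signal expression."""
    _, lc = tmm_normalize(signal_expression.counts)
    X = lc.to_numpy().T
    return (X - X.mean(0)) / np.maximum(X.std(0), 1e-12)
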