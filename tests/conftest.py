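import numpy as np
import pandas as pd
import pytest

from miresponse.io import ExpressionMatrix, RunConfig, SampleAnnotation
from miresponse.simulate import SyntheticSpec, generate_all


@pytest.fixture(scope="session")
def study_cohort():
    """One full synthetic cohort at the default study conditions (seed 0)."""
    spec = SyntheticSpec(seed=0)
    return spec, generate_all(spec)


@pytest.fixture
def balanced_annotations():
    def make(n1=6, n2=6):
        samples = [f"S{i+1:02d}" for i in range(n1 + n2)]
        groups = ["responder"] * n1 + ["non_responder"] * n2
        return samples, [SampleAnnotation(s, g) for s, g in zip(samples, groups)]
    return make


@pytest.fixture
def null_matrix(balanced_annotations):
    """A label-free (no group effect) expression matrix with model variances."""
    def make(n_features=200, n1=6, n2=6, seed=0, a=2.0, b=1.0):
        rng = np.random.default_rng(seed)
        samples, ann = balanced_annotations(n1, n2)
        sig = 1.0 / np.sqrt(rng.gamma(a, b, n_features))
        x = 8.0 + rng.normal(size=(n_features, n1 + n2)) * sig[:, None]
        mat = ExpressionMatrix(pd.DataFrame(
            x, index=[f"f{i}" for i in range(n_features)], columns=samples))
        return mat, ann
    return make


@pytest.fixture
def default_config():
    return RunConfig()
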