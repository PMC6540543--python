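import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gbmeta.io import ExpressionStudy
from gbmeta.study_de import Contrast

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_null_study(n_genes=60, n_per_side=8, seed=0, study_id="NULL"):
    """Two-class study with no differential signal."""
    rng = np.random.default_rng(seed)
    cases = [f"case{i}" for i in range(n_per_side)]
    controls = [f"ctrl{i}" for i in range(n_per_side)]
    genes = [f"G{i:03d}" for i in range(n_genes)]
    values = pd.DataFrame(
        rng.normal(7, 1, size=(n_genes, 2 * n_per_side)),
        index=genes,
        columns=cases + controls,
    )
    study = ExpressionStudy(study_id=study_id, values=values)
    contrast = Contrast("GBM", "NG", tuple(cases), tuple(controls))
    return study, contrast


@pytest.fixture
def null_study():
    return make_null_study()
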