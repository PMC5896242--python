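import warnings

import numpy as np
import pandas as pd
import pytest

from ctvtreg.count_model import CountMatrix, SampleDesign
from ctvtreg.synthetic_data import SimulationConfig

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def toy_counts() -> CountMatrix:
    """Three genes, two samples, sample B exactly double sample A per gene."""
    return CountMatrix(["g1", "g2", "g3"], ["A", "B"], np.array([[1, 2], [2, 4], [4, 8]]))


@pytest.fixture
def paired_design() -> SampleDesign:
    rows = []
    for dog in ("d1", "d2", "d3"):
        for b in (1, 2, 3):
            rows.append({"sample_id": f"{dog}_B{b}", "dog": dog, "biopsy": b,
                         "regression_status": "REGRESSIVE"})
    return SampleDesign(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def strong_config() -> SimulationConfig:
    """Small, high-expression config where planted effects are easy to see."""
    return SimulationConfig(
        n_genes=400,
        n_dogs_regressive=3,
        n_dogs_nonregressive=0,
        biopsies_per_dog=3,
        baseline_log_mean_range=(np.log(100.0), np.log(1000.0)),
        frac_early=0.05,
        frac_late=0.05,
        frac_progressive=0.05,
        frac_non_expressed=0.0,
        seed=11,
    )
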