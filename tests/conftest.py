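import numpy as np
import pandas as pd
import pytest

from methylomix.io import ExpressionMatrix
from methylomix.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def planted_spec() -> CohortSpec:
    """Small cohort with planted DEG/DMG/DMEG and prognostic structure."""
    return CohortSpec(
        n_normal=30,
        n_tumor=30,
        n_genes=150,
        planted_deg=(("G0010", 2.5), ("G0011", -2.5)),
        planted_dmg=(("G0020", "TSS200", -0.4), ("G0021", "Body", 0.4)),
        planted_dmeg=(("G0030", "TSS200", -0.4, 2.5), ("G0031", "TSS1500", 0.4, -2.5)),
        prognostic_genes=(("G0030", -0.8),),
        expr_noise_sd=0.5,
        seed=1234,
    )


@pytest.fixture(scope="session")
def planted_cohort(planted_spec):
    return generate_cohort(planted_spec)


@pytest.fixture()
def tiny_expression() -> ExpressionMatrix:
    """Two normals (2, 4) and three tumors (1.0, 3.5, 2.9) on one checkpoint gene."""
    values = pd.DataFrame(
        {
            "n1": [2.0, 5.0],
            "n2": [4.0, 6.0],
            "t1": [1.0, 7.0],
            "t2": [3.5, 8.0],
            "t3": [2.9, 9.0],
        },
        index=["PDCD1", "OTHER"],
    )
    labels = pd.Series(
        ["normal", "normal", "tumor", "tumor", "tumor"], index=values.columns
    )
    return ExpressionMatrix(values, log_scale=True, group_labels=labels)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
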