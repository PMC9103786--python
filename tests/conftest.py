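import numpy as np
import pandas as pd
import pytest

from wregdiv.expression_io import ExpressionMatrix, SampleSheet
from wregdiv.synthetic_data import SimulationConfig, generate_dataset

ALL_EFFECT_CLASSES = (
    "cis_dominant",
    "trans_dominant",
    "trans_additive",
    "trans_overdominant",
    "trans_underdominant",
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        gene_ids=("g1", "g2"),
        sample_ids=("s1", "s2", "s3"),
        values=np.array([[0.0, 1.0, 2.0], [3.0, 4.0, 5.0]]),
    )


@pytest.fixture
def design_sheet() -> SampleSheet:
    """The study design: 23 chicks, 3 female + 3 male per population except LC (2 F)."""
    rows = []
    for pop, n_f, n_m in (("Cor", 3, 3), ("WL", 3, 3), ("CL", 3, 3), ("LC", 2, 3)):
        for i in range(n_f):
            rows.append((f"{pop}_F{i + 1}", pop, "F", "brain", i + 1))
        for i in range(n_m):
            rows.append((f"{pop}_M{i + 1}", pop, "M", "brain", i + 1))
    return SampleSheet(
        pd.DataFrame(
            rows, columns=["sample_id", "population", "sex", "tissue", "replicate"]
        )
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small noiseless dataset covering every generating class, one tissue."""
    cfg = SimulationConfig(
        class_counts={c: 5 for c in ALL_EFFECT_CLASSES} | {"conserved": 5, "null": 5},
        seed=42,
        noise_cv=0.0,
        tissues=("brain",),
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Moderate-noise dataset used by several recovery-style tests."""
    cfg = SimulationConfig(
        class_counts={c: 30 for c in ALL_EFFECT_CLASSES},
        seed=7,
        noise_cv=0.1,
        baseline_log2_mean=3.5,
        baseline_log2_sd=0.5,
        dominance_excess=3.0,
        replicates={"Cor": 3, "WL": 3, "CL": 3, "LC": 3},
        tissues=("brain",),
    )
    return generate_dataset(cfg)
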