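import numpy as np
import pandas as pd
import pytest

from translatome.expression import ExpressionMatrix, SampleDesign

SAMPLES = [
    ("poly_kd_r1", "knockdown", "polysomal", 1),
    ("poly_ctrl_r1", "control", "polysomal", 1),
    ("poly_kd_r2", "knockdown", "polysomal", 2),
    ("poly_ctrl_r2", "control", "polysomal", 2),
    ("tot_kd_r1", "knockdown", "total", 1),
    ("tot_ctrl_r1", "control", "total", 1),
    ("tot_kd_r2", "knockdown", "total", 2),
    ("tot_ctrl_r2", "control", "total", 2),
]


def make_design(samples=SAMPLES) -> SampleDesign:
    frame = pd.DataFrame(samples, columns=["sample_id", "condition", "fraction", "replicate"])
    return SampleDesign(frame.set_index("sample_id"))


def make_matrix(values: dict, detected: dict | None = None) -> ExpressionMatrix:
    """Build a matrix from {gene: [8 values in SAMPLES order]}."""
    columns = [s[0] for s in SAMPLES]
    frame = pd.DataFrame.from_dict(values, orient="index", columns=columns).astype(float)
    frame.index.name = "gene_id"
    if detected is None:
        flags = pd.DataFrame(True, index=frame.index, columns=frame.columns)
    else:
        flags = pd.DataFrame.from_dict(detected, orient="index", columns=columns).astype(bool)
        flags.index.name = "gene_id"
    return ExpressionMatrix(values=frame, detected=flags)


@pytest.fixture
def design() -> SampleDesign:
    return make_design()


@pytest.fixture
def two_gene_matrix() -> ExpressionMatrix:
    return make_matrix(
        {
            "g1": [200, 100, 210, 105, 100, 100, 110, 110],
            "g2": [50, 100, 40, 100, 100, 50, 100, 40],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
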