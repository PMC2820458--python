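import numpy as np
import pytest

import xchromatin as xc
from xchromatin import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_annotation():
    """Small fly-like genome: five major arms plus the dot chromosome."""
    return xc.make_toy_genome(
        {"X": 30, "2L": 30, "2R": 30, "3L": 30, "3R": 30, "4": 8},
        {"X": 200_000, "2L": 202_000, "2R": 204_000, "3L": 200_000,
         "3R": 198_000, "4": 8_000},
        seed=11,
    )


@pytest.fixture(scope="session")
def array_annotation():
    """10,000-gene genome used for parameter-recovery checks."""
    return xc.make_toy_genome(
        {"X": 2000, "2L": 1980, "2R": 1980, "3L": 1980, "3R": 1980, "4": 80},
        seed=7,
    )


@pytest.fixture(scope="session")
def gene_arms(array_annotation):
    return array_annotation.gene_arms()


@pytest.fixture(scope="session")
def male_h4k16ac_matrix(array_annotation):
    """Normalized male H4K16ac ratio matrix from the planted-effects fixture."""
    effects = xc.reference_effects("H4K16ac")
    batches = xc.simulate_array_batch(
        array_annotation, effects, "H4K16ac",
        sexes=("male",), n_replicates={"male": 4}, seed=42,
    )
    return xc.build_ratio_matrix([batches["male"]])
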