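import numpy as np
import pandas as pd
import pytest

from atlaskit import synthetic_data as sd
from atlaskit.matrix import FpkmMatrix, LibraryInfo


@pytest.fixture(scope="session")
def atlas():
    """One seeded synthetic atlas at the default study conditions."""
    cfg = sd.AtlasConfig(seed=1)
    matrix, truth = sd.generate_fpkm_matrix(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def tiny_matrix():
    """A hand-sized FPKM matrix for arithmetic-level checks."""
    values = pd.DataFrame(
        {
            "lib1": [1.0, 5.0, 50.0, 0.2, 120.0],
            "lib2": [2.0, 5.0, 1.0, 0.9, 80.0],
            "lib3": [3.0, 5.0, 1.0, 0.8, 101.0],
        },
        index=[f"g{i}" for i in range(1, 6)],
    )
    meta = {
        "lib1": LibraryInfo("lib1", "gut", "L5", "P"),
        "lib2": LibraryInfo("lib2", "gut", "A", "S"),
        "lib3": LibraryInfo("lib3", "head", "A", "S"),
    }
    return FpkmMatrix(values=values, library_meta=meta)


@pytest.fixture(scope="session")
def power_track():
    """A seeded heavy-tailed depth track of 10^6 bases."""
    return sd.generate_depth_track(
        n_scaffolds=4, scaffold_len=250_000, total_mapped=5_000_000,
        tail_exponent=1.2, seed=9,
    )
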