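from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from socwage.preprocess import MasterDataset

settings.register_profile("default", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("default")


def random_master(rng: np.random.Generator, n_minor: int = 4,
                  units_per_minor: int = 3, n_per_unit: int = 12
                  ) -> MasterDataset:
    """A small arbitrary modelling table (y need not follow any model)."""
    rows = []
    for i in range(n_minor):
        minor = f"{101 + i:03d}"
        for j in range(units_per_minor):
            unit = f"{minor}{j + 1}"
            for _ in range(n_per_unit):
                rows.append({
                    "age": int(rng.integers(16, 66)),
                    "sex": "male" if rng.random() < 0.5 else "female",
                    "unit_code": unit,
                    "log_wage": float(rng.normal(5.5, 0.6)),
                })
    return MasterDataset.from_modelling_frame(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def small_master(rng) -> MasterDataset:
    return random_master(rng)
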