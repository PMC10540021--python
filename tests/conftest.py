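import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from promcat import (
    CATConfig,
    ItemBank,
    ItemParameters,
    NormalPrior,
    QuadratureGrid,
    make_synthetic_bank,
)


@pytest.fixture(scope="session")
def grid() -> QuadratureGrid:
    return QuadratureGrid.default()


@pytest.fixture(scope="session")
def bank() -> ItemBank:
    """The shipped synthetic 11-item, 7-category bank."""
    return make_synthetic_bank()


@pytest.fixture
def std_prior() -> NormalPrior:
    return NormalPrior(0.0, 1.0)


@pytest.fixture
def dichotomous_item() -> ItemParameters:
    return ItemParameters("d1", a=2.0, thresholds=(0.0,))


@pytest.fixture
def four_cat_item() -> ItemParameters:
    return ItemParameters("q1", a=2.0, thresholds=(-1.0, 0.0, 1.0))


@pytest.fixture
def toy_bank() -> ItemBank:
    """Five 4-category items with spread difficulty, for enumeration oracles."""
    rng = np.random.default_rng(7)
    items = [
        ItemParameters(
            f"t{i}",
            a=float(rng.uniform(1.0, 2.5)),
            thresholds=tuple(np.sort(rng.uniform(-2.5, 2.5, size=3))),
        )
        for i in range(5)
    ]
    return ItemBank(tuple(items))


def random_item(rng: np.random.Generator, n_categories: int | None = None) -> ItemParameters:
    k = n_categories or int(rng.integers(2, 8))
    return ItemParameters(
        f"r{rng.integers(1 << 30)}",
        a=float(rng.uniform(0.5, 3.0)),
        thresholds=tuple(np.sort(rng.uniform(-3.0, 3.0, size=k - 1))),
    )
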