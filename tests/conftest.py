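import numpy as np
import pandas as pd
import pytest

from freezenir.spectra_io import SpectraSet
from freezenir.synthdata import default_config, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_set(rng):
    """5 labeled samples x 10 channels with fish metadata."""
    wl = np.linspace(900, 1700, 10)
    X = 0.5 + 0.1 * rng.standard_normal((5, 10))
    meta = pd.DataFrame(
        {
            "fish_id": ["f1", "f1", "f2", "f2", "f3"],
            "region": ["dorsal", "ventral", "dorsal", "ventral", "dorsal"],
            "replicate": [0, 1, 0, 1, 0],
        }
    )
    return SpectraSet(
        wavelengths=wl,
        absorbance=X,
        sample_ids=[f"S{i}" for i in range(5)],
        labels=["fresh", "fresh", "frozen1", "frozen1", "frozen2"],
        meta=meta,
    )


@pytest.fixture(scope="session")
def default_small():
    """Default-condition synthetic set, 24 samples/class (session-cached)."""
    return generate(default_config(n_per_class=24, seed=7))


@pytest.fixture(scope="session")
def default_medium():
    """Default-condition synthetic set, 60 samples/class (session-cached)."""
    return generate(default_config(n_per_class=60, seed=1))
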