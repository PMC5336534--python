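import numpy as np
import pytest

import hpmcerode as h


@pytest.fixture(scope="session")
def small_invitro():
    """Reduced in vitro dataset: 12 tablets on a 1-h grid (fast fits)."""
    design = h.generate_invitro_design()
    cells = design[design["formulation"].isin(["F3", "F4"])]
    cells = cells[cells["replicate"] <= 2].head(12).reset_index(drop=True)
    X, y = h.simulate_invitro_dataset(design=cells, seed=42,
                                      times=np.arange(1.0, 10.1, 1.0))
    return X, y


@pytest.fixture(scope="session")
def small_invivo():
    """One replicate of the clinical crossover design."""
    X, y, gi = h.simulate_invivo_dataset(seed=11)
    return X, y, gi
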