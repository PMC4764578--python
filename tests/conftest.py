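import numpy as np
import pytest

import thymokinetics as tk


@pytest.fixture(scope="session")
def wt():
    return tk.preset_parameters("WT")


@pytest.fixture(scope="session")
def ko():
    return tk.preset_parameters("Itpkb-KO")


@pytest.fixture(scope="session")
def rag2_wt():
    return tk.preset_parameters("Rag2-WT")


@pytest.fixture(scope="session")
def rag2_ko():
    return tk.preset_parameters("Rag2-ItpkbKO")


@pytest.fixture(scope="session")
def c0_full():
    """The standard anti-CD3 initial condition: a pure DN3 pool of 3e8 cells."""
    return tk.CompartmentState(0.0, 3e8, 0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def acd3_grid():
    """3-hour (0.125-day) output grid over 3 days."""
    return tk.default_acd3_grid()


def max_rel_diff(a: np.ndarray, b: np.ndarray, floor: float = 0.0) -> float:
    """Elementwise relative difference with an absolute floor on the denominator."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    denom = np.maximum(np.maximum(np.abs(a), np.abs(b)), floor)
    denom = np.where(denom == 0, 1.0, denom)
    return float(np.max(np.abs(a - b) / denom))
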