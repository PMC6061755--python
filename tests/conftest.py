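import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from botanicad.chem import MolecularFormula
from botanicad.chromatogram import Trace
from botanicad.synthetic import emg_profile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def zero_baseline():
    def make(trace: Trace) -> Trace:
        return Trace(trace.detector, trace.times,
                     np.zeros_like(trace.intensities))
    return make


@pytest.fixture
def gaussian_trace():
    """Noiseless single Gaussian peak at 5.0 min on a 10 Hz grid."""
    t = np.arange(0.0, 10.0, 1.0 / 600.0)
    y = 100.0 * emg_profile(t, 5.0, 0.05, 0.0)
    return Trace("CAD", t, y)


def random_chno_formula(rng, max_c=50) -> MolecularFormula:
    """A plausible CHNO composition (H drawn within the valence cap)."""
    c = int(rng.integers(5, max_c + 1))
    n = int(rng.integers(0, 4))
    o = int(rng.integers(0, min(20, 2 * c) + 1))
    h_max = 2 * c + n + 2
    h = int(rng.integers(max(1, c // 2), h_max + 1))
    # force integer DBE (even-electron neutral)
    if (h + n) % 2 == 1:
        h += 1 if h < h_max else -1
    return MolecularFormula({"C": c, "H": h, "N": n, "O": o})
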