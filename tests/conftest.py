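import numpy as np
import pytest

from discmeta import load_bundled_effects


@pytest.fixture(scope="session")
def table1():
    """The bundled collection of 14 published time-discounting effects."""
    return load_bundled_effects()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190109)


# (printed z_r, printed SE) for each included fixture row, in row order, as
# published in the summary table of past PET discounting studies; tolerance
# is half a unit in the last printed digit.
PRINTED_TABLE1 = [
    (-0.867, 0.333),
    (-0.01, 0.333),
    (-1.42, 0.333),
    (0.151, 0.333),
    (0.758, 0.267),
    (-0.356, 0.204),
    (-0.181, 0.204),
    (-0.775, 0.378),
    (-0.711, 0.354),
    (0.633, 0.224),
    (-0.050, 0.250),
    (-0.567, 0.277),
    (0.599, 0.218),
    (0.027, 0.097),
]


def printed_tol(x: float) -> float:
    """Half a unit in the last place of a printed decimal."""
    s = f"{x}"
    decimals = len(s.split(".")[1]) if "." in s else 0
    return 0.5 * 10.0 ** (-decimals) + 1e-12
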