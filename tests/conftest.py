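import numpy as np
import pytest

from dosecopula.marginals import to_pseudo_observations

# Published worked examples of historical-unit dose conversion: one tuple per
# printed dose cell (dynasty, raw dose string, grams).  The Song "7 Qian" cell
# is printed as 30 g in the source table, which contradicts the same table's
# Song Qian = 4.0 g (and its own "7.5 Qian = 30 g" neighbour); the arithmetic
# value 28.0 g is asserted for it instead.
TABLE1_DOSES = [
    ("Tang", "3 Liang", 123.93),
    ("Tang", "1 Liang", 41.31),
    ("Tang", "2 Liang", 82.62),
    ("Song", "1 Fen", 0.4),
    ("Song", "7.5 Qian", 30.0),
    ("Song", "7 Qian", 28.0),  # printed 30 g; internally inconsistent (see above)
    ("Yuan", "0.5 Qian", 2.0),
    ("Yuan", "1 Liang", 40.0),
    ("Ming", "1 Liang", 36.9),
    ("Ming", "3 Liang", 110.7),
    ("Qing", "1 Liang and 3 Qian", 47.97),
    ("Qing", "1 Liang and 5 Qian", 55.35),
    ("Qing", "0.5 Liang", 18.45),
    ("Qing", "1 Liang", 36.9),
]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def rank_pseudo(samples: np.ndarray):
    """Rank pseudo-observations from an (n, 2) sample array."""
    return to_pseudo_observations(samples[:, 0], samples[:, 1], method="rank")
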