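import numpy as np
import pytest

from oxyreq import SyntheticSpec, generate
from oxyreq.evaluation import ConfusionTable


@pytest.fixture(scope="session")
def planted():
    """Standard planted fixture: 30 genomes/class, 40 associated domains/class
    at 0.95 in-class / 0.05 out-of-class, 100 background domains, seed 42."""
    spec = SyntheticSpec(seed=42)
    matrix, labels = generate(spec)
    return spec, matrix, labels


# One-step prediction counts (rows = true class, columns = predicted class).
TABLE2_COUNTS = np.array(
    [
        [137, 3, 17],  # aerobe genomes
        [6, 95, 7],  # anaerobe genomes
        [43, 21, 34],  # facultative genomes
    ]
)

# Two-step prediction counts, same layout.
TABLE4_COUNTS = np.array(
    [
        [141, 8, 8],
        [8, 96, 4],
        [47, 18, 32],
    ]
)

CLASSES3 = ("aerobe", "anaerobe", "facultative")


@pytest.fixture
def one_step_confusion():
    return ConfusionTable(CLASSES3, TABLE2_COUNTS.copy())


@pytest.fixture
def two_step_confusion():
    return ConfusionTable(CLASSES3, TABLE4_COUNTS.copy())
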