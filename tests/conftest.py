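import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pathmdd import build_collection, generate_collection


@pytest.fixture
def tiny_collection():
    """Three small hand-made graphs: a triangle, a star and a path."""
    return build_collection(
        [
            ("triangle", ["A", "B", "B"], [(0, 1), (0, 2), (1, 2)]),
            ("star", ["A", "B", "B", "C"], [(0, 1), (0, 2), (0, 3)]),
            ("path", ["C", "A", "B", "A", "C"], [(0, 1), (1, 2), (2, 3), (3, 4)]),
        ]
    )


@pytest.fixture
def seeded_collection():
    """A reproducible synthetic collection for mid-size checks."""
    return generate_collection(n_graphs=4, seed=20260923, n_range=(15, 30),
                               label_pct=0.15)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
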