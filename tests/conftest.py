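import numpy as np
import pytest

from tilring.core_io import ScoreMatrix


@pytest.fixture
def worked_4x3():
    """Small complete grid with strong slide effects and mild reader effects."""
    return ScoreMatrix(
        ("s1", "s2", "s3", "s4"),
        ("r1", "r2", "r3"),
        np.array([[10, 12, 14], [40, 38, 45], [5, 8, 6], [70, 65, 72]], float),
    )


@pytest.fixture
def identical_readers():
    """20 slides, 6 readers, every reader returns the slide's true score."""
    truth = np.arange(5.0, 101.0, 5.0)  # 5, 10, ..., 100
    grid = np.tile(truth[:, None], (1, 6))
    return ScoreMatrix(
        tuple(f"s{i}" for i in range(20)),
        tuple(f"r{j}" for j in range(6)),
        grid,
    )


def random_matrix(rng, n=None, k=None, missing_rate=0.0):
    """Random score matrix helper shared across test modules."""
    n = n or int(rng.integers(3, 31))
    k = k or int(rng.integers(3, 11))
    scores = rng.uniform(0, 100, (n, k))
    if missing_rate:
        mask = rng.random((n, k)) < missing_rate
        mask[mask.all(axis=1)] = False  # keep at least one score per slide
        scores[mask] = np.nan
    return ScoreMatrix(
        tuple(f"s{i:03d}" for i in range(n)),
        tuple(f"r{j:02d}" for j in range(k)),
        scores,
    )
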