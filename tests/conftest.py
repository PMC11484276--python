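import numpy as np
import pytest

from varclade import Alignment, ClassifyConfig
from varclade.synthetic import FixtureSpec, generate_msa

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def small_fixture():
    """A seeded synthetic alignment with truth, shared across tests."""
    spec = FixtureSpec(n_rows=25, L=60, paralog_rows=4, seed=101)
    return generate_msa(spec)


@pytest.fixture
def toy_alignment():
    return Alignment(
        [
            ("ref", "MKVLDHE"),
            ("s1", "MKV-DHE"),
            ("s2", "MKVLDAE"),
            ("s3", "MRVLDHE"),
        ]
    )


@pytest.fixture
def shallow_config():
    """Classification config usable on toy alignments of a few rows."""
    return ClassifyConfig(min_depth=2, max_gap_fraction=0.75)


def random_alignment(rng: np.random.Generator, max_rows=8, max_cols=30):
    """A random gapped/masked alignment with a gapless reference row 0."""
    n_rows = int(rng.integers(2, max_rows + 1))
    n_cols = int(rng.integers(3, max_cols + 1))
    ref = "".join(CANONICAL[i] for i in rng.integers(0, 20, size=n_cols))
    rows = [("ref", ref)]
    for k in range(1, n_rows):
        chars = []
        for c in range(n_cols):
            u = rng.random()
            if u < 0.15:
                chars.append("-")
            elif u < 0.2:
                chars.append("x")
            elif u < 0.6:
                chars.append(ref[c])
            else:
                chars.append(CANONICAL[int(rng.integers(20))])
        rows.append((f"s{k}", "".join(chars)))
    return Alignment(rows)


def random_classify_config(rng: np.random.Generator):
    return ClassifyConfig(
        mode=["strict", "conservation"][int(rng.integers(2))],
        conservation_threshold=float(rng.uniform(0.5, 1.0)),
        adjacency_window=int(rng.integers(1, 4)),
        max_gap_fraction=float(rng.uniform(0.2, 1.0)),
        min_depth=int(rng.integers(1, 6)),
    )
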