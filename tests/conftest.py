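import numpy as np
import pytest

from palmcensus import Field


def random_field(rng: np.random.Generator, n: int, width: float = 2000.0) -> Field:
    """A field of n uniformly scattered localizations, random channels."""
    return Field(
        ids=np.arange(n, dtype=np.int64),
        channels=rng.integers(0, 2, size=n).astype(np.uint8),
        xy=rng.uniform(0.0, width, size=(n, 2)),
        width=width,
        height=width,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


TINY_PDB = """\
HEADER    SYNTHETIC TEST PROTOMER
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       2.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       1.000   3.000   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    """Synthetic 3-residue Cα trace with centroid (1, 1, 0)."""
    p = tmp_path / "protomer.pdb"
    p.write_text(TINY_PDB)
    return p
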