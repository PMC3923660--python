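from pathlib import Path

import pytest

from tcrdesign import make_synthetic_complex
from tcrdesign.packing import RotamerLibrary

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def tripeptide_pdb() -> Path:
    return DATA / "tripeptide.pdb"


@pytest.fixture()
def complex_touching():
    """Two chains in contact (gap 4.5 A): nonzero interface energy."""
    return make_synthetic_complex(seed=1, n_receptor=5, n_ligand=3, gap=4.5)


@pytest.fixture()
def complex_apart():
    """Two chains separated beyond the interface cutoff."""
    return make_synthetic_complex(seed=1, n_receptor=5, n_ligand=3, gap=6.0)


@pytest.fixture(scope="session")
def template_library():
    """Single-conformer library (template pose per amino acid): fast scans."""
    return RotamerLibrary({}, sigma=9.0)
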