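"""Shared fixtures: small synthetic datasets and hand-written format files."""

import numpy as np
import pytest

from dtipred import SyntheticSpec, make_benchmark
from dtipred.alphabet import PSIBLAST_ORDER


@pytest.fixture(scope="session")
def benchmark60():
    """The default 60-pair planted-signal benchmark (12 drugs x 6 proteins)."""
    return make_benchmark(SyntheticSpec())


@pytest.fixture(scope="session")
def benchmark30():
    """A smaller 30-pair planted-signal benchmark for faster model tests."""
    return make_benchmark(
        SyntheticSpec(n_drugs=7, n_proteins=5, n_positive=10, seed=3)
    )


@pytest.fixture()
def sentinel_pssm_file(tmp_path):
    """A 4-residue PSI-BLAST-layout PSSM whose cell values encode their file
    position (row*100 + file-column), so the column permutation is checkable."""
    lines = ["", "Last position-specific scoring matrix computed", ""]
    header = " " * 10 + "  ".join(PSIBLAST_ORDER)
    lines.append(header)
    for i, aa in enumerate("MKVL"):
        cells = " ".join(str((i + 1) * 100 + j) for j in range(20))
        lines.append(f"{i + 1:5d} {aa}  {cells}")
    path = tmp_path / "sentinel.pssm"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
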