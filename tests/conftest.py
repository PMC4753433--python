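import numpy as np
import pytest

from asymx.synthetic import WT_PARAMS, FixtureSpec, fixture_sequence


@pytest.fixture(scope="session")
def wt_params():
    return WT_PARAMS


@pytest.fixture(scope="session")
def fixture_protein():
    """(sequence, peptides) of the 301-residue synthetic fixture."""
    return fixture_sequence(FixtureSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


# minimal synthetic PDB: CA-only trace for residues 47-53, chain A
SYNTHETIC_PDB = "".join(
    f"ATOM  {i + 1:>5}  CA  ALA A{res:>4}    {8.0 + i:8.3f}{4.0:8.3f}{2.0:8.3f}"
    f"{1.00:6.2f}{0.00:6.2f}           C\n"
    for i, res in enumerate(range(47, 54))
) + "END\n"


@pytest.fixture()
def synthetic_pdb(tmp_path):
    path = tmp_path / "synthetic_trace.pdb"
    path.write_text(SYNTHETIC_PDB)
    return path
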