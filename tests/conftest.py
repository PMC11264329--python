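import numpy as np
import pytest

from gvscreen import (
    ECOLI_TABLE,
    NoiseModel,
    ParentCDS,
    WellGrid,
    WellResponse,
)


def parent_with_protein(protein: str, id: str = "custom") -> ParentCDS:
    """Build a parent CDS encoding exactly ``protein`` from preferred codons."""
    assert protein.startswith("M")
    return ParentCDS(
        id=id, sequence="".join(ECOLI_TABLE.preferred(aa) for aa in protein)
    )


@pytest.fixture(scope="session")
def gvpa_like():
    """A 70-codon parent (the gvpA-scale test gene) with T at residue 6."""
    rng = np.random.default_rng(42)
    aas = "ACDEFGHIKLNPQRSTVWY"
    body = "".join(aas[i] for i in rng.integers(0, len(aas), size=69))
    protein = "M" + body[:4] + "T" + body[5:]
    return parent_with_protein(protein, id="gvpA-like")


@pytest.fixture(scope="session")
def gvpb_like():
    """An 87-codon parent with S9, R31, R85 so 'S9G-R31L-R85L' parses."""
    rng = np.random.default_rng(43)
    aas = "ACDEFGHIKLNPQTVWY"  # no R/S so the fixed residues are unique-ish
    body = list(aas[i] for i in rng.integers(0, len(aas), size=86))
    protein = list("M" + "".join(body))
    protein[8] = "S"
    protein[30] = "R"
    protein[84] = "R"
    return parent_with_protein("".join(protein), id="gvpB-like")


@pytest.fixture
def small_grid():
    """2x3 well grid with modest ROIs; fast to render."""
    return WellGrid.standard(n_rows=2, n_cols=3, roi_radius=12, n_background=2)


@pytest.fixture
def noiseless():
    return NoiseModel(background_mean=2.0, speckle=False)


@pytest.fixture
def speckle():
    return NoiseModel(background_mean=2.0, speckle=True)


@pytest.fixture
def gv_well():
    return WellResponse(amplitude=10.0, p_buck=150.0, p_col=300.0, w_col=20.0)
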