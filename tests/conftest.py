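import numpy as np
import pytest

from ntproc.io import load_table1_evidence
from ntproc.physchem import net_charge


@pytest.fixture(scope="session")
def table1():
    """The packaged 58-protein evidence table."""
    return load_table1_evidence()


@pytest.fixture(scope="session")
def table1_path():
    from importlib import resources

    return str(resources.files("ntproc.data") / "table1_evidence.tsv")


def grid_search_pi(peptide, model=None, n_phospho=0, step=1e-4):
    """Independent pI oracle: exhaustive pH grid minimizing |net charge|."""
    grid = np.arange(0.0, 14.0 + step, step)
    charge = net_charge(peptide, grid, model, n_phospho)
    return float(grid[np.argmin(np.abs(charge))])


def random_peptide(rng, min_len=3, max_len=30, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))
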