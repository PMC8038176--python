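import numpy as np
import pandas as pd
import pytest

from dascreen.chem_io import MoleculeRecord
from dascreen.descriptors import DescriptorMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def benzene():
    return MoleculeRecord("benzene", "c1ccccc1")


def make_matrix(values, ids=None, names=None, set_id="synthetic-v1"):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"m{i}" for i in range(values.shape[0])]
    names = names or [f"d{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=ids, columns=names)
    df.index.name = "molecule_id"
    return DescriptorMatrix(df, set_id)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def smi_file(tmp_path):
    """Factory writing a .smi file and returning its path."""

    def _write(lines, name="mols.smi"):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return p

    return _write
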