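"""2D molecular-descriptor matrix and the physicochemical filter profile.

The descriptor set ``rdkit2d-v1`` is the full RDKit 2D descriptor list
(~210 descriptors: constitutional counts, topological indices, fragment
counts, physicochemical estimates) in fixed alphabetical column order.
Descriptors that fail for a molecule are recorded as missing (NaN), never
silently zero, and the missing marker is propagated downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .chem_io import MoleculeRecord
from .moriguchi import mlogp

log = logging.getLogger(__name__)

#: name -> callable for the default descriptor set, frozen alphabetical order
_RDKIT_2D = {name: fn for name, fn in sorted(Descriptors.descList)}

DESCRIPTOR_SETS: dict[str, dict] = {"rdkit2d-v1": _RDKIT_2D}

DEFAULT_DESCRIPTOR_SET = "rdkit2d-v1"


@dataclass
class DescriptorMatrix:
    """Molecules x descriptors table; missing values are NaN.

    ``values`` is a DataFrame indexed by molecule id with descriptor-name
    columns; ``descriptor_set_id`` tags the set and version that produced it
    so templates and queries can be checked for compatibility.
    """

    values: pd.DataFrame
    descriptor_set_id: str

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    def row(self, molecule_id: str) -> pd.Series:
        return self.values.loc[molecule_id]

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "molecule_id", out.index)
        out.to_csv(path, index=False, float_format="%.17g",
                   lineterminator="\n", encoding="utf-8")

    @classmethod
    def from_csv(cls, path: str | Path,
                 descriptor_set_id: str = "external") -> "DescriptorMatrix":
        df = pd.read_csv(path, encoding="utf-8")
        df = df.set_index("molecule_id")
        df.index = df.index.astype(str)
        return cls(df.astype(float), descriptor_set_id)


def compute_descriptors(
    molecules: Sequence[MoleculeRecord],
    descriptor_set_id: str = DEFAULT_DESCRIPTOR_SET,
) -> DescriptorMatrix:
    """Compute the descriptor matrix for a molecule collection.

    Deterministic: repeated calls on the same input give bitwise-identical
    matrices. A descriptor that raises or returns a non-finite value for a
    molecule is set to NaN (missing).
    """
    if descriptor_set_id not in DESCRIPTOR_SETS:
        raise KeyError(
            f"unknown descriptor set {descriptor_set_id!r}; "
            f"available: {sorted(DESCRIPTOR_SETS)}")
    funcs = DESCRIPTOR_SETS[descriptor_set_id]
    names = list(funcs)
    rows = np.full((len(molecules), len(names)), np.nan)
    for i, rec in enumerate(molecules):
        mol = rec.mol
        for j, name in enumerate(names):
            try:
                v = float(funcs[name](mol))
            except Exception:
                log.debug("descriptor %s failed for %s", name, rec.id)
                continue
            if math.isfinite(v):
                rows[i, j] = v
    df = pd.DataFrame(rows, index=[r.id for r in molecules], columns=names)
    df.index.name = "molecule_id"
    return DescriptorMatrix(df, descriptor_set_id)


@dataclass(frozen=True)
class PhyschemProfile:
    """The named physicochemical properties the drug-likeness panel needs.

    mw in g/mol; tpsa in squared angstroms; hbd/hba are Lipinski's original
    counts (OH+NH donors; N+O acceptors); rotb excludes amide C-N bonds;
    wlogp is the Wildman-Crippen atom-contribution logP; mlogp the Moriguchi
    regression logP.
    """

    molecule_id: str
    mw: float
    hbd: int
    hba: int
    rotb: int
    tpsa: float
    wlogp: float
    mlogp: float


def physchem_profile(molecule: MoleculeRecord) -> PhyschemProfile:
    mol = molecule.mol
    return PhyschemProfile(
        molecule_id=molecule.id,
        mw=Descriptors.MolWt(mol),
        hbd=Lipinski.NHOHCount(mol),
        hba=Lipinski.NOCount(mol),
        rotb=Descriptors.NumRotatableBonds(mol),
        tpsa=Descriptors.TPSA(mol),
        wlogp=Crippen.MolLogP(mol),
        mlogp=mlogp(mol),
    )
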