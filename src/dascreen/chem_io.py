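"""Reading and writing molecules and tabular pipeline data.

Molecules come in as SMILES (.smi, whitespace-delimited ``SMILES id`` lines,
``#`` comments allowed) or SDF (V2000). Each record is standardized on read:
the largest organic fragment is kept and charges are neutralized, so that
descriptor values are independent of the salt form a vendor catalog happens
to ship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

log = logging.getLogger(__name__)

# RDKit is chatty about every unparsable block; we log skips ourselves.
RDLogger.DisableLog("rdApp.error")


@dataclass(frozen=True)
class MoleculeRecord:
    """A single molecule with a stable identifier.

    ``smiles`` is canonical (RDKit canonicalization of the standardized
    structure), so equality of records implies equality of structures.
    """

    id: str
    smiles: str
    name: Optional[str] = None

    @property
    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - canonical SMILES always re-parses
            raise ValueError(f"stored SMILES for {self.id!r} failed to parse")
        return m


class MoleculeReadError(ValueError):
    pass


def _standardize(mol: Chem.Mol) -> Chem.Mol:
    """Largest organic fragment + charge neutralization."""
    mol = rdMolStandardize.Cleanup(mol)
    mol = rdMolStandardize.LargestFragmentChooser().choose(mol)
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    Chem.SanitizeMol(mol)
    return mol


def _check_unique_ids(records: list[MoleculeRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise MoleculeReadError(f"duplicate molecule id {r.id!r}")
        seen.add(r.id)


def _read_smi(path: Path) -> tuple[list[MoleculeRecord], int]:
    records: list[MoleculeRecord] = []
    skipped = 0
    index = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        index += 1
        mol = Chem.MolFromSmiles(parts[0])
        if mol is None:
            skipped += 1
            log.warning("skipping unparsable SMILES at %s:%d", path, lineno)
            continue
        mol = _standardize(mol)
        mid = parts[1] if len(parts) > 1 else f"mol_{index}"
        name = " ".join(parts[2:]) if len(parts) > 2 else None
        records.append(MoleculeRecord(mid, Chem.MolToSmiles(mol), name))
    return records, skipped


def _read_sdf(path: Path) -> tuple[list[MoleculeRecord], int]:
    records: list[MoleculeRecord] = []
    skipped = 0
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for index, mol in enumerate(supplier, start=1):
        if mol is None:
            skipped += 1
            log.warning("skipping unparsable SDF block %d in %s", index, path)
            continue
        mol = _standardize(mol)
        mid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not mid and mol.HasProp("ID"):
            mid = mol.GetProp("ID").strip()
        if not mid:
            mid = f"mol_{index}"
        records.append(MoleculeRecord(mid, Chem.MolToSmiles(mol)))
    return records, skipped


def read_molecules(
    path: str | Path,
    format: Optional[str] = None,
    *,
    return_skipped: bool = False,
):
    """Read molecules from a .smi or SDF file.

    Unparsable entries are skipped with a logged warning; ids are taken from
    the file where present, else auto-assigned ``mol_<index>``.

    Parameters
    ----------
    path : file to read (must exist).
    format : ``"smi"`` or ``"sdf"``; inferred from the suffix when omitted.
    return_skipped : also return the number of skipped entries.

    Raises
    ------
    FileNotFoundError : missing file.
    MoleculeReadError : zero parsable molecules, or duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sdf" if path.suffix.lower() in {".sdf", ".sd"} else "smi"
    if format not in {"smi", "sdf"}:
        raise ValueError(f"unknown molecule format {format!r}")
    records, skipped = (_read_smi if format == "smi" else _read_sdf)(path)
    if not records:
        raise MoleculeReadError(f"no molecules could be read from {path}")
    _check_unique_ids(records)
    if return_skipped:
        return records, skipped
    return records


def write_molecules(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write records as a whitespace-delimited .smi file."""
    path = Path(path)
    with path.open("w") as fh:
        for r in records:
            fh.write(f"{r.smiles} {r.id}\n" if r.name is None
                     else f"{r.smiles} {r.id} {r.name}\n")


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as RFC-4180 CSV (UTF-8, header, '.' decimals).

    Floats are written with 17 significant digits so a read-back reproduces
    the values exactly (well inside the 12-significant-digit contract).
    """
    rows.to_csv(path, index=False, float_format="%.17g", lineterminator="\n",
                encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
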