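"""Drug-likeness filter panel: PAINS, Lipinski, Veber, Egan.

Violation counts, not pass/fail flags — a molecule can break several
criteria of one rule. The Lipinski variant tests MLOGP <= 4.15 (the
convention of the SwissADME service, whose output format this panel
mirrors), which is why the descriptor engine carries a Moriguchi logP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from .chem_io import MoleculeRecord
from .descriptors import PhyschemProfile, physchem_profile

# Rule thresholds
LIPINSKI_MW = 500.0
LIPINSKI_MLOGP = 4.15
LIPINSKI_HBD = 5
LIPINSKI_HBA = 10
VEBER_ROTB = 10
VEBER_TPSA = 140.0
EGAN_WLOGP = 5.88
EGAN_TPSA = 131.6


def _pains_catalog() -> FilterCatalog:
    params = FilterCatalogParams()
    params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)  # A+B+C
    return FilterCatalog(params)


_PAINS = _pains_catalog()


@dataclass(frozen=True)
class FilterReport:
    molecule_id: str
    pains: int
    lipinski: int
    veber: int
    egan: int

    @property
    def total(self) -> int:
        return self.pains + self.lipinski + self.veber + self.egan

    @property
    def clean(self) -> bool:
        return self.total == 0


def pains_alerts(molecule: MoleculeRecord) -> int:
    """Number of distinct PAINS patterns (families A+B+C) matched."""
    return len(_PAINS.GetMatches(molecule.mol))


def lipinski_violations(profile: PhyschemProfile) -> int:
    """Rule-of-five violations, MLOGP variant: mw>500, mlogp>4.15,
    hbd>5, hba>10."""
    return sum([profile.mw > LIPINSKI_MW,
                profile.mlogp > LIPINSKI_MLOGP,
                profile.hbd > LIPINSKI_HBD,
                profile.hba > LIPINSKI_HBA])


def veber_violations(profile: PhyschemProfile) -> int:
    """Oral-bioavailability violations: rotb>10, tpsa>140."""
    return sum([profile.rotb > VEBER_ROTB, profile.tpsa > VEBER_TPSA])


def egan_violations(profile: PhyschemProfile) -> int:
    """Passive-absorption (Egan egg) violations: wlogp>5.88, tpsa>131.6."""
    return sum([profile.wlogp > EGAN_WLOGP, profile.tpsa > EGAN_TPSA])


def filter_report(molecule: MoleculeRecord) -> FilterReport:
    prof = physchem_profile(molecule)
    return FilterReport(
        molecule_id=molecule.id,
        pains=pains_alerts(molecule),
        lipinski=lipinski_violations(prof),
        veber=veber_violations(prof),
        egan=egan_violations(prof),
    )


def filter_panel(molecules: Sequence[MoleculeRecord]) -> list[FilterReport]:
    """One report per molecule; deterministic and order-independent."""
    return [filter_report(m) for m in molecules]


def clean_count(reports: Sequence[FilterReport]) -> int:
    return sum(r.clean for r in reports)


def reports_to_frame(reports: Sequence[FilterReport]) -> pd.DataFrame:
    """CSV-ready table with the conventional P/L/V/E column names."""
    return pd.DataFrame(
        {"molecule_id": [r.molecule_id for r in reports],
         "P": [r.pains for r in reports],
         "L": [r.lipinski for r in reports],
         "V": [r.veber for r in reports],
         "E": [r.egan for r in reports],
         "total": [r.total for r in reports]})
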