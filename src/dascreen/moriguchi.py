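"""Moriguchi octanol/water partition coefficient (MLOGP).

The Moriguchi model is a 13-parameter regression on simple structural
counts, fitted on 1230 compounds:

    MLOGP = -1.014
            + 1.244 * CX**0.6   - 1.017 * NO**0.9  + 0.406 * PRX
            - 0.145 * UB**0.8   + 0.511 * HB       + 0.268 * POL
            - 2.215 * AMP       + 0.912 * ALK      - 0.392 * RNG
            - 3.684 * QN        + 0.474 * NO2      + 1.582 * NCS
            + 0.773 * BLM

where
    CX   carbons + halogens, weighted C 1.0, F 0.5, Cl 1.0, Br 1.5, I 2.0
    NO   nitrogen + oxygen atom count
    PRX  N/O proximity: +2 per directly bonded N/O pair, +1 per pair
         separated by one C/S/P atom; -1 per carboxamide or sulfonamide
    UB   unsaturated bonds (double/triple, aromatic rings kekulized),
         excluding the N=O bonds of nitro groups
    HB   dummy: intramolecular hydrogen bond (ortho donor/acceptor pair
         on an aromatic ring, the dominant case in the training set)
    POL  aromatic polar substituents: non-ring N, O, S or halogen
         substituents attached to aromatic carbon
    AMP  amphoteric property: alpha-amino acid 1.0, aminobenzoic or
         pyridinecarboxylic acid 0.5
    ALK  dummy: pure hydrocarbon with zero or one double bond
    RNG  dummy: ring structures other than benzene and fused benzenes
    QN   quaternary nitrogen 1.0, N-oxide 0.5
    NO2  nitro group count
    NCS  isothiocyanate 1.0, thiocyanate 0.5
    BLM  dummy: beta-lactam

The Lipinski variant used by common drug-likeness services tests
MLOGP <= 4.15, which is why this model (rather than an atom-contribution
logP) backs the Lipinski filter here.
"""

from __future__ import annotations

from rdkit import Chem

_CX_WEIGHTS = {6: 1.0, 9: 0.5, 17: 1.0, 35: 1.5, 53: 2.0}

_SMARTS = {
    "carboxamide": Chem.MolFromSmarts("[CX3](=O)[NX3]"),
    "sulfonamide": Chem.MolFromSmarts("[SX4](=O)(=O)[NX3]"),
    "nitro": Chem.MolFromSmarts("[N+](=O)[O-]"),
    "nitro_neutral": Chem.MolFromSmarts("[N;X3](=O)=O"),
    "quat_n": Chem.MolFromSmarts("[NX4+]"),
    "n_oxide": Chem.MolFromSmarts("[#7+][OX1-]"),
    "ncs": Chem.MolFromSmarts("N=C=S"),
    "scn": Chem.MolFromSmarts("[SX2]C#N"),
    "beta_lactam": Chem.MolFromSmarts("[NX3R]1[CX3R](=O)[CR][CR]1"),
    "alpha_amino_acid": Chem.MolFromSmarts("[NX3;H2,H1][CX4][CX3](=O)[OX2H1,OX1-]"),
    "aminobenzoic": Chem.MolFromSmarts("[NX3;H2,H1]c1ccccc1[CX3](=O)[OX2H1,OX1-]"),
    "pyridine_cooh": Chem.MolFromSmarts("[nX2]1ccccc1"),  # combined with acid below
    "aromatic_acid": Chem.MolFromSmarts("c[CX3](=O)[OX2H1,OX1-]"),
    # ortho donor/acceptor pair on an aromatic ring (salicylate-like motif)
    "intra_hb": Chem.MolFromSmarts(
        "[$([OX2H]),$([NX3;H1,H2])]-c:c-[$([OX1]=[C,N,S]),$([OX2]),$([NX2]),$([NX3](=O)=O)]"),
}


def _nitro_count(mol: Chem.Mol) -> int:
    seen = set()
    for pat in (_SMARTS["nitro"], _SMARTS["nitro_neutral"]):
        for match in mol.GetSubstructMatches(pat):
            seen.add(match[0])
    return len(seen)


def _prx(mol: Chem.Mol) -> float:
    """N/O proximity with the carboxamide/sulfonamide correction."""
    hetero = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8)]
    dm = Chem.GetDistanceMatrix(mol)
    prx = 0.0
    for i, ai in enumerate(hetero):
        for aj in hetero[i + 1:]:
            d = dm[ai][aj]
            if d == 1:
                prx += 2.0
            elif d == 2:
                # the bridging atom must be C, S or P
                for nbr in mol.GetAtomWithIdx(ai).GetNeighbors():
                    if nbr.GetAtomicNum() in (6, 16, 15) and \
                            mol.GetBondBetweenAtoms(nbr.GetIdx(), aj) is not None:
                        prx += 1.0
                        break
    prx -= len(mol.GetSubstructMatches(_SMARTS["carboxamide"]))
    prx -= len(mol.GetSubstructMatches(_SMARTS["sulfonamide"]))
    return max(prx, 0.0)


def _unsaturated_bonds(mol: Chem.Mol) -> int:
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    nitro_no = set()
    for pat in (_SMARTS["nitro"], _SMARTS["nitro_neutral"]):
        for n_idx, o1, o2 in kek.GetSubstructMatches(pat):
            nitro_no.update({frozenset((n_idx, o1)), frozenset((n_idx, o2))})
    ub = 0
    for bond in kek.GetBonds():
        if bond.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE):
            key = frozenset((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
            if key not in nitro_no:
                ub += 1
    return ub


def _pol(mol: Chem.Mol) -> int:
    count = 0
    for atom in mol.GetAtoms():
        if atom.GetIsAromatic() or atom.IsInRing():
            continue
        if atom.GetAtomicNum() in (7, 8, 16, 9, 17, 35, 53):
            if any(nbr.GetIsAromatic() for nbr in atom.GetNeighbors()):
                count += 1
    return count


def _is_hydrocarbon_alk(mol: Chem.Mol) -> bool:
    if any(a.GetAtomicNum() not in (1, 6) for a in mol.GetAtoms()):
        return False
    if any(a.GetIsAromatic() for a in mol.GetAtoms()):
        return False
    doubles = sum(1 for b in mol.GetBonds()
                  if b.GetBondType() == Chem.BondType.DOUBLE)
    triples = sum(1 for b in mol.GetBonds()
                  if b.GetBondType() == Chem.BondType.TRIPLE)
    return triples == 0 and doubles <= 1


def _has_non_benzenoid_ring(mol: Chem.Mol) -> bool:
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        benzenoid = (len(ring) == 6
                     and all(a.GetIsAromatic() and a.GetAtomicNum() == 6
                             for a in atoms))
        if not benzenoid:
            return True
    return False


def _amp(mol: Chem.Mol) -> float:
    if mol.HasSubstructMatch(_SMARTS["alpha_amino_acid"]):
        return 1.0
    if mol.HasSubstructMatch(_SMARTS["aminobenzoic"]):
        return 0.5
    # pyridinecarboxylic acid: aromatic acid on a pyridine-type ring
    if mol.HasSubstructMatch(_SMARTS["aromatic_acid"]):
        for match in mol.GetSubstructMatches(_SMARTS["aromatic_acid"]):
            c_arom = mol.GetAtomWithIdx(match[0])
            ring_info = mol.GetRingInfo()
            for ring in ring_info.AtomRings():
                if match[0] in ring and any(
                        mol.GetAtomWithIdx(i).GetAtomicNum() == 7
                        and mol.GetAtomWithIdx(i).GetIsAromatic()
                        for i in ring):
                    return 0.5
    return 0.0


def mlogp(mol: Chem.Mol) -> float:
    """Moriguchi logP of a (sanitized, implicit-H) RDKit molecule."""
    cx = sum(_CX_WEIGHTS.get(a.GetAtomicNum(), 0.0) for a in mol.GetAtoms())
    no = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8))
    prx = _prx(mol)
    ub = _unsaturated_bonds(mol)
    hb = 1.0 if mol.HasSubstructMatch(_SMARTS["intra_hb"]) else 0.0
    pol = _pol(mol)
    amp = _amp(mol)
    alk = 1.0 if _is_hydrocarbon_alk(mol) else 0.0
    rng = 1.0 if _has_non_benzenoid_ring(mol) else 0.0
    qn = 1.0 if mol.HasSubstructMatch(_SMARTS["quat_n"]) else (
        0.5 if mol.HasSubstructMatch(_SMARTS["n_oxide"]) else 0.0)
    no2 = _nitro_count(mol)
    ncs = 1.0 * len(mol.GetSubstructMatches(_SMARTS["ncs"])) + \
        0.5 * len(mol.GetSubstructMatches(_SMARTS["scn"]))
    blm = 1.0 if mol.HasSubstructMatch(_SMARTS["beta_lactam"]) else 0.0

    return (-1.014
            + 1.244 * cx ** 0.6
            - 1.017 * no ** 0.9
            + 0.406 * prx
            - 0.145 * ub ** 0.8
            + 0.511 * hb
            + 0.268 * pol
            - 2.215 * amp
            + 0.912 * alk
            - 0.392 * rng
            - 3.684 * qn
            + 0.474 * no2
            + 1.582 * ncs
            + 0.773 * blm)
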