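"""Reference structures used in tests and worked examples.

SMILES transcribed from the published names of screening hits that were
identified in the source catalog by name (catalog code -> common name):

* PZ0240 — (S)-crizotinib, 3-[(1S)-1-(2,6-dichloro-3-fluorophenyl)ethoxy]-
  5-(1-piperidin-4-ylpyrazol-4-yl)pyridin-2-amine;
* E7887 — quinestrol, the 3-cyclopentyl ether of 17alpha-ethinylestradiol;
* B8063 — BML-210, N-(2-aminophenyl)-N'-phenyloctanediamide;
* J3955 — J-113397, 1-[(3R,4R)-1-(cyclooctylmethyl)-3-(hydroxymethyl)-
  piperidin-4-yl]-3-ethyl-1,3-dihydro-2H-benzimidazol-2-one.
"""

from .chem_io import MoleculeRecord

CRIZOTINIB_S = MoleculeRecord(
    id="PZ0240",
    smiles="C[C@@H](Oc1cc(-c2cnn(C3CCNCC3)c2)cnc1N)c1c(Cl)c(F)ccc1Cl",
    name="(S)-crizotinib",
)

QUINESTROL = MoleculeRecord(
    id="E7887",
    smiles="C#C[C@]1(O)CC[C@H]2[C@@H]3CCc4cc(OC5CCCC5)ccc4[C@H]3CC[C@@]21C",
    name="quinestrol",
)

BML210 = MoleculeRecord(
    id="B8063",
    smiles="Nc1ccccc1NC(=O)CCCCCCC(=O)Nc1ccccc1",
    name="BML-210",
)

J113397 = MoleculeRecord(
    id="J3955",
    smiles="CCN1c2ccccc2N(C2CCN(CC3CCCCCCC3)C[C@@H]2CO)C1=O",
    name="J-113397",
)

NAMED_HITS = [CRIZOTINIB_S, QUINESTROL, BML210, J113397]
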