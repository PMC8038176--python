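"""Build a descriptor template from actives and score candidates with DAS.

The template records, for every molecular descriptor, the mean and
population standard deviation over a set of known actives. A candidate's
DAS is the fraction of its descriptors falling inside mu +/- sigma: 1.0
means template-like on every descriptor, 0.0 means template-like on none.
"""

from dascreen import (MoleculeRecord, build_template, compute_descriptors,
                      das_score)

# a toy chemotype: para-substituted anilides as "actives"
actives = [
    MoleculeRecord("a1", "CC(=O)Nc1ccc(C)cc1"),
    MoleculeRecord("a2", "CC(=O)Nc1ccc(CC)cc1"),
    MoleculeRecord("a3", "CC(=O)Nc1ccc(Cl)cc1"),
    MoleculeRecord("a4", "CC(=O)Nc1ccc(OC)cc1"),
]
candidates = [
    MoleculeRecord("similar", "CC(=O)Nc1ccc(Br)cc1"),   # same chemotype
    MoleculeRecord("remote", "OCC(O)C(O)C(O)C(O)CO"),   # sorbitol
]

template = build_template(compute_descriptors(actives))
print(f"template: {len(template.entries)} descriptors "
      f"from {template.built_from} actives")

queries = compute_descriptors(candidates)
for mid in queries.molecule_ids:
    s = das_score(queries.row(mid), template)
    print(f"{mid:8s} DAS = {s.das:.3f} "
          f"({s.n_in_range}/{s.n_evaluated} descriptors in range)")

# The chemotype neighbour scores well above the polyol. The polyol still
# clears 0.5: most fragment-count descriptors are zero for actives and
# query alike, and a sigma = 0 descriptor matched exactly counts as in
# range — the score separates ranks, it is not a calibrated probability.
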