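# Methods

## Scope and model

`dascreen` implements a ligand-based screening protocol in three stages —
descriptor-template affinity (DAS), expression/chemosensitivity pattern
correlation (Φ), drug-likeness filtering — plus dose-response reduction and
a synthetic-data generator. The target application is prioritizing
candidate modulators of a protein target (the motivating case: the Cdc25
phosphatase family, three isoforms profiled over a 60-line tumor panel)
from a vendor catalog, ahead of structure-based work and wet screening.

The protocol's two scoring ideas are deliberately simple and distribution-
free: DAS counts descriptors inside a one-standard-deviation window rather
than fitting a classifier, and Φ is an L1 distance between max-abs
normalized patterns rather than a correlation coefficient. Both choices
make the scores unit-free and robust to outliers at the cost of
sensitivity; the package implements them exactly rather than "improving"
them.

## Descriptor set

The template score is defined over *some* fixed descriptor set; the
original platform's ~1400-descriptor list is proprietary. This package
uses the open RDKit 2D descriptor list (~210 descriptors: constitutional,
topological, fragment counts, physchem estimates), tagged `rdkit2d-v1`,
with a fixed alphabetical column order. Consequence, stated loudly: DAS
values published for the proprietary set are **not** bit-reproducible
here; the verified surface is the DAS algorithm (oracle equivalence,
bounds, 1/n sensitivity, monotonicity in interval width), not its outputs
on any particular descriptor list. Descriptors that fail for a molecule
are recorded as missing and never imputed.

## DAS conventions

Underspecified corners of the score, resolved as declared package
decisions:

* **Population σ (÷N), not sample σ** — makes the template invariant to
  duplicating the actives set and well-defined for one active (all σ = 0,
  template flagged degenerate).
* **Closed interval with guard ε = max(1e-9, 1e-9·|μ|)** — "within μ ± σ"
  read inclusively; the ε keeps σ = 0 (constant-descriptor) entries
  satisfiable at the boundary under float round-off. Constant descriptors
  are retained: they encode hard constraints of the chemotype.
* **Missing query descriptors shrink the denominator** rather than
  scoring 0, so an engine limitation does not penalize a molecule;
  `n_evaluated` is reported so callers can threshold coverage.

## Pattern ranking conventions

* **Orientation.** Sensitivity must enter on a larger-is-more-sensitive
  scale. The ranking's premise — strong effect where expression is high
  gives low Φ — fails if raw molar GI50 is used (low value = strong
  effect), so `to_oriented` provides −log10(GI50 [M]) and the matrix type
  documents the contract. This is the protocol's largest ambiguity and is
  therefore made explicit in the API.
* **Aggregation order.** Replicate expression experiments are averaged
  per cell line (available-case mean) *before* normalization, per isoform.
* **Panel mismatches.** φ is computed on the intersection of the two
  cell-line panels and refuses to proceed below 2 shared lines, naming the
  mismatched lines — silent imputation would fabricate correlation.
* **Normalization degenerate rule.** A constant pattern maps to all
  zeros. Positive affine invariance (and antisymmetry under negative
  scaling) is property-tested; it is what makes Φ comparable across
  expression platforms.
* **Determinism.** Φ ties break by molecule id; ranks are a permutation
  of 1..N.

## Sensitivity predictor

The upstream platform's antiproliferative predictor is undisclosed. The
module boundary is the contract "per-molecule, per-cell-line oriented
sensitivity": precomputed CSV input bypasses prediction entirely, and a
descriptor-kNN baseline (Euclidean distance over panel-standardized shared
descriptors, inverse-distance weights 1/(d+1e-12), standardization
statistics from the training panel only) stands behind the same contract
for end-to-end runs. The kNN smoke test (out-of-sample r > 0.7 on a
linear-signal synthetic) validates the plumbing, not any pharmacological
claim.

## Drug-likeness panel

Counts are violations per rule family, not pass/fail. Lipinski uses the
MLOGP ≤ 4.15 variant (the convention of the SwissADME service whose output
the panel mirrors), which requires a Moriguchi logP; no installed package
provides one, so it is implemented from the published 13-parameter
regression (weighted C/halogen count to the 0.6 power, N+O count to the
0.9, N/O proximity with amide correction, unsaturation, intramolecular
H-bond dummy, aromatic polar substituents, amphoteric/quaternary-N/nitro/
NCS/β-lactam terms, non-benzenoid ring dummy). Two structural dummies are
approximated with SMARTS where the original publication describes them verbally:
the intramolecular H-bond term matches ortho donor/acceptor pairs on an
aromatic ring (the dominant training-set case), and "aromatic polar
substituents" counts non-ring N/O/S/halogen atoms attached to aromatic
carbon. Spot checks against published model values: benzene 2.28,
glycine −3.8, quinestrol 5.11.

Rotatable bonds follow Veber's original definition (non-ring single bonds
between non-terminal heavy atoms, amide C–N excluded, RDKit's default).
Note one divergence from web-service counters that include amide bonds:
compounds whose rotatable-bond count straddles 10 only when amides are
included (e.g. long-chain dianilides) classify differently under Veber
there; this package keeps the published definition.

PAINS alerts use RDKit's built-in catalog of the published families
A+B+C (480 SMARTS), counting distinct matched patterns.

## Assay reduction

Percent growth uses the standard two-branch formula (relative to control
when the culture grew, relative to time-zero when it shrank; continuous at
the branch point). GI50 interpolates PG = 50 linearly in
**log10(concentration)** between the bracketing adjacent test
concentrations — dose series span orders of magnitude, where linear-in-log
is the standard reading of "linear regression between bracketing
concentrations". An exact PG = 50 point wins; multiple crossings resolve
to the lowest concentration; non-bracketed curves return an explicit
sentinel ("GI50 > 25"), never a number.

## Synthetic-data generator

The generator emulates the three input kinds with a planted,
noise-controlled signal:

* **Chemistry** (descriptor space, not structure space): actives ~
  N(μ_d, σ_d) per descriptor with μ_d ~ U(−10, 10), σ_d ~ U(0.5, 2);
  decoys shifted by 3σ_d with a random fixed sign per descriptor. The
  3σ shift makes the DAS separation sharp (mean gap > 0.4) without being
  degenerate. Defaults mirror the motivating study's conditions: 117
  actives, a 60-label cell panel, isoforms A/B/C with 10/6/10 experiments;
  the screening-catalog stand-in defaults to 1,000 decoys.
* **Expression**: one latent pattern over the panel plus per-experiment
  Gaussian noise (default σ = 0.25 on N(0,1) latent scale, a realistic
  replicate spread). Isoforms share the latent by default so the
  noise-free planted case reaches Φ = 0 exactly; `shared_latent=False`
  gives independent isoform patterns.
* **Sensitivity**: planted molecules follow the mean isoform pattern plus
  N(0, noise_sigma) per line; decoys are panel-independent noise.

**What the generator does not emulate**: real descriptor correlation
structure (descriptors are independent here; real ones are heavily
collinear), heavy-tailed expression noise, batch effects, or any actual
chemistry→sensitivity link. Passing planted-recovery tests therefore shows
the ranking machinery recovers a planted linear signal under Gaussian
noise — not that the protocol finds real modulators.

**Generator-matched cutoff.** An active-like molecule drawn from
N(μ_d, σ_d) falls inside μ ± σ on ≈ 68% of independent descriptors, so its
DAS concentrates near 0.68 and the protocol default cutoff of 0.8 would
empty a synthetic catalog. Synthetic end-to-end runs therefore use 0.5,
which separates actives (~0.68 ± 0.03) from shifted decoys (~0.02)
cleanly. With real, collinear descriptor sets actives score far higher,
which is why the protocol default remains 0.8.

## Problem sizes

Test and example runs use desk-scale sizes chosen to exercise every code
path with comfortable statistics: planted-recovery acceptance uses 10
planted + 200 decoys over 60 lines × 3 isoforms, 50 seeds per noise level
(SE of the recovery fraction ≈ 2%, hence the 0.02 monotonicity slack);
the DAS oracle check runs 1,000 random instances; the end-to-end
determinism check hashes two full screen runs on a 158-molecule catalog.

## Known limitations

* Descriptor-set dependence: DAS values are only comparable within one
  `descriptor_set_id`; the API enforces the tag but cannot detect two
  different sets published under one name.
* MLOGP structural dummies (intramolecular H-bond, amphoteric patterns)
  are SMARTS approximations; molecules dominated by those terms can
  deviate from the original model by a few tenths of a log unit.
* Acceptor counts follow Lipinski's N+O convention; services that exclude
  some N/O contexts can disagree on edge-case molecules.
* The kNN baseline is a placeholder predictor; any serious application
  should supply measured or independently modeled sensitivity via CSV.
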