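# Methods

This note documents the modelling and numerical choices behind `lbvs`:
what each stage computes, the defaults and why, what the synthetic
benchmark does and does not establish, and the known limitations.

## Molecule standardization

Input SMILES/SDF records are parsed and aromaticity-perceived by RDKit.
Standardization then (1) keeps the largest connected fragment by
heavy-atom count — the usual salt/counter-ion strip — breaking equal-size
ties by lexicographically smaller canonical SMILES so the rule is
deterministic; (2) neutralizes charges only where a proton can be added
or removed (carboxylates, alkoxides, thiolates, ammoniums); zwitterions
whose charges cannot be cancelled by a proton transfer are left intact;
(3) re-perceives aromaticity.  Standardization is idempotent.

3D coordinates are taken from the SDF when present; otherwise a
distance-geometry embedding (ETKDGv3 + MMFF relaxation) with a fixed,
caller-supplied seed provides reproducible geometries.  Any reasonable
embedding satisfies the geometric-descriptor contracts; no attempt is
made to reproduce a specific commercial 3D builder.

Supported elements are the common organic subset H, C, N, O, S, P and the
halogens.  Anything else raises an explicit error: silently assigning a
wrong valence degree would corrupt every downstream connectivity and
E-state descriptor.

## Descriptor registry

The registry fixes descriptor order and is versioned (`1.0`, 79 entries)
so feature columns remain stable across releases.  Families:

* **simple (15)** — monoisotopic mass, heavy/element/halogen/H counts,
  bonds, cyclomatic ring count (edges − vertices + components),
  aromatic-atom count, rotatable bonds (acyclic single bonds whose both
  ends have another heavy neighbor), H-bond donors (N/O bearing H) and
  acceptors (all N/O).  The donor/acceptor and rotatable-bond rules are
  deliberately the simplest defensible conventions and are documented
  rather than tuned.
* **topological (7)** — Wiener index, Balaban pruning centric index
  (*Tcent*), Zagreb M1/M2, Platt number, graph radius and diameter.  The
  centric index deletes all degree-1 vertices per step and adds
  (deleted)²; a lone survivor adds 1, a surviving edge 4, and a cyclic
  core of c vertices adds c² — the generalization used for
  ring-containing molecules.
* **connectivity (30)** — ᵐχ and ᵐχᵛ for paths (m = 0–6), star-branched
  clusters and simple rings ("chains", m = 3–6).  Each qualifying
  connected subgraph contributes (Π δᵢ)^(−1/2) over its vertices, with
  δᵛ = valence electrons − attached hydrogens for the valence variants.
  Subgraphs are enumerated exactly (ESU-style growth rooted at the
  minimum edge index) and classified by degree sequence: paths (max
  degree 2), clusters (trees with no degree-2 vertex), chains (simple
  cycles, each counted once — so a fused bicyclic contributes one term
  per constituent simple ring); mixed path/cluster trees and multicyclic
  subgraphs are not indexed.  Vertices with δ = 0 (a lone heavy atom)
  contribute nothing, including to order 0.
* **shape (6)** — Kier ¹κ–³κ with the parity-dependent ³κ formula, plus
  α-modified variants using covalent-radius ratios by element and
  hybridization.  Degenerate denominators (molecules too small to have
  the required path count) yield masked values, not exceptions.
* **estate (16)** — per-atom intrinsic state I = ((2/N)²δᵛ + 1)/δ,
  field perturbation ΔIᵢ = Σⱼ (Iᵢ − Iⱼ)/(dᵢⱼ + 1)², S = I + ΔI, summed
  over a documented coarse atom typing (element × aromaticity × bonding
  pattern).  S(27) is the aromatic-carbon sum.  Pairwise antisymmetry
  guarantees Σ ΔI = 0, which the tests assert to machine precision.
* **geometric (5, require 3D)** — rugosity (*Rugty*), radius of
  gyration, span, solvent-accessible surface area and volume.  Rugosity
  is SASA divided by the surface of the sphere of equal
  solvent-accessible volume: exactly 1 for a single united atom, larger
  for folded surfaces, dimensionless and scale-invariant.  Surface uses
  Shrake–Rupley sampling on a 256-point Fibonacci sphere; volume uses a
  0.4 Å grid; probe radius 1.4 Å (water); united-atom van der Waals
  radii because hydrogens are implicit.  All three are configurable.

Quantum-chemical descriptors are deliberately absent — they need an
electronic-structure engine and contribute nothing to the graph-based
pipeline here.

Missing values (geometric descriptors without coordinates, degenerate
kappas) are masked in the descriptor vector and imputed with training-set
medians before modelling.

## Classifiers

All four classifiers are implemented in this package; scikit-learn
appears only as an independent cross-check in the test suite.

**Random forest.**  `N_tree` CART trees (Gini impurity, unpruned, minimum
node size 1) on bootstrap samples of size n; each node considers `M_try`
features sampled uniformly without replacement.  Scores are vote
fractions; a label is "active" iff score > 0.5, so an exact tie on an
even forest predicts inactive — the conservative choice for screening.
OOB error uses, per training compound, only trees whose bag excluded it;
compounds never out of bag leave the denominator.  Tuning is the
two-stage scan: stage 1 varies `M_try` at a fixed reference forest size
(default 500), stage 2 varies `N_tree` at the winning `M_try`; both
minimize the test-set error rate, with ties broken by lower training
(OOB) error and then by the smaller forest (cheaper to evaluate).  The
tie-break rule is exposed separately (`select_best`) so it is unit
testable on constructed scan tables.  Feature importance is Breiman
permutation importance: per tree, the OOB-accuracy drop when one
feature's values are permuted within the OOB sample, averaged over trees.
Gini-decrease importance was deliberately not used; permutation
importance is the standard forest "contribution rate" and is less biased
toward high-cardinality features.

**SVM.**  RBF kernel k(x,y) = exp(−‖x−y‖²/(2σ²)) (so k(x,x) = 1), with
the γ-parameterization accepted as an alternative.  The dual is solved by
simplified SMO; convergence is a full pass with no multiplier updates at
KKT tolerance 10⁻³, and exhausting the iteration cap raises an error.
The reported score is a logistic map of the decision value — monotone in
the margin and used only for ranking, not as a calibrated probability.

**k-NN.**  Euclidean metric on standardized features; distance ties go to
the lower training index (stable sort), split votes to the nearest
neighbor's class; score = active fraction among the k neighbors.
Default k = 6.

**C4.5-style tree.**  Binary threshold splits on continuous features by
gain ratio (among candidate thresholds with positive gain), then
bottom-up pessimistic pruning: a subtree collapses to a leaf when the
leaf's Clopper–Pearson upper confidence bound on training error (default
confidence 0.25) does not exceed the subtree's summed bound.

**Data handling.**  Splits are stratified by class and seeded; the
training share per class is rounded to the nearest integer (1457
compounds at 2/3 give 971/486).  Standardization is z-scoring with
training statistics only; numerically constant columns are dropped from
both sets.  Labels are fixed to {+1, −1}.

## Evaluation

SE/SP/Q are percentages; MCC uses the standard denominator
(TP+FP)(TP+FN)(TN+FP)(TN+FN).  Zero marginals mask the statistic with a
warning instead of raising.  ROC curves sweep unique scores descending;
tied scores advance as a single threshold step (diagonal segment), which
makes the trapezoidal area identical to the Mann–Whitney pair statistic
with half credit for ties — asserted exactly on 1000 random instances.

## Diversity

D(A) is the mean dissimilarity over ordered pairs.  The package default
dissimilarity is 1 − Tanimoto on hashed linear-path fingerprints (paths
of 1–7 bonds, 2048 bits); any precomputed symmetric matrix with zero
diagonal and entries in [0,1] is accepted, since reasonable practitioners
differ on whether diss should act on fingerprints or descriptors.

## Screening

Both filters are strict inequalities: retained hits have score > 0.7 and
binding energy < −10.0 kcal/mol (both configurable).  Score-filtered hits
are ranked by descending score; energy-filtered hits are re-ranked by
ascending energy (more negative = more stable predicted complex).
Docking itself is out of scope: energies arrive as an id→kcal/mol CSV
from whatever docking program the user runs, and the receptor grid-box
parameters used to produce them are carried in an exportable config block
(`lbvs.screening.DOCKING_BOX`).

## Synthetic benchmark — what it shows and what it does not

`gen_dataset` draws two p-dimensional Gaussian classes (±1) whose means
differ by a separation d (pooled-sd units) on a chosen number of
informative features; covariance is identity or equicorrelated ρ, with a
Student-t (df = 5, unit variance) option for heavy-tail robustness
checks.  The standard benchmark is 500 compounds per class, p = 10, one
informative feature, d = 4 — Bayes error Φ(−2) ≈ 2.3 % — which makes
"test accuracy ≥ 95 %", "|OOB − test error| ≤ 0.03" and "informative
feature ranked first" meaningful, falsifiable checks.  The default test
run and the acceptance script train 300-tree forests on this size; that
is ample for vote and OOB estimates to stabilize at n ≈ 10³.

What passing these tests shows: the forest machinery (bootstrap, random
subspaces, OOB bookkeeping, permutation importance) is implemented
correctly and behaves as the theory predicts on clean data.  What it does
not show: performance on real structure–activity data, where descriptors
are correlated blocks, classes are label-noisy and activity cliffs break
smoothness.  No claim about real-target screening accuracy follows from
the synthetic results.

`gen_library` enumerates analogs of one scaffold at a marked attachment
point, emulating the scaffold redundancy of vendor libraries; its D(A) is
reliably below that of a set of unrelated drugs, reproducing the
qualitative diversity contrast between an analog-heavy screening library
and a curated training collection.

## Numerical and degenerate-input conventions

* Chi contributions skip subgraphs containing a vertex with δ (or δᵛ)
  ≤ 0; a lone-atom molecule gets I computed with δ = 1 in the E-state.
* Kappa with zero path-count denominator → masked, not raised.
* Forest vote tie → inactive; k-NN vote tie → nearest neighbor's class;
  distance ties → lower training index.
* Empty fingerprints are identical by convention (diss = 0).
* Energy filter: hits without an imported energy are excluded and
  counted, never treated as passing.
* All stochastic components (splits, bootstraps, permutations, SMO's
  working-pair choice, embedding) take explicit seeds; identical seeds
  give bit-identical outputs.

## Known limitations

* The descriptor registry is a curated 79-descriptor subset, not an
  exhaustive commercial descriptor suite; the registry version field
  exists so larger sets can be added without breaking column order.
* E-state atom typing is coarser than the full published type table;
  finer types would add columns, not change existing ones.
* The SMO implementation targets the small-to-medium problems used here;
  it has no shrinking or caching and will be slow at n ≫ 10³.
* Tautomer enumeration and stereochemistry-aware standardization are out
  of scope; enantiomers collapse to identical descriptor vectors.
* D(A) values depend on the fingerprint choice; absolute numbers are not
  comparable across dissimilarity definitions, only contrasts computed
  with the same one.
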