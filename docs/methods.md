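# Methods

This note documents the models, conventions and numerical choices behind
`dockface`, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and what the synthetic benchmark
does and does not demonstrate.

## Structures and filtering

Input is standard fixed-column PDB (plain or gzipped), two chains per
complex. Only the first MODEL of a multi-model file is read — a decoy is a
single pose. Author residue numbering and insertion codes are kept
verbatim and form the residue identity `(chain, resSeq, iCode)`; FNAT and
iRMSD match reference and pose residues by this key, so renumbering would
silently break both metrics. Filtering removes hydrogens/deuteriums,
HETATM records and waters, and non-standard residues (MSE and friends are
dropped rather than remapped, because the feature schema is defined over
the 20 standard types). Alternate locations keep altLoc ∈ {'', 'A'}, the
most common convention; the policy is configurable. These policies are
reconstructions — upstream tools rarely document their own.

## SASA, BSA and the ΔG surrogate

Solvent-accessible surface area uses the Shrake–Rupley construction: each
atom's expanded sphere (van der Waals radius + 1.4 Å water probe) is
sampled with a deterministic golden-spiral point set (960 points/atom by
default) and a point counts as exposed when outside every neighbour's
expanded sphere. Per-atom area = (exposed/total) · 4π(r+probe)².
Neighbour search uses a k-d tree restricted to r_i + r_j + 2·probe. A
compiled (numba) kernel evaluates the point tests when available; a pure
numpy path computes identical counts otherwise.

Radii are a Chothia-style protein set (C 1.87 with 1.76 for trigonal/
aromatic carbons, N 1.65, O 1.40, S 1.85 Å) with element fallback, shipped
as an editable text table.

Buried surface area of a residue is ASA(own chain alone) − ASA(complex).
Because the same deterministic quadrature, radii and probe are used in
both evaluations and adding the partner chain can only occlude points,
BSA ≥ 0 holds *exactly*, not just statistically.

The binding-energy estimate is an atomic-solvation-parameter sum,
ΔG = −Σ_atoms σ(class)·ΔASA(atom), with Eisenberg–McLachlan-style
parameters (σ_C = +0.016, σ_N/O = −0.006, σ_S = +0.021, carboxylate
O −0.024, charged N −0.050 kcal·mol⁻¹·Å⁻²). Burying apolar carbon
stabilises (ΔG more negative); burying charged groups is penalised. This
is a rank/sign-faithful surrogate for a full interface thermodynamics
calculation — absolute values are not calibrated against any experimental
ΔG scale, and only the ordering property (tighter, more apolar interfaces
score as more stable) should be relied on.

Note on invariances: translations leave the quadrature geometry unchanged,
so areas are exactly translation-invariant; rotations move atoms relative
to the fixed space-frame point set, so rotation invariance holds only to
quadrature accuracy (≈1% of the total at 960 points). Tests assert the
exact and the approximate invariance separately.

## Interface definitions, hydrogen bonds, salt bridges

Three interface notions coexist, each for its job:

- contact (FNAT): any cross-chain heavy-atom pair ≤ 5 Å — the community
  convention for native-contact counting;
- interface residue (iRMSD): any heavy atom within 10 Å of the other
  chain, evaluated on the reference only so every decoy is measured
  against the same residue set;
- interface residue (features): BSA > 0.1 Å², mirroring the area-based
  interface notion of surface-area pipelines.

All cutoffs are configurable; none is canonical, and the source protocols
for this kind of analysis typically leave them unstated.

Hydrogen bonds are donor-heavy-atom to acceptor-heavy-atom pairs across
chains within 3.5 Å, using shipped text tables (donors: backbone N;
side-chain N/O of R, K, H, W, N, Q, S, T, Y — acceptors: backbone O;
side-chain O of D, E, N, Q, S, T, Y; side-chain N of H). With hydrogens
absent from filtered structures no angular term is possible; this
distance-only criterion over-counts slightly and is documented as an
approximation. Salt bridges pair D/E carboxylate oxygens with K NZ,
R NE/NH1/NH2 or H ND1/NE2 across chains within 4 Å.

## FNAT and iRMSD

FNAT = conserved native contacts / native contacts, intersecting residue
pairs by identity; a pose with no residues in common with the reference
scores 0, and `fnat(ref, ref) = 1` by construction. iRMSD pools the
backbone atoms (N, CA, C, O) of the reference-defined interface residues
from both chains, matches them by (residue, atom name) — atoms missing
from a pose are dropped pairwise with a logged count — and minimises RMSD
with the Kabsch algorithm (SVD with determinant correction, so the
rotation is always proper). For homodimers whose chains have identical
sequence and numbering the chain labelling is arbitrary; both assignments
are evaluated and the more favourable (max FNAT, min iRMSD) reported.

## Categorization and training-set assembly

Native: FNAT > 0.8, or iRMSD < 5 Å. Non-native bands:

| band | FNAT | iRMSD (Å) |
|---|---|---|
| high | [0, 0.25] | [15, ∞) |
| moderate | (0.25, 0.5] | [10, 15) |
| weak | (0.5, 0.8] | [5, 10) |
| mixed | [0, 0.8] | [5, ∞) |

Upper boundaries are half-open against the next band so the three narrow
bands partition the non-native range; FNAT = 0 (zero conserved contacts)
belongs to the high band — it is the most distinguishable pose there is.
A pose in neither the native region nor the requested band is *excluded*
from that scheme's training set.

Each reference contributes a fixed 1:5 block: 2 natives (the reference
plus the best-by-metric decoy passing the native cutoff — a deterministic
rule, since no selection rule is canonical) and 10 non-natives drawn
seeded-uniform from the band. Strict mode errors when the pools are short;
lenient mode returns what exists with a flag.

## The synthetic-data generator

`make_toy_dimer` emulates a compact two-chain complex: each chain is a
self-avoiding random CA walk (3.8 Å steps, centroid-attraction bias for
compactness) dressed with idealized backbone atoms (N, C, O, CB placed in
local frames of the CA trace). Residue types are drawn from a
distribution enriched for the types that dominate real interfaces
(R, D, E, F, Y, I). The second chain is docked by sliding a randomly
oriented copy toward the first along random approach directions and
keeping the orientation with the most residue contacts; the placement
must make ≥ 20% of residues interfacial and carry ≥ 8 contacts (enough
granularity for the FNAT bands), else it is retried. Everything is
deterministic given (n, seed).

`generate_decoys` emulates rigid-body docking output: seeded random
rotations of the ligand about its centroid (0–180°) and translations
(0–25 Å), rejecting poses with cross-chain atoms closer than 2 Å. The
stratified mode cycles a gentle-to-violent proposal schedule (including a
dissociating outward-biased rung) until every FNAT band, every iRMSD band
and the native region hold a quota of poses, and errors naming the empty
bands if the attempt budget runs out.

What the generator does *not* emulate: side chains beyond CB (so
side-chain H-bond and salt-bridge features are rare in synthetic data and
the 210 pair-count features are mostly constant there), real secondary
structure, evolved interface complementarity, and docking-engine pose
distributions. Passing the synthetic benchmark therefore demonstrates the
pipeline's correctness and its ability to separate classes whose
interfaces genuinely differ — it does not certify accuracy on real
PDB-derived corpora, where the discriminating signal is richer.

## Feature schema

274 features, fixed order, versioned: per-residue-type ASA of interface
residues (20), per-type BSA (20), interface residue-type frequencies
pooled over both chains (20, summing to 1 or all zero when no interface),
hydrogen-bond counts per unordered residue-type pair (210), total H-bond
count, salt-bridge count, total interface area (Σ BSA / 2, since both
sides bury the shared area), and ΔG (1 each). The exact feature list of
the original pipeline is not published; this schema reconstructs it from
the documented property categories and is user-overridable. A pose with
no buried residue yields the zero vector plus a `no_interface` flag so
non-binding candidates can still be scored.

Group screening uses a two-sided Mann–Whitney U test per feature
(distributions are non-normal; no test is canonical for this screening)
at α = 0.01 with no multiple-testing correction by default, mirroring
plain per-feature screening practice; Benjamini–Hochberg is available as
an option. Constant features report p = 1.

## Classifier and evaluation protocol

Features are standardized with training-set statistics (constant features
get scale 1). The SVM uses an RBF kernel with C = 10 and γ = 1/n_features
— chosen as sensible library defaults since the original
hyperparameters are not published — and class weights inverse to class
frequency, mirroring the designed 1:5 imbalance without oversampling.
P(native) comes from Platt (sigmoid) calibration fitted on stratified
folds of the training data only.

Evaluation: 100 trials of seeded stratified 80/20 splits (stratification
added because unstratified splits of a 1:5 design are occasionally
single-class), reporting mean ± SD test accuracy (percent, at threshold
0.5) and AUC, plus mean confusion counts at thresholds 0.50–0.95 in
steps of 0.05 — fractional mean counts are meaningful and all derived
metrics (sensitivity, specificity, NPV, precision, F1, MCC) are computed
from them with the 0/0 → 0 convention. All randomness derives from one
master seed (trial i uses seed + i).

## Benchmark problem sizes

The end-to-end synthetic benchmark uses 8 reference dimers of 45
residues per chain per seed, ladders of ≥ 60 stratified decoys with ≥ 10
poses per band, and 100-trial evaluation, repeated over 5 seeds. 45
residues per chain is the smallest size at which random rigid-body poses
can geometrically exceed the 15 Å iRMSD band threshold (the pooled
superposition absorbs roughly half of any ligand displacement, so tiny
complexes cannot reach it); 8 references keep the pooled sets (96
samples) large enough for stable split statistics.

## Known limitations

- Numerical SASA only; no analytic surface, no hydrogen-inclusive areas.
- ΔG is a desolvation-only surrogate: no electrostatics, entropy or
  dissociation barriers.
- Distance-only H-bonds; no π-stacking, cation-π or water-mediated
  interactions.
- Two chains only; no mmCIF; no nucleic acids.
- The synthetic benchmark's caveats above: results there bound what the
  pipeline can do, not what it achieves on real complexes.
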