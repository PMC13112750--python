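# Methods

## Problem setting

The regression target is the ³¹P chemical shift δ (ppm) of a molecule given
only its 2D heavy-atom graph (SMILES). Experimental shift collections
aggregate measurements taken in different solvents, concentrations and
temperatures without recording them, so the labels carry irreducible
(aleatoric) noise on the order of 1–3 ppm for typical compounds; this bounds
achievable accuracy from below. Multiple entries for the same molecule are
kept as independent records — they are legitimate experimental variance, not
duplicates to be merged.

## Network

One MetaLayer-style message-passing round, applied exactly once:

    e′ᵢⱼ = φe(vᵢ, vⱼ, eᵢⱼ, u)                 per directed edge
    v′ᵢ  = φv(vᵢ, mean of incoming e′, u)      per atom
    u′   = φu(mean v′, mean e′, u)             per molecule
    δ̂    = φr(mean of v′ over P atoms, u′)

Each update function is a two-layer perceptron of width `hd` (rectifier on
the hidden layer, linear output). All aggregations are arithmetic means, so
predictions are invariant to atom renumbering and to how a dataset is
partitioned into batches. Atoms with no incoming edges (the PH₃ heavy-atom
graph is a single node) aggregate a zero message.

Design choices that were genuinely open:

- **Update depth and aggregator.** Two-layer perceptrons with mean
  aggregation are the committed interpretation; the three update blocks and
  the readout are isolated behind one interface each so a different variant
  can be swapped in. At `hd`=256 with the realized 42-column node block this
  yields ≈0.57 M trainable parameters.
- **Multi-phosphorus readout.** Datasets provide one shift per record with no
  atom mapping, so the readout averages the updated states of all P atoms.
  This is an approximation for genuinely multi-P molecules.
- **Target standardization.** Shifts span hundreds of ppm; targets are
  standardized with training-split mean/std during optimization and inverted
  exactly at inference (affine round-trip, machine precision).
- **Optimizer.** Adam with decoupled weight decay (the `wd` hyperparameter),
  β=(0.9, 0.999), ε=1e-8; MAE loss (its subgradient `sign(residual)/N` at the
  kink). No dropout. Batch order is reshuffled each epoch from the run's
  master seed, so runs are bit-reproducible.

The forward and reverse passes are plain float64 NumPy; the hand-derived
gradients are validated against central finite differences in the test suite.

## Featurization

29 named node descriptors, 9 edge descriptors, 9 molecule-level descriptors.
Two node descriptors are one-hot groups — formal charge over {−3…+3, other}
(8 columns) and hybridization over {S, SP, SP2, SP3, SP3D, SP3D2, other}
(7 columns) — so the realized node width is 42 columns; the constant lives in
one place (`featurize.NODE_WIDTH`) and each named descriptor maps to a column
slice used by the ablation machinery.

Conventions:

- degrees are heavy-atom degrees (hydrogens implicit);
- "ring size" is the smallest SSSR ring containing the atom/bond, 0 when
  acyclic; a bond is rotatable iff single and not in a ring;
- element-level properties (radii, polarizability, electron affinity,
  electrophilicity, electronegativity, neutron count) come from a bundled
  snapshot CSV of standard reference values, frozen in the package for
  reproducibility; elements absent from the snapshot impute 0 with one
  warning per element;
- Gasteiger charge failures (exotic valences) impute 0, and the "charge
  difference" descriptor follows;
- standardization uses the population standard deviation; zero-variance
  dimensions divide by 1, so constant columns scale to exactly 0. Scalers are
  fitted on the training split only and reused, never refitted, on
  validation/test data.

## Evaluation protocol

Molecule-disjoint repeated splits: records are grouped by canonical SMILES or
by Bemis–Murcko scaffold (all acyclic molecules share the empty scaffold),
groups are shuffled with fold seed `seed + fold`, and 80/10/10 of the
*groups* go to train/validation/test. "Ten folds" means ten independent
repeated splits, not a 10-fold partition. A leakage assertion runs on every
emitted plan. Fold metrics (MAE, RMSE, error quantiles) are aggregated as
mean ± population standard deviation, so a single fold reports ±0.

Grid search enumerates lr ∈ {0.01, 0.001, 0.0001} × wd ∈ {0, 0.0001} ×
bs ∈ {16, 32, 48} × hd ∈ {32, 64, 128, 256} × patience ∈ {40, 200}
(144 combinations) with 3-fold CV and early stopping; epochs are fixed at
500. Ties break toward smaller hd, then larger batch, then lower lr (cheaper
models), then lower wd and patience — deterministic and invariant to grid
enumeration order. Hyperparameter optimization runs on random CV folds;
final testing uses the chemically informed grouped splits.

## HOSE-style baseline

The code of a phosphorus atom at sphere *s* is the canonical fragment SMILES
of all atoms within *s* bonds, rooted at the focus atom, with stereochemistry
excluded and formal charges kept. This gives order-invariant, sphere-refining
codes; unlike classic HOSE strings, boundary atoms are not marked with
open-valence symbols — they appear with their true implicit-H counts, which
slightly increases specificity at truncated spheres. The table stores the
running mean shift and support per (sphere, code) up to sphere 4; prediction
matches the deepest available sphere with fallback 4→3→2→1 and fails
explicitly when sphere 1 is unseen. For multi-P queries, per-atom predictions
are averaged and the molecule fails if any P atom is unmatched. MAE/RMSE are
reported conditional on success, next to the failure rate — the baseline's
headline numbers are therefore optimistic by construction, which is the point
of reporting the failure rate.

## Feature ablation

Importance of a named feature = mean over noise seeds of (MAE with that
feature's standardized columns replaced by N(0,1) draws across the whole test
set) minus (baseline MAE). One-hot groups are ablated jointly. Five seeds by
default; single draws are high-variance. Noise is injected after scaling.

## Chemical validation

- **Subclass table.** SMARTS registry: phosphine `[PX3;!$(P=O)]([#6])([#6])[#6]`,
  phosphine oxide `[PX4](=O)([#6])([#6])[#6]`, phosphonate
  `[PX4](=O)([OX2])([OX2])[#6]`, phosphate `[PX4](=O)([OX2])([OX2])[OX2]`;
  charged = net formal charge ≠ 0; silyl = any P–Si bond. The four
  coordination classes are mutually exclusive on the fixture corpus. Rows
  report n, MAE, RMSE, q50, q95 (linear-interpolation quantiles, so the
  median of an odd-length list is its middle element), plus an all-neutral
  reference row. Empty bins report n=0 with null metrics.
- **Increment model.** δ = B + n_β·A_β + n_γ·A_γ, with n_β/n_γ the carbons at
  heavy-atom shortest-path distance 2/3 from the (single) P atom; ring
  carbons count once at their shortest distance. Ordinary least squares with
  intercept; rank-deficient designs (a series that never varies n_β or n_γ)
  raise a typed error; R² is the coefficient of determination.

## Synthetic fixtures

The generator emits homologous n-alkyl members of six parent classes
(RPH₂, R₂PH, R₃P, R₃P=O, R₃PH⁺, R₄P⁺) with shifts from the increment model
evaluated on the assembled molecule's actual β/γ counts, plus Gaussian label
noise. Defaults: the literature increment coefficients per class (so fixture
shifts are chemically plausible), chains up to length 5, and noise sd 2 ppm,
emulating the 1–3 ppm solvent/condition variability of aggregated
experimental shifts. Substituents are linear chains by default so β/γ
counting is unambiguous; a ring-containing variant (phenyl/cyclohexyl arms,
`ring_fraction`) is opt-in and exists to give scaffold-based splits a
non-degenerate group structure. The generator deliberately does **not**
emulate the real data's extreme shift tails (−457…+800 ppm), its element
breadth (35 element types), fused-ring diversity, or multi-phosphorus
compounds — so green synthetic tests demonstrate that the machinery is
correct and that the model can learn local substituent structure, not that
real-data accuracies transfer.

## Problem sizes and numerical choices in the shipped tests

The test suite trains on synthetic corpora of 50–2,000 records with hd 8–32
and ≤60 epochs — sizes chosen so the whole suite runs in well under a minute
of CPU while still separating a learning model from the constant-mean
baseline by a factor of two. Early stopping uses strict improvement of
validation MAE; with lr=0 training halts after patience+1 epochs with a flat
history. Finite-difference gradient checks run on standardized inputs: raw
feature magnitudes (atomic numbers, radii in pm) saturate the rectifiers and
can park pre-activations exactly on the kink, where the subgradient and a
central difference legitimately disagree.

## Known limitations

- 2D graphs with approximate charges: conformational, through-space,
  counterion and solvent effects are at best coarsely captured by global
  features.
- The experimental-dataset checks (composition counts; k=1000 grouped-split
  accuracy) require the published shift collection at
  `data/ilm_nmr_p31.csv`; it is not redistributable here, so those two tests
  fail with download instructions until it is supplied.
- The update blocks are one committed design among several reasonable ones
  (deeper perceptrons, sum/attention aggregation, per-atom readout are all
  plausible); the block interfaces isolate that choice so variants can be
  swapped in without touching the training or evaluation code.
- HOSE baseline failure behaviour depends on the sphere limit and fallback
  policy; both are explicit parameters here.
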