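# Methods

This note documents the models and procedures implemented in `catscreen`,
the choices made where the underlying workflow left the design open, and
what the synthetic benchmarks do and do not demonstrate.

## Molecule standardization ("wash")

Raw SMILES are standardized before any descriptor is computed:

1. parse; unparseable records are logged, never fatal in library reads;
2. metal–ligand bonds in simple salts are disconnected (RDKit metal
   disconnector);
3. the largest organic fragment is kept — organic (carbon-containing)
   preferred, then most heavy atoms, then most atoms, then smallest
   canonical SMILES. The lexicographic tail exists only to make ties
   deterministic;
4. strong acids are deprotonated and strong bases protonated by the
   SMARTS rule table in `src/catscreen/data/wash_rules.yaml`
   (carboxylic/sulfonic/phosphonic acids; aliphatic amines and
   amidine/guanidine imine nitrogens). Aniline- and amide-type nitrogens
   are deliberately not protonated. Editing the YAML changes the
   chemistry without code changes.

The operation is idempotent, and every washed molecule is a single
connected component. Commercial "wash" implementations use richer
pKa perception; exact parity with any of them is not claimed.
Tautomer enumeration, stereochemistry normalization, and 3D force-field
minimization are out of scope — every descriptor in the package is
topological/2D, so 3D geometry would be dead weight.

Duplicate structures are merged *after* washing, by canonical SMILES.

## Descriptor blocks

**CATS2D** (implemented from definition). Each heavy atom receives a
subset of six generalized pharmacophore types — donor D, acceptor A,
positive P, negative N, hydrophobe H, aromatic R — from the SMARTS table
in `data/cats_types.yaml`. For each of the 21 unordered type pairs and
each topological distance bin the number of atom pairs is counted,
giving a 21 × 10 = 210-vector. Conventions:

* distance bins default to d = 0…9 bonds; d = 0 counts single atoms
  carrying both types of a pair (e.g. a hydroxyl oxygen contributes to
  DA at d = 0). The alternative 1…10 origin is available via
  `d_start=1` — the binning origin is a known ambiguity of the
  descriptor family, so it is exposed rather than guessed silently;
* each unordered atom pair contributes at most once per distinct
  unordered type pair (DA and AD are the same cell);
* raw integer counts by default; optional scaling divides each
  type-pair slice by the summed occurrence counts of its two types
  (slices with absent types stay zero).

**MACCS**: the public 166-key MDL set, via RDKit (its placeholder bit 0
is dropped).

**PHYS2D**: an open block of 36 RDKit 2D physicochemical and topological
descriptors (size, Crippen logP/MR, H-bond counts, TPSA, flexibility,
ring counts, charge, Kier–Hall connectivity and kappa shape indices,
Balaban J, Bertz complexity, Labute ASA). It plays the role a
proprietary 2D property block plays in commercial pipelines; parity with
any vendor's values is explicitly not claimed.

## Dataset curation

Activity records (IC50 / Ki / KD / EC50, nM) are validated, averaged
per unique washed structure by arithmetic mean **on the nM scale**
(fidelity to the usual curation practice of averaging replicate
activities before transformation), labeled *positive* at ≤ 100 nM
(boundary inclusive, so a compound measured exactly at the threshold
counts as highly active), and log-transformed as
pActivity = 9 − log10(nM) = −log10(molar). Mixed endpoint types for one
structure are pooled with a warning — no inter-endpoint conversion is
attempted.

The train/test split maximizes training-set coverage of descriptor
space with Kennard–Stone max–min selection on standardized descriptors:
start from the two mutually most distant compounds, repeatedly add the
compound farthest from the selected set. A seeded permutation breaks
distance ties, making the split reproducible. Train size is
⌊fraction · N⌋ (80% of 1,259 compounds → 1,007 / 252).

A consequence worth knowing: Kennard–Stone sends the extreme points to
the training set, so the test set is interior and has deliberately
reduced variance. Test-set R² under a KS split is therefore
structurally pessimistic; the parameter-recovery benchmarks below use a
random held-out split for that reason.

## Random-forest models and statistics

Classification (highly vs lowly active) and regression (pActivity) both
use random forests: 500 trees, √p features per split, unlimited depth,
mandatory seed. Tree count is the only hyperparameter the benchmarks
override (100–300 trees) to keep desk-scale runs fast; results are
insensitive to it well before 500.

Statistics follow the standard definitions: SE = TP/(TP+FN),
SP = TN/(TN+FP), Q = (TP+TN)/(TP+TN+FP+FN) (percent); ROC AUC is the
Mann–Whitney probability that a random positive outscores a random
negative (ties ½); R² = 1 − Σ(ŷ−y)²/Σ(y−ȳ)², RMSE = √mean((y−ŷ)²);
cross-validated Q² and RMSE_CV use the pooled out-of-fold predictions.

Cross-validation is stratified for classification, plain K-fold for
regression (5 folds default). Fold aggregation reports both the mean ±
SD of per-fold statistics and the statistics of the fold-averaged
confusion counts: mean-of-ratios and ratio-of-means differ slightly and
published tables rarely say which they used, so both are available and
neither is adjudicated.

**Recursive feature elimination** drops the lowest-importance 10% of
surviving features per round until ≤ 60 remain, then one per round to
the target — coarse early, fine near the optimum, so the Q²-vs-k
profile has resolution where it matters. The profile (one entry per
elimination state) is recorded on request.

**Applicability domain** (standardization approach): for query k and
descriptor i, S_ki = |x_ki − mean_i| / sd_i with training-set mean and
sample (n−1) SD. Inside if max_i S_ki ≤ 3; outside if min_i S_ki > 3;
otherwise inside iff mean(S_k·) + 1.28 · sd(S_k·) ≤ 3. The 3 and 1.28
constants follow the published standardization recipe but are exposed
as parameters since variants exist. Zero-variance training descriptors
are excluded with a warning. AD verdicts are attached to screening
output for reporting; they filter only when explicitly enabled, since
the domain check is a reliability annotation, not a potency criterion.

## Screening cascade

Lipinski profile: violations of {MW > 500, logP > 5, HBD > 5,
HBA > 10}, logP by Crippen atom contributions; compounds violating more
than two rules are removed. Classification stage: three RF classifiers
(CATS, MACCS, PHYS2D); by default the **union** of positive votes
advances — any single representation can rescue a compound, which
maximizes scaffold diversity (intersection is available for stricter
screens). Regression stage: the PHYS2D RF regressor predicts pActivity;
compounds at or above the cutoff (default 7.0 = 100 nM; `top_n` as an
alternative) are ranked descending. Libraries are deduplicated by
canonical SMILES before screening. The SPR utility K_D = k_off / k_on
(molar) completes hit characterization. Note that one published
description of a confirmed binder rounds this ratio inconsistently
(4.48×10³ and 1.42×10⁻³ give 3.17×10⁻⁷ M = 317 nM, sometimes quoted as
370 nM); the arithmetic here follows the rate constants.

## Scaffolds and SOM selection

Bemis–Murcko scaffolds (RDKit) keep ring systems plus inter-ring
linkers; acyclic molecules yield the empty scaffold and are reported,
not dropped. Exocyclic double bonds attached to rings remain in the
scaffold (the common convention). Carbon skeletons replace every
heteroatom by carbon and every bond by a single bond, with aromaticity
dropped and hydrogens re-derived — topologically equivalent frameworks
collapse together, so unique skeletons can never outnumber unique
scaffolds.

The SOM is a seeded Kohonen map written in numpy: default 3 × 5 grid,
1,000 epochs of online training in seeded shuffled order, learning rate
0.5 with linear decay to 0, Gaussian neighborhood with radius
max(rows, cols)/2 decaying exponentially to 0.3 cells, codebook
initialized uniformly within the per-feature data range. Training on
multiple identical rows aborts (zero variance is pathological); a
single sample trains to the fixed point. Known actives and screened
hits are co-projected (CATS descriptors); hits in cells containing at
least one active are eligible, and selection walks eligible cells
round-robin, taking the highest-predicted-pActivity hit each visit and
preferring scaffolds not yet selected while the cell offers one. All
tie-breaks are deterministic, so selection is invariant to input order.

## Synthetic data: what it emulates, what it does not

`generate_library` assembles molecules from a fragment grammar (8 ring
systems, 6 linkers, 15 substituents by default): ring (+ optional
linker + second ring) + 0–3 substituents, washed, deduplicated by
canonical SMILES, with the ground-truth scaffold class recorded. Same
seed, same output.

`generate_qsar_dataset` plants a sparse linear signal:
pActivity = intercept + β·z + ε with z the z-scored values of
`n_informative` descriptor columns (default 20, over CATS + PHYS2D),
ε ~ N(0, 0.3), values clipped to 0.001–9,900 nM and labeled at 100 nM.
Defaults mirror a curated bioactivity compilation (n = 1,259, ~61%
active). Two deliberate design rules keep the benchmark meaningful:

* *eligibility* — informative columns must vary in ≥ 10% of the library
  (a non-modal value in at least 10% of molecules). A "signal" planted
  on a descriptor only a handful of molecules possess is carried by
  those few samples and is unrecoverable by any method;
* *effect sizes* — |β| ~ Uniform(0.5, 1.5) with random sign, so every
  planted feature contributes materially; a near-zero coefficient would
  make the feature informative in name only.

The intercept is calibrated against the realized noisy scores, so the
observed active fraction matches the target exactly.

`planted_screen_benchmark` builds a screening deck (default 1,000
molecules) in which exactly 50 carry the active signature — the top
scores under a sparse linear model over the physicochemical block —
plus a matching training table. The score-to-potency link inserts a
2-log-unit deadband at the threshold: hidden actives sit at ≤ 10 nM,
background at > 1 µM, emulating the bimodal potency structure of real
actives-vs-decoys benchmarks (confirmed actives are rarely borderline).
The training table is enriched to ~50% actives by oversampling
signature carriers from a larger pool, as curated training compilations
are; the screened deck keeps its rare (5%) signature rate. The signal
lives in the physicochemical block because that is the block the
regression stage reads — a benchmark whose generative signal is
invisible to the scoring model would test nothing.

What passing these benchmarks shows: the pipeline recovers planted,
learnable structure — washing preserves molecules, descriptors are
computed correctly, RFE finds real signal carriers, the cascade ranks
signature molecules first. What it does not show: performance on real
bioactivity data, whose descriptor–activity relationship is nonlinear,
assay-noisy and scaffold-clustered in ways the linear generator does
not emulate; published headline statistics on proprietary compound
collections are not reproducible from synthetic data and are not
claimed.

## Problem sizes and numerics

Benchmarks run at desk scale on one CPU: recovery at n = 1,000
compounds × 210 CATS features, 10 generative seeds for feature
retention, 5 for held-out R²; the cascade benchmark at 1,000 library /
600 training molecules with 150-tree forests. Degenerate inputs are
handled explicitly: zero-variance descriptors are excluded from
standardization and AD; empty libraries and single-class training sets
raise typed errors; unparseable SMILES carry the offending string.
Seeds are mandatory wherever randomness exists (RF, splits, SOM,
generators); all reported quantities are reproducible bit-for-bit given
the seed.

## Known limitations

* Acid/base rules are a minimal curated table, not full pKa perception.
* PHYS2D is an open substitution; models trained on it are not
  comparable number-for-number with pipelines using proprietary blocks.
* The Kennard–Stone split is deterministic up to distance ties; with
  heavily duplicated descriptor rows the tie permutation matters.
* The SOM uses online (not batch) training; different epoch/decay
  settings give different but equally valid maps — only seeded runs are
  comparable.
* The fragment grammar spans a narrow, lead-like chemistry; property
  distributions of commercial screening decks are not matched.
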