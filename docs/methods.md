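# Methods

## Problem setting

Four homologous kinase targets are modelled jointly as a multitask
regression of pIC50 (`9 − log10(IC50/nM)`, i.e. −log10 of the molar
IC50). Labels are sparse: each compound carries measurements for an
arbitrary subset of the targets. The package's premise is that the
targets are related enough — correlated activities, overlapping
chemistry — that a shared molecular representation helps the sparsely
labelled ones.

## Curation

Structures are standardized with the cheminformatics toolkit's
normalizer (functional-group normalization, then largest-fragment
desalting, then charge neutralization), and the canonical SMILES is the
unique key. Duplicates merge per target by keeping the **lowest IC50**
(the most potent measurement) before log conversion. Rejected rows are
reported with reasons, never silently dropped. The split is a seeded
random partition at ratios 0.8/0.1/0.1; validation and test sizes are
rounded to the nearest integer and the remainder goes to training, so
the partition is disjoint and exhaustive and exactly reproducible from
the 64-bit seed.

## Graphs and featurization

Molecules become directed attributed graphs: every bond is stored in
both directions so neighbor attention treats incoming edges uniformly.
The default schema has 39 atom features (element one-hot over 15
symbols + other, heavy-atom degree 0–5, formal charge, hybridization,
aromaticity, total H count 0–4, tetrahedral chirality tag) and 10 bond
features (type, conjugation, ring membership, E/Z stereo) — the
canonical attentive-fingerprint featurization. Chirality and bond
stereo are encoded so enantiomers and cis/trans isomers yield different
tensors. The schema is declarative; its hash is stored in checkpoints
and checked on load.

## Network

- Input projection: `h = LeakyReLU(x W + b)` into a `graph_feat_size`
  dimensional state (default 300; desk-scale experiments use 40).
- Attentive layers (default 2): per directed edge `j→k`, logit
  `LeakyReLU(a^T [W h_k || W h_j])`, softmax-normalized over `k`'s
  neighbors; the attended context is an attention-weighted sum of
  neighbor messages (neighbor state, optionally concatenated with the
  bond features — on by default), and the node state is updated with a
  GRU. Atoms without bonds receive a self-loop with zero bond features
  so single-heavy-atom molecules remain scorable.
- Readout (default 2 timesteps, parameters shared across timesteps): a
  super-node initialized to the mean atom state attends over the
  molecule's atoms with the same logit form and is GRU-updated; the
  per-atom readout attention is retained for interpretation.
- Heads: dropout (training only) on the molecule embedding, then one
  linear output per target.

LeakyReLU slope is 0.01 throughout. Parameters are Glorot-uniform
initialized from the model seed. Labels are z-scored per target on the
training split (means/scales stored with the model and inverted at
inference); this keeps early optimization well-conditioned without
changing the reported units.

The loss is masked MSE: the mean of squared errors over all labelled
(molecule, target) entries in the batch. Unlabelled entries contribute
exactly zero loss and zero gradient (verified as an invariant). The
per-entry mean (rather than a per-task mean of means) is the simplest
unbiased form.

### Autodiff engine

No tensor-autodiff library is part of the package's dependency set; the
network runs on `mtqsar.tensor`, a ~300-line reverse-mode engine over
NumPy float64 arrays (matmul, broadcasting arithmetic, elementwise
nonlinearities, concat, row gather, segment sum/mean/softmax). The
softmax max-shift is treated as a constant, which is exact for the
gradient. Gradients of every composite expression used by the network
are tested against central finite differences. Single-threaded float64
makes training bitwise reproducible for fixed seeds.

## Training

Adam (β = 0.9/0.999, ε = 1e-8) with additive L2 weight decay. Library
defaults mirror standard practice for this architecture family:
learning rate 1e-3, weight decay 1e-6, batch size 256, up to 1000
epochs, early stopping with patience 20 on the **global validation R²**
(unweighted mean over targets with ≥2 labelled, non-constant validation
entries). The returned parameters are the snapshot from the best
monitored epoch, never a later one. Non-finite loss aborts with a
diagnostic.

Random hyperparameter search draws from the classic grids (learning
rate {0.1, 0.01, 0.001, 0.0001}, dropout {0.2–0.5}, batch {64, 128,
256}) at a reduced per-trial epoch budget, ranks trials by validation
R², and emits the full trial table; the final fit re-trains at full
budget.

Y-randomization permutes labels **within each target column** over the
labelled rows of the train and validation splits (the mask pattern is
fixed, so per-task sample sizes and label multisets are conserved),
retrains from scratch with a per-round seed, and records train and
validation R². The original matrices are untouched.

## Evaluation

R² uses the total-sum-of-squares denominator; MAE and RMSE are the
usual masked means. Global metrics are the unweighted mean across
targets (per-target metrics on labelled entries only); a pooled
aggregation over all labelled entries is available as an option and is
more stable when a target has very few labelled molecules in a split —
per-target R² on fewer than ~10 points is noise-dominated and is
reported as such, not suppressed. Threshold AUC binarizes the *truth*
at pIC50 6 (active iff IC50 ≤ 1 µM, boundary inclusive) and ranks the
continuous predictions with midrank tie handling, which equals the
Mann–Whitney U statistic normalized by n₊·n₋.

The optional baseline trains one LightGBM regressor per target on
1024-bit radius-2 Morgan (ECFP4-equivalent) fingerprints over the
identical split; targets with fewer than 10 training labels are skipped
with a warning entry.

## Interpretation

Two attribution routes sit behind one interface. The default,
**readout attention**, averages the super-node's per-atom attention
over readout timesteps — nonnegative, summing to one per molecule, and
shared across heads. **Gradient saliency** backpropagates a head's
output (or the sum over heads) to the initial atom embeddings and takes
per-atom L2 norms; it is head-specific. Weights are min-max normalized
per molecule for display (constant vectors map to 0.5); atoms above
the molecule mean are *key atoms*. Region importance uses a one-sided
Wilcoxon rank-sum test (region stochastically greater than the rest):
exact by full enumeration of group assignments for combined samples of
≤12 atoms (ties handled by half-credit in the U statistic), normal
approximation with tie correction above that. Both normalized and raw
region means are reported since either convention appears in practice.
Because single small molecules give the test little power, the
validation experiments pool region/complement weights across all test
molecules containing the planted group.

## Applicability domain

`d_ave` and `θ` are the mean and standard deviation (population form)
of each training compound's distance to its **nearest other** training
compound; the threshold is `D_T = d_ave + Z·θ`, and a query is
in-domain iff none of its k nearest training distances exceeds `D_T`.
Distances operate on radius-2, 2048-bit Morgan fingerprints
(configurable) with two selectable kernels: `1 − Tanimoto` (default)
and Euclidean normalized by √n_bits. Both live in [0, 1], so
thresholds are comparable across kernels; raw Euclidean distance on
long bit vectors would not produce the sub-0.2 `d_ave` magnitudes
typical of published domain analyses, which motivated the normalized
variants. The (k, Z) sweep reports out-of-domain counts and, when
predictions are supplied, ID/OD-partitioned metric tables.

## Synthetic fixtures

The generator assembles molecules from six heteroaromatic scaffolds
(quinazoline, pyrimidine, pyridine, purine-like, thiazole, benzene)
with two substitution slots drawn from 22 medicinal-chemistry
substituents, standardizes and deduplicates them. Activities are
additive in pIC50: base 5.0, a small fixed per-target offset, the sum
of matched pharmacophore effects, plus Gaussian noise (default sd 0.3,
a typical inter-laboratory IC50 reproducibility scale). Default planted
effects: sulfonamide +2.0, piperazine +1.5, amide +1.0, nitrile +0.6,
trifluoromethyl −0.8. A `shared_effect_fraction` (default 0.6) controls
how many effects act on all targets versus a single owner target,
which sets the inter-task correlation (≈0.8 at defaults); per-target
label missingness defaults to (0.4, 0.2, 0.65, 0.8), emulating a panel
with two densely and two sparsely assayed members. Matched atom indices
per pharmacophore are recorded as attribution ground truth.

What the fixtures do **not** emulate: real binding physics (activity
cliffs, scaffold-dependent effects, 3D shape), inter-assay systematic
shifts, and chemical-series redundancy. Passing tests therefore
demonstrate that the machinery works and recovers planted mechanisms at
realistic noise — not that any particular real-data accuracy will be
achieved.

## Desk-scale study conditions

The validation experiments (`mtqsar.experiments`) use a 40-unit trunk,
2 attentive layers, 2 readout timesteps, dropout 0.1, Adam at 3e-3
with batch 64 for 60 epochs — sizes chosen so a full experiment
(library generation, training, evaluation) completes in minutes on a
single CPU while leaving clear headroom between signal and noise:

- attention normalization: 100 molecules, untrained model;
- multitask benefit: n = 400, one target thinned to 10% label density,
  multitask vs single-task at identical budget, 3 seeds, median test
  R² on the sparse target;
- Y-randomization: n = 240, 3 shuffle rounds vs the unshuffled fit;
- attribution recovery: n = 240, 5 seeds, pooled rank-sum on the
  planted sulfonamide region;
- fixture benchmark: n = 300, one multitask fit plus the LightGBM
  baseline and the 1 µM AUC.

## Known limitations

- Pure-NumPy training is CPU-bound; hundreds of molecules and a
  40–64-unit trunk are comfortable, tens of thousands of molecules at
  width 300 are not the intended scale of this implementation.
- Global R² is an unweighted mean over targets: a target with a
  handful of labelled molecules in a split adds large variance to the
  global number (use the pooled option for a stable summary).
- Attention attribution is shared across heads by construction;
  per-target attribution requires the saliency route.
- The applicability domain is purely structural (fingerprint
  distances); it does not see the model's own uncertainty.
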