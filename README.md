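# mtqsar

Multitask attentive graph-network QSAR for kinase selectivity profiling.

Designing inhibitors that hit one kinase isoform of a closely homologous
family (the canonical case: JAK1/JAK2/JAK3/TYK2) requires predicting a
compound's potency against *all* members at once, from sparse and noisy
multi-source IC50 data. `mtqsar` is a library for that workflow: it
curates multi-target activity tables into pIC50 datasets, trains one
graph-attention regressor with a shared trunk and a linear head per
target, evaluates and stress-tests the model, attributes predictions to
atoms, and gates predictions with a distance-to-model applicability
domain.

## The model

Molecules are attributed graphs (atoms: element, degree, charge,
hybridization, aromaticity, H count, chirality; bonds: type,
conjugation, ring, E/Z stereo). Each atom state `h_k` repeatedly
aggregates neighbor messages through softmax attention

    alpha_{k<-j} = softmax_j( LeakyReLU( a^T [W h_k || W h_j] ) )

followed by a GRU state update; an attentive readout over a virtual
super-node produces the molecule embedding, and per-target linear heads
emit predicted pIC50 (`pIC50 = 9 − log10(IC50/nM)`). Training minimizes
a masked MSE — only (molecule, target) pairs with an experimental label
contribute — so sparsely assayed targets borrow representation from
densely assayed ones. Validation tools include Y-randomization
(label-shuffled refits), per-target and global R²/MAE/RMSE, active/
inactive AUC at the 1 µM threshold, attention- and gradient-based atom
attribution with one-sided rank-sum substructure tests, and a k-NN
applicability domain with threshold `D_T = d_ave + Z·θ` on Morgan
fingerprint distances.

The network and its training loop run on the package's own small
reverse-mode autodiff tensor engine (`mtqsar.tensor`, pure NumPy,
float64, single-threaded), so results are exactly reproducible from
seeds; gradients are verified against finite differences in the test
suite.

A synthetic-fixtures module generates kinase-inhibitor-like libraries
with *planted* pharmacophore effects, partially shared across targets,
so every claim (multitask benefit, attribution recovery, randomization
collapse) can be tested against known ground truth without downloading
anything.

## Worked example

```python
from mtqsar.synthetic import FixtureSpec, make_fixture_dataset
from mtqsar.network import MTModelConfig
from mtqsar.training import GraphDataset, TrainConfig, train, evaluate_split

spec = FixtureSpec(n_molecules=200, seed=7)
records, _ = make_fixture_dataset(spec)          # curated, split records
dataset = GraphDataset(records, list(spec.targets))
state, history = train(
    dataset,
    MTModelConfig(targets=spec.targets, graph_feat_size=40, dropout=0.1, seed=7),
    TrainConfig(learning_rate=3e-3, batch_size=64, max_epochs=60, patience=59, seed=7),
)
print(evaluate_split(dataset, state, "test"))
```

prints (about a minute on one CPU):

```
[test] global: r2=0.629  mae=0.419  rmse=0.561
  JAK1: n=14  r2=0.678  mae=0.472  rmse=0.597
  JAK2: n=16  r2=0.721  mae=0.358  rmse=0.504
  JAK3: n=8  r2=0.514  mae=0.311  rmse=0.490
  TYK2: n=7  r2=0.605  mae=0.536  rmse=0.653
```

Per-target rows are masked metrics over the labelled test compounds of
that target; the global row is their unweighted mean. With label noise
of 0.3 pIC50 units on roughly one unit of planted signal, R² around
0.6–0.75 is close to the attainable ceiling — the model has learned the
planted structure–activity relationships. The scripts under `examples/`
walk through each capability one at a time (curation, training,
interpretation, applicability domain, chemical-space diagnostics,
Y-randomization) and print a line or two explaining every number.

A thin CLI mirrors the library (`mtqsar curate|fixtures|train|evaluate|
yrand|interpret|ad|chemspace`); run `mtqsar --help`.

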