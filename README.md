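# p31shift

Prediction of ³¹P NMR chemical shifts from 2D molecular graphs, for
cheminformatics and synthetic-chemistry workflows where a fast, data-efficient
shift estimate is more useful than a DFT calculation.

³¹P is a sensitive, 100 %-abundant nucleus, but open experimental shift data
is scarce (~10⁴ values, versus ~10⁵ for ¹³C). `p31shift` implements a
**small-data graph neural network**: a single MetaLayer-style message-passing
round over the heavy-atom molecular graph,

- edge update &nbsp; e′ᵢⱼ = φe(vᵢ, vⱼ, eᵢⱼ, u)
- node update &nbsp; v′ᵢ = φv(vᵢ, mean⟨e′·ᵢ⟩, u)
- global update u′ = φu(mean⟨v′⟩, mean⟨e′⟩, u)
- readout &nbsp;&nbsp;&nbsp;&nbsp;&nbsp;&nbsp; δ̂ = φr(mean over phosphorus v′, u′)

where each φ is a two-layer perceptron of width *hd*. The single round
restricts each phosphorus node's receptive field to one bond plus a
molecule-level state — a deliberate locality constraint that keeps the model
in the 10⁴–10⁵ parameter range and resistant to overfitting on small
training sets. Nodes carry 29 named descriptors (atomic identity, element
reference properties, hybridization, ring membership, Gasteiger charge, …),
bonds 9, and the molecule 9 (TPSA, molar refractivity, aromatic content, …);
all blocks are standardized with training-split statistics only. Training
minimizes the mean absolute error (MAE, ppm) with decoupled-weight-decay
Adam, early stopping on a validation split, and best-epoch restore.

Alongside the network the package provides:

- a **HOSE-style lookup baseline** (canonical sphere-environment codes with
  4→3→2→1 fallback and explicit failure accounting),
- **molecule-disjoint evaluation**: repeated 80/10/10 splits grouped by
  canonical SMILES or Bemis–Murcko scaffold, with a built-in leakage guard,
- **grid search** over (lr, wd, bs, hd, patience) with 3-fold CV,
- **noise-injection feature ablation** (ΔMAE per named descriptor),
- **chemical-consistency validation**: SMARTS subclass error tables
  (phosphines, phosphine oxides, phosphonates, phosphates, charged, P–Si)
  and recovery of the classical substituent-increment model
  δ = B + n_β·A_β + n_γ·A_γ (deshielding β-effect, shielding γ-effect),
- a **synthetic fixture generator** (homologous organophosphorus series with
  increment-model shifts) so everything is testable without downloading the
  experimental dataset.

The network, its optimizer, and the hand-derived reverse pass are plain
float64 NumPy; gradients are verified against finite differences in the test
suite. Molecular handling is RDKit throughout.

## Worked example

```python
import numpy as np
from p31shift import (
    gen_toy_dataset, build_graphs, make_splits, train_model, mae,
    TrainConfig, SDGNNConfig, gen_increment_series, fit_increment_model,
)
from p31shift.fixtures import SeriesSpec
from p31shift.io import parse_molecule

# 1. substituent-increment recovery on primary phosphines
spec = SeriesSpec.from_literature("RPH2", max_chain=4)
series = [(parse_molecule(r.smiles), r.shift_ppm) for r in gen_increment_series(spec)]
fit = fit_increment_model(series)
print(f"B = {fit.B:.1f} ppm, A_beta = {fit.A_beta:.1f} ppm, "
      f"A_gamma = {fit.A_gamma:.1f} ppm, R^2 = {fit.r_squared:.3f}")

# 2. train a small model on synthetic fixtures and score a held-out split
toy = gen_toy_dataset(1000, seed=0)
graphs, _ = build_graphs(toy.records)
split = make_splits(toy.records, "smiles_group", n_folds=1, seed=0)[0]
model, history = train_model(
    graphs, split,
    TrainConfig(lr=0.01, wd=0.0, bs=32, patience=15, epochs=60, seed=0),
    SDGNNConfig(hidden_dim=32, seed=0),
)
test = [g for g in graphs if split.assignment[g.record_id] == "test"]
y = np.array([g.y for g in test])
print(f"trainable parameters: {model.n_parameters}")
print(f"best epoch: {history['best_epoch']}")
print(f"held-out MAE: {mae(y, model.predict(test)):.2f} ppm")
```

prints

```
B = -163.5 ppm, A_beta = 35.5 ppm, A_gamma = -7.0 ppm, R^2 = 1.000
trainable parameters: 13633
best epoch: 19
held-out MAE: 1.82 ppm
```

The first block generates the MePH₂…n-BuPH₂ homologous series from the
literature increments for primary phosphines, refits the increment model by
least squares, and recovers the generating coefficients exactly (β-carbons
deshield by +35.5 ppm, γ-carbons shield by −7.0 ppm). The second block trains
a 13k-parameter network on 1,000 synthetic records and predicts held-out
molecules (disjoint by canonical SMILES) to within ~1.8 ppm — on par with the
2 ppm label noise the generator injects.

## Command line

```bash
p31 fixtures --n 1000 --seed 7 --out fx.csv      # synthetic dataset + truth sidecar
p31 ingest fx.csv --out clean.csv                # validate/normalize a dataset
p31 train --config cfg.yaml --out model.json     # one grouped-split training run
p31 predict --model model.json --in clean.csv --out preds.csv
p31 hose-train clean.csv --out table.json        # lookup-baseline table
p31 hose-predict --table table.json --in clean.csv --out hose.csv
p31 ablate --model model.json --test clean.csv --seeds 5 --out ablation.csv
p31 chemcheck --predictions merged.csv --out report.json
```

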