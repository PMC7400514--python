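# tilexpr

Weakly-supervised, multi-task regression of per-sample gene expression from
bags of whole-slide-image tile features, with:

- **supertile preprocessing** — spatial k-means over tile coordinates with
  feature averaging, plus gene filtering (nonzero median) and
  `log10(1 + a)` normalization;
- **a per-tile MLP regression core** — one shared network applied to every
  tile, trained with stochastic top-k aggregation (a single k drawn per
  optimizer step from a list L) and evaluated with a deterministic multi-k
  average, which is equivalent to a fixed rank-weighted mean of tile scores;
- **empirical-null significance testing** — per-gene Pearson correlations on
  patient-grouped CV folds, p-values against an untrained-model null,
  Holm–Šidák / Benjamini–Hochberg corrections per cohort, and a
  pathway-vs-random-gene-lists resampling test;
- **virtual spatialization** — per-tile score maps for gene sets, validated
  by tile-level correlation, percentile-threshold AUCs, top-tile summaries
  and per-slide region-overlap AUCs, rendered as TSV + PNG heatmaps;
- **representation transfer** — a two-hospital experiment where an
  expression regressor trained at hospital A provides a latent
  representation that improves small-cohort binary classification at
  hospital B, against raw-feature and autoencoder baselines, with a
  bootstrap split harness and Wilcoxon comparisons;
- **a synthetic-data module** — seeded desk-scale cohorts (spatially
  coherent tile types, composition-linked expression, patient hierarchy,
  composition-linked binary labels) so the whole pipeline runs with no
  external data.

All neural components are small dense networks implemented on NumPy
(float64, fully seeded, CPU-only), so results are bit-reproducible.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(aggregation oracle equivalence, AUC/Wilcoxon enumeration oracles,
multiple-testing calibration, parameter/spatial recovery, pathway-test
calibration, the transfer crossover, and an end-to-end CLI smoke test).
The recovery, calibration and transfer tests train many small models and
take several minutes each on one CPU.

## CLI

Every subcommand writes its artifacts plus a `run_manifest.json` (inputs,
config hash, seed, versions). A full synthetic run:

```sh
tilexpr simulate   --out runs/sim --seed 0
tilexpr preprocess --bags runs/sim/bags.h5 --expression runs/sim/expression.tsv \
                   --out runs/prep --n-clusters 100
tilexpr train      --bags runs/prep/supertiles.h5 --expression runs/sim/expression.tsv \
                   --genes runs/prep/genes.txt --out runs/train
tilexpr predict    --bags runs/sim/bags.h5 --model runs/train/model.npz --out runs/pred
tilexpr spatialize --bags runs/sim/bags.h5 --model runs/train/model.npz \
                   --genes SIG000 --out runs/spat
tilexpr significance --bags runs/prep/supertiles.h5 --expression runs/sim/expression.tsv \
                   --manifest runs/sim/manifest.tsv --out runs/signif
tilexpr transfer   --bags runs/sim/bags.h5 --expression runs/sim/expression.tsv \
                   --manifest runs/sim/manifest.tsv --labels runs/sim/patient_labels.tsv \
                   --out runs/transfer
```

Exit codes: 0 ok, 2 usage/config error, 3 data error, 4 numeric failure.

## Layout

```
src/tilexpr/
  synthetic.py       seeded cohort generator (+ slide-level nuisance factors)
  preprocessing.py   gene filter, log transform, Otsu tissue mask,
                     tile subsampling, supertiles, mean pooling
  nn.py              minimal dense-network core (backprop, Adam, dropout)
  aggregation.py     top-k training/inference aggregation and rank weights
  model.py           regression model, training loop, CV, checkpoints
  significance.py    folds, correlations, empirical null, HS/BH, pathway test
  spatialization.py  score maps, validation metrics, heatmap rendering
  transfer.py        two-hospital experiment, baselines, split harness, Wilcoxon
  presets.py         pinned desk-scale experiment configurations
  cli.py             click CLI (simulate/preprocess/train/predict/
                     spatialize/significance/transfer)
  io.py              HDF5 bag container, TSV/GMT/JSON readers and writers
```
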