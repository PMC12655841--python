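# dooit

Dual-Objective Optimization with ITerative feature pruning (DOO-IT): a
QSPR model-selection framework for predicting the solubility of
pharmaceutical acids in deep eutectic solvents (DESs), built on nu-support
vector regression and COSMO-RS molecular descriptors.

## The problem

Deep eutectic solvents — mixtures of a hydrogen-bond acceptor (choline
chloride, menthol, ...) and a hydrogen-bond donor (glycerol, glycols, ...)
— are tunable green solvents for poorly water-soluble drugs. Screening the
combinatorial space of solute x HBA x HBD x ratio x temperature
experimentally is expensive, so quantitative structure–property models are
fitted to measured log mole-fraction solubilities, `log x`, using
physically meaningful descriptors from COSMO-RS computations:

* five energetic descriptors per species — total interaction energy
  `E_int`, its misfit, hydrogen-bonding and van der Waals components, and
  the chemical potential `mu`; solvent values are mole-fraction-weighted
  over the solute-free mixture, and solute-minus-solvent differences give
  Δ-prefixed relative descriptors;
* a 61-point σ-potential curve per species on the screening-charge
  density grid [-0.03, +0.03] e/Å², reduced to 12 region descriptors
  (HBD1–4, HH1–4, HBA1–4) by averaging over 0.005-wide intervals;
* the COSMO-RS computed solubility `log(x^COSMO)` itself.

This yields descriptor **set 1** (16 energetic + computed-solubility
columns) and **set 2** (set 1 plus the 12 relative Δσ descriptors; 28
columns).

## The method

For a candidate feature subset, a nuSVR with RBF kernel is tuned by a
seeded random search over (nu, C, log10 gamma-scale), where gamma is
anchored at the median heuristic `gamma_base = 1 / median ||x_i - x_j||²`.
Each trial is scored by 5-fold cross-validation on two competing
objectives: **CV MAE** (accuracy) and the **support-vector ratio**
(complexity; nu lower-bounds it). The non-dominated trials form a Pareto
front; the **1-SE rule** picks the simplest front member within one
standard error of the most accurate one. Features are then ranked by
**permutation importance** (10 repeats) on a seeded carve-out of the
training split, the weakest is dropped, and the search repeats down to a
minimum feature count — one candidate model per complexity level.

The whole run is repeated on many random 80/20 splits. Aggregation across
runs gives, per descriptor count, its frequency and mean ± SD test MAE;
counts with frequency ≥ 30% within one SE of the best form the stable
"basins". Finalists there are ranked by a composite score — 0.5 ×
accuracy + 0.3 × R² + 0.2 × generalization (train/test gap), each min–max
normalised in the cohort — with near-ties broken by descriptor stability.

## Worked example

```python
from dooit import DooIt, RunConfig
from dooit.synthetic import SyntheticSpec, generate

spec = SyntheticSpec(n_records=150, n_features=6, informative_indices=(0, 3),
                     effect_sizes=(1.0, 0.6), seed=5)
table, truth = generate(spec)                      # truth: x00, x03
cfg = RunConfig(min_features=3, n_runs=3, n_trials=20, master_seed=7)
res = DooIt.from_descriptor_table(table, feature_set="custom", config=cfg).fit()
print(res.summary())
```

prints (abridged):

```
DOO-IT model selection results
==============================
runs: 3    master seed: 7    records: 150
 n_features  frequency  n_runs_with  mean_test_mae  sd_test_mae  mean_train_mae selected
          3     1.0000            3         0.1876       0.0163          0.1895        *
          4     1.0000            3         0.2049       0.0414          0.1941
          5     1.0000            3         0.1999       0.0230          0.1877
          6     1.0000            3         0.1911       0.0365          0.1974        *

Final model
-----------
descriptors (6): x00, x01, x02, x03, x04, log_x_cosmo
cv_mae=0.2390 (+/- 0.0116 SE)  sv_ratio=0.3729
train_mae=0.2003  test_mae=0.1586  train_r2=0.9593  test_r2=0.9538
composite score: 0.8189 (accuracy 1.000, r2 1.000, generalization 0.094)
```

The basin table shows which model sizes recur across the independent
splits and how well they generalise; the final-model card reports the
winning candidate's descriptors, hyperparameters, hold-out metrics and
composite-score breakdown. `res.predict(new_frame)` scores new records
with the selected model.

The same pipeline is scriptable from the shell:

```bash
dooit simulate --out data --n-records 200 --n-features 8 --seed 1
dooit run --features data/features.csv --out campaign \
          --n-runs 3 --n-trials 50 --seed 1
dooit report --runs campaign/runs --out campaign/basin.csv
```

and `dooit featurize` assembles the set-1/set-2 tables from raw
`species_energetics.csv`, `sigma_potentials.csv` and `solubility.csv`
inputs.

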