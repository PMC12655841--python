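# Methods

## Model and procedure

The package selects a nu-support-vector regression (RBF kernel) model of
decadic log mole-fraction solubility, `log x`, of pharmaceutical acids in
deep eutectic solvents, from COSMO-RS-derived descriptors. Selection is
dual-objective: predictive error (cross-validated MAE) and model
complexity (support-vector ratio) are minimised jointly, and feature
subsets are explored by iterative backward pruning. The assumptions are
those of any QSPR study of this kind: records are exchangeable across
random splits, descriptors computed for the neutral solute form carry the
dominant signal, and the nuSVR with an RBF kernel is flexible enough that
model choice reduces to hyperparameters and descriptor subset.

One run proceeds as follows on a fresh random 80/20 train/test split:

1. **Search.** For the current feature subset, draw hyperparameter
   triples (nu, C, log10 gamma-scale) from a seeded random-search sampler
   and score each by k-fold cross-validation on the training split only,
   recording mean fold MAE and mean fold support-vector ratio (support
   vectors / fold-training samples). The kernel width is
   `gamma = gamma_base * 10^scale` with `gamma_base` the inverse median
   pairwise squared Euclidean distance of the standardized training
   features (the median heuristic), so the scale search spans four
   decades around a data-driven anchor.
2. **Front and 1-SE.** Keep the non-dominated (MAE, SV-ratio) trials;
   take the front member with minimal CV MAE, compute the standard error
   of its fold MAEs (sample SD / sqrt(k)), and select the front member
   with the lowest SV ratio among those within one SE (ties: lower MAE,
   then lower trial id).
3. **Prune.** Refit the selected model on the full training split for
   train/test metrics; rank features by permutation importance (mean MAE
   increase over 10 seeded shuffles) evaluated on a 20% seeded carve-out
   of the training split (the model used for importance is fitted on the
   other 80%, so the validation rows are out-of-sample; the test split is
   never touched before final metrics); drop the least important feature
   and return to step 1 until `min_features` (default 3) remain.

Runs are repeated `n_runs` times (default 50). Aggregation yields, per
descriptor count, its frequency across runs and the mean ± SD of test
MAE. Counts with frequency ≥ 30% and mean test MAE within one SE (at the
minimising count, SE = SD / sqrt(runs at that count)) of the minimum are
architecturally admissible. All candidates at admissible counts are
scored by the composite 0.5·accuracy + 0.3·R² + 0.2·generalization;
composite totals within `tie_delta` (default 0.01) of the best are
resolved by descriptor stability — the mean cross-run occurrence
frequency of the candidate's features at its count.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_trials` | 2000 | hyperparameter draws per search |
| `folds` | 5 | CV folds inside each trial |
| `n_runs` | 50 | independent 80/20 splits |
| `min_features` | 3 | pruning floor |
| `n_permutation_repeats` | 10 | shuffles per feature |
| `freq_threshold` | 0.30 | stability gate on descriptor counts |
| `composite_weights` | 0.5/0.3/0.2 | accuracy / R² / generalization |
| `nu_bounds` | [0.05, 0.95] | nu search box |
| `c_bounds` | [1e-2, 1e3] | C search box (log-uniform) |
| `log10_gamma_scale_bounds` | [-2, 2] | gamma scale around the anchor |
| `train_fraction` | 0.8 | split proportion |

Energies pass through in the units of the source tables; solubility
logarithms are decadic. Search bounds bracket the hyperparameter optima
typical for standardized descriptor matrices of this size (nu ≈ 0.25,
C in the tens, gamma scale ≈ 0.5–1).

## Design choices where the design was open

* **Sampler.** The dual-objective search uses a seeded random-search
  sampler over the configured box. Random search is reproducible, has no
  cross-trial state, and for the 3-dimensional, fairly smooth objective
  surfaces here covers the box well at the default trial counts; every
  downstream component consumes only the completed trial list, so a
  model-based sampler could be substituted without interface change.
* **Bin edges.** σ-potential bins are half-open `[lo, lo + 0.005)` with
  the last bin closed at +0.03, so the uniform 61-point grid distributes
  5 points per bin with the +0.03 endpoint joining bin 12. Grid points
  within 1e-9 of an edge are treated as on the edge (float grids place
  edge values a few ulp off).
* **Feature sets.** Only the 12 *relative* (solute minus mixture-weighted
  solvent) Δσ descriptors enter set 2, giving 16 + 12 = 28 columns —
  consistent with the winning published models containing only Δ-prefixed
  σ descriptors.
* **Standardization.** Fold-wise refit of the scaler inside CV is the
  default (no leakage from held folds); a "global" mode scaling once per
  training split is available and is the choice when mirroring the
  original protocol. `gamma_base` is always computed on the standardized
  training features.
* **1-SE rule SE.** The SE is the sample SD (ddof = 1) of the best
  trial's fold MAEs over sqrt(k).
* **Importance data.** Permutation importance is evaluated on a seeded
  20% carve-out of the training split; using the test split would leak
  selection information into the reported hold-out metrics.
* **Composite normalisation.** Min–max within the finalist cohort for all
  three components; the generalization component uses |test − train| MAE,
  penalising over- and under-fitting symmetrically. A single-member
  cohort (or zero spread) maps every component to 1.
* **Failed trials** (solver exceptions) are recorded with `failed`
  status and excluded from fronts rather than given penalty objectives.
* **Seeds.** All randomness derives from one master seed via a
  splitmix64 hash chain: per-run split seeds, per-level fold and
  carve-out seeds, and sampler streams are all independent and
  reproducible; derived seeds stay below 2^31.
* **Run count.** 50 independent runs is the default; it is a config knob
  (`n_runs`) rather than a fixed constant.

## Synthetic data: what it emulates and what it does not

`dooit.synthetic.generate` draws a block-correlated Gaussian feature
matrix (blocks of three consecutive features with within-block
correlation ρ, mimicking the solute/solvent/relative triplication of the
energetic descriptors), a response `-3 + Σ effect_i · x_i (+ optional
quadratic/interaction terms) + N(0, noise_sd)` on a realistic `log x`
scale, and optionally replaces the last feature by a computed-solubility
proxy with a requested correlation to the noiseless signal. `noise_sd`
may be left unset and is then solved in closed form for a target
population R² given the effects and the block covariance. Defaults
mirror the study scale: 1020 records, 16 features, 4 informative.

The generator reproduces the *statistical* obstacles of the real problem
— collinear descriptor blocks, a sparse signal, a strong proxy column,
noise — but not its chemistry: no temperature structure, no shared
solute/solvent identities across records, no heteroscedastic measurement
error, no σ-potential physics. Passing tests therefore demonstrate that
the machinery finds sparse signal under collinearity and noise, not that
any particular descriptor matters for real DES systems.

## Numerical choices and degenerate inputs

* nuSVR solver tolerance 1e-3 (`svr_tol`), unlimited iterations by
  default (`svr_max_iter = -1`).
* Constant training columns are dropped from standardization with a
  warning; an all-constant matrix is an error, as is a
  duplicate-dominated matrix whose median pairwise distance is zero.
* `gamma_base` uses a seeded 2000-row subsample beyond 2000 training
  rows to bound the O(n²) distance computation.
* Pareto-front ties on both objectives are all retained; equal-MAE
  groups keep only their minimal-SV members.
* Importance ties are broken by feature order (first minimum is pruned).
* Split sizes use `round(n * train_fraction)` (1020 → 816/204).

## Problem sizes used by the test suite

The suite runs on one CPU; simulation sizes are chosen so the full run
finishes comfortably while leaving each property detectable: unit tests
use 150–500 records and 10–60 trials; the nuSVR-contract battery checks
120 trials on 200 records; the parameter-recovery experiment runs 5
dataset seeds × one pruning run × 60 trials per search on 500 records
with 16 features (4 informative, ρ = 0.5, noise solved for R² = 0.95),
requiring ≥ 3 of 4 true features at the 4-feature level in ≥ 80% of
seeds. Full-protocol reproduction (50 runs × 2000 trials on the
reference descriptor table) is implemented but requires that table to be
supplied externally; the corresponding test reports the missing input
otherwise.

## Known limitations

* Random search explores the hyperparameter box less efficiently than a
  model-based sampler at equal trial counts; conclusions about *which*
  basin wins on small trial budgets are noisier than the published
  full-scale protocol.
* The SV-ratio objective is nearly proportional to nu (nu lower-bounds
  it), so the complexity axis of the front largely orders models by nu;
  this matches the intended parsimony semantics but means the front's
  shape is partly mechanical.
* Permutation importance on correlated features splits credit across a
  block; with very high ρ the pruned member of a block is close to
  arbitrary, which is precisely the instability the multi-run frequency
  analysis is designed to expose.
* The composite score is only defined relative to its cohort; totals are
  not comparable across campaigns.
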