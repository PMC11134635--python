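# Methods

## Pipeline model

The package treats retrospective virtual screening as a four-channel
measurement problem. Each channel produces one raw score per compound:

| channel        | raw score                                                | orientation |
|----------------|----------------------------------------------------------|-------------|
| qsar           | measured pIC50 of the actives                            | higher better |
| similarity     | max ECFP4 Tanimoto to cluster-representative actives     | higher better |
| pharmacophore  | RMSE of 2D feature-family counts vs cluster consensus    | lower better |
| docking        | binding affinity (kcal/mol), ingested from CSV/Vina logs | lower better |

pIC50 = 6 − log10(IC50/µM), log base 10 (the standard potency convention).
Curation keeps the largest organic fragment (ties broken by canonical-SMILES
order), neutralizes charges with RDKit's uncharger, canonicalizes, and merges
duplicates keeping the first-seen id. Stereocenters are retained as written;
no stereo enumeration or protonation-state assignment is attempted (both
need 3D/pKa machinery out of scope here).

For each channel a regression model is selected from a twelve-model zoo and
used to predict the channel score for *every* compound, actives and decoys
alike; the four prediction vectors are oriented (lower-better channels
negated), z-scored over the pooled screening set, and combined as a weighted
mean with each channel weighted by its best model's W_new. Ranking is by
descending weighted mean, ties broken by compound id.

## W_new

W_new collapses R²_train, R²_val, MAE, RMSE and MSE into one number in
[0, 1): `P = R²_train + R²_val`, `E = MSE + RMSE + MAE`,
`D = |R²_train − R²_val|`, `A = (1−D)/(1+D)`, `W = (P/E)·A`,
`W_new = W/(1+W)`. Key behaviors:

* symmetric in the two R² values; strictly decreasing in each error metric;
  strictly increasing in R²_val when R²_val ≤ R²_train;
* applicable only for R² ∈ [0, 1] — a fit with negative validation R² is
  *excluded*, not clipped, which prunes uninformative regressors before any
  ranking happens;
* `E = 0` (a perfect interpolation with zero validation error) is treated as
  degenerate rather than infinitely good;
* boundary values: `W_new = 0` when P = 0 or D = 1; these are valid but
  never competitive.

Error metrics are computed on the validation partition (the conservative
choice; the partition is not dictated by the formula itself). MAE, RMSE and
MSE are all kept even though RMSE² = MSE — the redundancy is intentional in
the metric's design, weighting large errors more than once.

## Model selection

`ChannelModelSelector` (a scikit-learn estimator: `fit`/`predict`,
`get_params`/`set_params`, fitted attributes with trailing underscores)
splits its input 70:30 (seeded), then evaluates every grid cell of every
requested model behind a shared scaling + feature-selection front end (PCA
or mutual-information top-k; candidate sizes 10/25/50, clipped to the data).
The front end depends only on the training partition and the size, so it is
fitted once per size and shared across grid cells — this keeps mutual
information over a few thousand fingerprint columns affordable.

Default grids span under- and over-fitting regimes: tree depths
{2,4,8,None}; KNN k {3,5,7,9}; boosting estimators {50,200} × learning rate
{0.05,0.3}; SVR C {0.1,1,10} × gamma {scale,0.01,0.1}; Nu {0.25,0.5,0.75};
elastic-net alpha {0.01,0.1,1} × l1_ratio {0.2,0.5,0.8}. Grid search ranks
cells by W_new directly (default) or by cross-validated RMSE with W_new
reported afterwards (`mode="cv"`, cv_folds default 5). Ties break to the
higher validation R², then the lexicographically smaller model name.

Decoys are scored with the selected models' predictions by default; a config
switch (`decoy_score_mode: raw`) substitutes externally supplied raw decoy
scores when available. Prediction mode asks the models to extrapolate to
compounds structurally unlike the training actives; on diverse decoy sets
this can degrade or even invert a channel's enrichment, which is a genuine
property of the approach, not an implementation artifact — the per-channel
AUC spread seen on real benchmarks (down to ~0.3 for QSAR channels on some
targets) reflects the same effect.

## Scoring-channel details

* K-means (Euclidean on ECFP4 bit vectors, 2048 bits, radius 2) groups the
  actives into chemotype clusters; k defaults to 3 for similarity
  representatives and 4 for pharmacophore models (valid range 3–5). Empty
  clusters trigger a bounded re-seed.
* Cluster representatives are the members with the longest canonical SMILES
  (a complexity proxy), ties to the lexicographically smallest string.
* The pharmacophore channel is a deliberate 2D surrogate for 3D
  feature-match scoring: feature points from RDKit's base feature catalog
  are counted per family (donor, acceptor, aromatic, hydrophobe,
  positive/negative ionizable); a cluster's consensus is the per-family mean
  count, retained only if ≥ `min_features` (3–5, default 4) families are
  nonzero, else members score against the global consensus. The score is the
  RMSE between a compound's 6-vector and its cluster consensus. No claim of
  equivalence with 3D engines is made.
* Docking is ingestion-only (CSV `id,score` or Vina-format logs, best-mode
  affinity line); running docking is out of scope. A stub scorer (negated
  similarity + noise) exists for end-to-end tests.

## Enrichment metrics

ROC AUC is the normalized Mann–Whitney statistic (ties rank-averaged). The
enrichment factor at fraction f uses a ceiling top slice
(`⌈f·N⌉`, so a 1% slice of a small pool is never empty) and is capped at
1/f. BEDROC follows the exponential early-recognition construction: the sum
of `exp(−α·r_i/N)` over active ranks, min-max normalized between the worst
and perfect orderings so the extremes are exactly 0 and 1; α defaults to 20
(the common literature choice) and is recorded in every report. Compounds
with tied consensus scores are pre-ordered by id so all metrics are
reproducible.

## Bias audit

1. **Physicochemical panel** — Welch (unequal-variance) two-sample t-tests
   per property at p < 0.05. The 17-property panel is configurable with the
   width enforced: molecular weight, cLogP, HBD, HBA, TPSA, rotatable bonds,
   ring count, aromatic rings, heavy atoms, fraction sp³ carbons, formal
   charge, molar refractivity, stereocenters, heteroatoms, QED, an ESOL logS
   estimate, largest ring size. Properties with zero variance in both groups
   are excluded from the significant/non-significant counts with a warning.
2. **Diversity ranking** — MaxMin picking over Tanimoto distance on the
   ECFP4 block (used here in place of proprietary fragment-fingerprint
   descriptors). The pick starts at the medoid (largest total similarity,
   ties by id), making ranks seed-free; rank 1 is the most diverse pick.
3. **PCA neighbors** — standardize, project to 2 principal components,
   threshold at the 10th percentile of the pooled active→decoy Euclidean
   distances, count decoys within threshold per active, take the median, and
   correct it to the reference 1:125 active:decoy composition:
   `corrected = median · (n_decoys/n_actives) / 125`. At exactly 125
   decoys per active the median is unchanged. The pooled (not per-active)
   percentile is used; consequently actives far from the decoy cloud get
   zero neighbors only relative to wherever the pooled percentile lands.

## Synthetic data generator

The generator emulates a single-target screening dataset: a small active set
(default 40) with continuous activity and a larger decoy pool (default 500),
within the capacity guarantee of a four-core (benzene, pyridine, pyrimidine,
piperidine), three-slot, 25-substituent grammar (> 10⁴ distinct molecules).
Actives form a congeneric series on one core — as SAR-derived active sets
do — while decoys are drawn from all cores. Active pIC50 is a linear
function of named physicochemical descriptors (default: 0.8·cLogP −
0.02·TPSA + 0.01·MW) plus Gaussian noise (SD relative to the signal's
spread, default 0.1), affinely rescaled into the [4, 10] potency window.
Decoy latent activity is N(μ_actives − 2, 1): separable but overlapping, so
enrichment is non-trivial. Each channel is a channel-specific monotone link
(identity, logistic, negative affine, softplus) of the standardized latent
plus independent Gaussian noise; `channel_noise = 1` means noise SD equal to
signal SD, the default study condition. An optional `property_shift` draws
actives from the low tail and decoys from the high tail of the named
properties, producing deliberately biased datasets for audit tests.

What the generator does *not* emulate: property-matched (DUD-E-style) decoy
selection, activity cliffs, assay noise structure, or any true binding
physics. Passing tests on this fixture demonstrate the pipeline's mechanics
and statistical behavior under known ground truth, not predictive validity
on real targets.

## Numerical and design choices

* Z-scores use the population SD over the pooled actives+decoys being
  ranked — that is the pool the enrichment curve is drawn over. Zero-variance
  channels are an error, not silently skipped.
* The weighted average divides by Σw, so consensus scores are invariant to a
  common rescaling of the weights.
* Splits: the external hold-out is sampled first (seeded), the remainder
  split 70:30 unstratified (stratification is configurable territory but not
  default). All randomness flows from explicit config seeds; two runs from
  one config produce byte-identical artifacts and manifests. Stage timings
  are logged but deliberately kept out of the manifest to preserve that
  guarantee.
* Descriptor columns with non-finite values are imputed to the column median
  (robust on small active sets) and logged.
* Default problem sizes (40 actives / 500 decoys for pipeline runs; reduced
  model lists in some smoke tests) were chosen as the package's standard
  demonstration conditions; the full twelve-model zoo runs in the default
  `run-all`.

## Known limitations

* The pharmacophore channel is a 2D count-vector surrogate; its RMSE is not
  comparable in magnitude to 3D feature-match RMSEs.
* Prediction-mode decoy scoring extrapolates; channels can lose enrichment
  on structurally remote decoys (see above).
* The bias audit's diversity stage substitutes ECFP4 for fragment
  fingerprints; absolute rank values differ from tools built on the latter.
* The ratio correction for the median neighbor count is linear in the
  decoy:active ratio; alternative normalizations exist for pools whose decoy
  counts differ greatly from the reference composition.
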