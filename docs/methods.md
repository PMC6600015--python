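# Methods

`drugsense` benchmarks how well different molecular data types — binary
mutation profiles, transcript abundances, and (phospho)protein levels —
predict drug sensitivity across a panel of cancer cell lines. This note
records the statistical models, the protocol, the synthetic-data
generator that the test suite exercises the pipeline on, and the
numerical and design choices made where the problem left them open.

## Drug-sensitivity summary

Each (cell line, drug) pair is screened at `n_doses` concentrations on an
evenly log-spaced serial dilution (default nine doses, 1:3). Sensitivity
is summarised as the **mean viability** over the dose grid,

  AUC_i = (1/K) Σ_k v_i(d_k),

which on an even log-dose grid equals the normalised area under the
dose–response curve up to endpoint weighting (the unweighted mean is used
rather than the trapezoid rule; the two differ only in how the first and
last dose are weighted). Lower AUC means a more sensitive line. IC50 and
maximum inhibition are computed as optional curve summaries but feed no
downstream model: AUC avoids their saturation and extrapolation
artefacts. Missing (cell line, drug) pairs stay missing; modelling
discards the affected lines per drug rather than imputing.

Drugs are selected for analysis by the coefficient of variation of their
AUC across lines (σ/μ with sample SD), either the top-k drugs or a
threshold (σ/μ ≥ 0.2 is the threshold used in transfer benchmarking,
applied in both the target tissue and its complement).

## Per-drug modelling protocol

For one drug with response vector a (AUC per line) and a feature block X,
the cross-validated protocol is:

0. Discard cell lines without sensitivity data.
1. Randomly partition the remaining lines into 10 folds (unstratified).
2. Within each training fold: transform expression values — log2(1+x)
   for transcripts, log2(x) for proteins, identity for mutations — and
   discard transcripts with mean < 2.0 or sample SD < 0.5, and proteins
   with sample SD < 0.1, computed on the training lines only.
3. Centre and scale the surviving training columns to mean 0 / SD 1;
   zero-variance columns are dropped.
4. Select the learner's hyperparameter by nested 10-fold CV inside the
   training fold (see below), then fit on the whole training fold.
5. Transform the held-out fold with the *training* fold's filter set and
   scaling parameters, and predict it.
6. After all folds, compute Spearman ρ_s and the fraction of variance
   explained, R² = 1 − ⟨(â_i − a_i)²⟩ / ⟨(a_i − ā)²⟩, between measured
   and predicted AUC.
7. Repeat the whole partition (default 100 repeats; smaller counts are
   used in tests, see "Problem sizes"). Summary metrics are the mean of
   the per-repeat metrics; per-line predictions are reported as the
   across-repeat mean. A negative ρ_s is reported as-is — it indicates a
   non-predictive model, not an error.

Test-set leakage is excluded by construction: filter membership and
standardisation parameters are functions of the training lines only, and
the test suite asserts this by perturbing held-out rows and recomputing.

### PLS (primary learner)

Partial least squares builds latent components t_a = X w_a whose
covariance with the response is maximal, which regularises the p ≫ n
regime (e.g. 88 antibodies, 49 lines) where ordinary least squares is
undefined. The implementation is classical NIPALS with deflation:

- single response: w_a ∝ X_a' y (one step; no inner iteration), then
  t_a = X_a w_a, loadings p_a = X_a' t_a / t_a't_a,
  q_a = y' t_a / t_a't_a, and deflation X_{a+1} = X_a − t_a p_a'.
- multi-response (PLS2): the standard inner iteration on the dominant
  covariance direction, tolerance 1e-12, at most 500 iterations,
  initialised from the highest-variance response column (deterministic).

The model is always representable exactly as â = b₀ + X β with
β = W (P'W)⁻¹ q accumulated incrementally, so coefficients for *every*
truncation 1..A fall out of one fit. The number of components is chosen
by nested 10-fold CV with a first-local-minimum rule: the smallest PC
whose RMS increases when one more component is added (PC_min = 1,
PC_max = 10); if the RMS never increases, PC_max is used. With
n_components = rank(X), PLS reproduces the least-squares solution; the
test suite verifies this and cross-checks predictions against an
independent eigendecomposition-based construction and against
scikit-learn's `PLSRegression` (used only as an oracle).

Feature importance is read from the regression coefficients on
normalised inputs (chosen over VIP for interpretability; VIP is
implemented, with mean squared VIP = 1 by construction).

The univariate coefficient-path computation that the nested CV loop
calls thousands of times is additionally compiled with numba; it
computes the identical path to the plain numpy implementation (asserted
to 1e-12 in the tests) and falls back to numpy if numba is unavailable.

### Comparison learners

All learners share the same contract (fit on training lines only,
hyperparameters by nested 10-fold CV, pure predict):

- **Regression tree** (for mutation data): CART with greedy
  variance-reduction splits, minimum bucket size 5, pruned by
  cost-complexity. The pruning level grid is the full tree's own
  weakest-link sequence (at most 8 levels); nested CV picks the level
  with minimal RMS, ties resolved toward the smaller tree. Growing
  delegates to scikit-learn; the inner CV evaluates all pruning levels by
  collapsing weakest links on a single fitted tree, which is verified in
  the tests to agree exactly with refitting at each `ccp_alpha`.
- **Elastic net / Lasso**: minimises (1/2n)·RSS + λ[(1−α)‖β‖² + α‖β‖₁]
  with an unpenalised intercept (coordinate descent via scikit-learn;
  the (α, λ) pair maps exactly onto scikit-learn's (alpha, l1_ratio)).
  α is searched over {0.0, 0.1, …, 1.0} and λ over a 20-point log-spaced
  path below the data-driven λ_max; ties prefer the smallest α, then the
  largest λ. Lasso is the α = 1 special case; a sparsity sweep reports
  cross-validated performance as a function of support size along the λ
  path.
- **Maximum correlation**: simple regression on the single feature with
  the largest |Pearson r| to the response (ties: lowest column index) —
  the "best single biomarker" baseline.
- **PLS2**: one shared component set predicting all drugs at once,
  restricted to lines with complete sensitivity data; the component
  count minimises the summed RMS over drugs.

### Permutation background and significance

Observed metrics are compared with an empirical null obtained by
shuffling the response across cell lines and rerunning the *entire*
pipeline (fold-wise filtering, standardisation and nested selection
included), one CV run per shuffle. The one-sided add-one estimator

  p = (1 + #{null ≥ observed}) / (1 + N)

avoids p = 0 and satisfies p ≥ 1/(1+N). p-values are Benjamini–Hochberg
adjusted across drugs within each (data type, learner) family. Trees are
scored against the background by R², the linear models by ρ_s, matching
how each model family is typically summarised.

## Integration and transfer

- **Early integration** concatenates the fold-wise–prepared blocks
  before one fit; with a single block it reduces exactly to the plain
  protocol.
- **Late integration** combines per-block predictions with weights
  1/RMS_m, where RMS_m is block m's nested-CV RMS on the training fold —
  a convex combination, so combined predictions are bounded by the
  per-block predictions, and no test information enters the weights.
- **Tissue-mean baseline**: leave-one-out mean AUC of the line's tissue.
- **Cross-tissue transfer**: one model trained on all lines outside the
  target tissue (hyperparameters by nested CV within the training set),
  evaluated once on the target. **Cross fair** repeats this with the
  training set resampled, without replacement, down to the target
  tissue's size (default 1024 resamples; 64 in the acceptance tests),
  removing the sample-size advantage of pooling tissues.
- **Duplicate handling**: panels may contain cell lines from the same
  patient; `exclude_duplicate_patients` keeps the first line per patient
  in stable panel order so robustness to duplicates can be checked.

## Exploratory structure

Hierarchical clustering is complete linkage over the Euclidean metric
(monotone merge heights); the two-cluster cut is taken below the final
merge. PCA is SVD of the centred matrix with a deterministic sign
convention. Cluster-wise drug response differences use Welch's t test
(Satterthwaite degrees of freedom) with BH adjustment across drugs.

## Synthetic panel generator

The generator produces panels with the statistical structure the
analyses assume, plus the planted ground truth needed for parameter
recovery tests. Defaults describe a 49-line, single-tissue panel with 88
antibodies, 2,000 transcripts, 150 mutations and 27 drugs.

| parameter | default | meaning / rationale |
|---|---|---|
| `n_cell_lines` | 49 | mid-sized single-tumor-type screen |
| `n_proteins` | 88 | RPPA-scale antibody panel |
| `n_transcripts` | 2000 | enough for a non-trivial mean+variance filter |
| `n_mutations` | 150 | desk-scale stand-in for an exome-wide matrix |
| `driver_prevalence` | 0.7 | one high-prevalence driver (≈ 34/49) |
| `n_drugs`, `drug_classes` | 27, (2,3,4 shared) | classes with correlated sensitivities; the first class is driver-dependent |
| `n_null_drugs` | 5 | drugs with no molecular association |
| `effect_size` | 1.5 | planted signal SD / residual AUC noise SD |
| `auc_noise_sd` | 0.08 AUC | residual biological noise the effect size is measured against |
| `driver_effect_auc` | 0.25 AUC | sensitivity gain conferred by the driver |
| `tissue_effect_sd` | 0.1 AUC | per-(tissue, drug) offsets when multi-tissue |
| `viability_noise_sd` | 0.05 | per-dose assay noise (not reported by typical screens; exposed in config) |
| `n_duplicate_patients` | 4 | near-copy lines sharing a patient |

Generation details:

- **Transcripts** are log-normal: log2 values Normal(μ_g, σ_g) with
  μ_g ~ N(4, 2), σ_g ~ U(0.2, 1.5), so the default mean/variance filter
  retains a non-trivial subset (~65%).
- **Proteins** are noisy linear readouts of one matched transcript plus
  one of three latent pathway factors: log2 p_j = μ_j + 0.5·z_(m(j)) +
  0.45·L_(f(j)) + 0.74·ε. The transcript loading reproduces the
  mRNA–protein correlation of ≈ 0.5 reported across proteomic studies;
  the factor share (~20% of variance) matches the leading-component
  share of typical RPPA panels. Proteins are therefore partially
  predictable from transcripts, as real panels are. Two designated
  antibodies form a mutually exclusive switch (bimodal state, Pearson
  r ≤ −0.5), emulating inhibitor/substrate pairs such as PTEN and
  phosphorylated AKT.
- **Drug effects**: each non-null, non-driver drug receives five
  informative proteins drawn from antibodies sharing one latent factor,
  with coefficients of coherent sign and magnitude U(0.5, 1.5) before
  scaling — pathway-coherent marker sets, the structure real drug-class
  markers show (e.g. MAPK-pathway phospho-markers moving together).
  The combination is scaled so the per-drug signal SD equals
  `effect_size × auc_noise_sd`. Shared-effect classes mix a class-level
  coefficient vector (weight √0.8) with per-drug variation (√0.2),
  producing correlated within-class sensitivities. Driver-class drugs
  instead subtract `driver_effect_auc` in lines carrying the driver
  mutation. True AUC = baseline U(0.3, 0.8) + planted effects + tissue
  offset + residual N(0, `auc_noise_sd`), clipped to [0, 1.2]. With
  `effect_tissues` set, planted continuous effects act only in those
  tissues (tissue-private effects, for transfer studies).
- **Dose–response curves** realise each true AUC exactly: a logistic in
  log-dose with upper asymptote 1, lower asymptote max(0, 2·AUC − 1) and
  the inflection solved by bisection so the noiseless dose-grid mean
  equals the target to < 1e-9; true AUC ≥ 1 yields flat curves (growth
  stimulation). Gaussian per-dose noise is added and viability clipped
  at 0 (the clipping bias on recomputed AUC is < 0.01 at the default
  noise level, verified by simulation).
- **Duplicates**: the last `n_duplicate_patients` lines are near-copies
  of the first ones (features perturbed by N(0, 0.05·feature SD),
  binary mutations copied exactly, AUC residuals shared up to a 25%
  perturbation), same tissue, same patient ID.
- **Randomness**: one master seed; each matrix draws from an
  independent named substream (`SeedSequence(seed, spawn_key)`), so
  changing the drug panel cannot perturb the molecular layers.

The generator emulates the *statistical* structure the pipeline relies
on — planted linear effects, class correlation, a dominant driver,
tissue offsets, duplicates — not the biology of real panels: no
mutational signatures, copy number, methylation, pathway topology, or
pharmacokinetics, and mutations are independent Bernoulli columns rather
than co-occurrence-structured. Passing tests on these panels shows the
pipeline recovers what was planted under its own assumptions; it does
not certify performance on real screens.

Protein matrices are emitted on a positive linear intensity scale (the
pipeline applies the log2 transform), matching how RPPA intensities
arrive after array normalisation.

## Numerical choices

- NIPALS tolerance 1e-12, max 500 inner iterations; component loops stop
  (with truncation warning) when the residual covariance or score norm
  underflows the tolerance — degenerate inputs yield an intercept-only
  model rather than an error.
- Standardisation uses population SD (ddof = 0), making the
  "training mean 0 / SD 1" identity exact; the expression filters and CV
  filter use sample SD (ddof = 1).
- Empirical p-values use the add-one estimator; the permutation stream
  is seeded per (drug, shuffle) so each drug is independently
  reproducible, and shuffle partitions are drawn from a stream distinct
  from the observed run's.
- Tree tie-breaks: pruning-level ties pick the larger penalty (smaller
  tree); split determinism comes from a fixed `random_state`. The
  weakest-link evaluation uses a relative tolerance of 1e-9 when
  comparing collapse levels so that last-ulp differences from
  scikit-learn's path arithmetic cannot flip a boundary node.
- Elastic-net tie-breaks: smallest α, then largest λ. The (1/2n) RSS
  normalisation pins down the λ scale; the λ grid is data-driven
  (λ_max = max|X'y_c|/n, floor 1.0 when the response is degenerate).
- Fold partition: a random permutation split into nearly equal folds
  (49 lines / 10 folds = nine fives and one four). Fewer lines than
  folds reduces the fold count with a warning.

## Problem sizes used by the test suite

The acceptance tests run the full protocol at sizes chosen to finish in
minutes on one CPU while keeping the panel scale of the defaults:
calibration uses 50 null drugs × 200 shuffles with 5-repeat CV on the
49 × 88 protein panel; the driver positive control uses 6 drugs × 200
shuffles of the regression-tree pipeline; transfer comparisons use 64
cross-fair resamples; the data-type ranking panel uses 800 transcripts
and 60 permutations. `scripts/acceptance.py` re-runs the same
computations from scratch at these sizes and writes the headline numbers
as JSON.

## Known limitations

- PLS2 restricts to cell lines complete for all modelled drugs — the
  simplest consistent missing-data policy, documented rather than solved.
- λ selection uses the plain CV minimum (no 1-SE rule); likewise tree
  pruning (the 1-SE variant is not implemented).
- The permutation background uses a single CV run per shuffle; the
  observed metric averages over repeats. This keeps large shuffle counts
  tractable and only widens the null slightly (conservative).
- Population-variant filtering of mutation tables against external
  databases is out of scope; variant tables are assumed pre-filtered.
- `max_corr_fit` uses Pearson correlation, pairing naturally with its
  linear-regression step.
- Cross-study merging (averaging correlations across sensitivity
  censuses) is not implemented; inputs are single-census panels.
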