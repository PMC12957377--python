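# Methods

This note documents the models, defaults and numerical choices behind
`longomics`, and what the synthetic validation surface does and does not
demonstrate about real data.

## The synthetic cohort

`simulate.SimConfig` encodes the study design the pipeline assumes: two
genotypes (`WT`, `MUT`) sampled at 6, 24 and 36 months with 6, 9 and 9
animals per genotype per timepoint (48 samples). In the longitudinal
default, each genotype has a pool of nine subjects and the first *n_t* are
sampled at timepoint *t*, so subjects recur across ages and any honest
train/test split must group by subject.

Each log2 abundance is additive:

```
value = analyte baseline            N(10, 1) across analytes
      + subject intercept           N(0, subject_sd), per (subject, analyte)
      + genotype effect             planted analytes only, in units of noise_sd
      + age slope x age             planted age-correlated analytes
      + mixture shift               N(0, mixture_shift_sd), per (mixture, analyte)
      + residual noise              N(0, noise_sd)
```

then masked missing completely at random with probability `missing_rate`.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_proteins`, `n_metabolites` | 40, 30 | desk scale; dimensions only change runtime, not the planted structure |
| planted stable | 2 proteins, 2 metabolites at +3 SD | the lysosomal-protease / glycerophosphodiester marker analogs: strong, stable elevation at every age |
| planted late | 1 per block at +3 SD, 36 months only | the neurofilament-light analog: late-onset neurodegeneration marker |
| planted age | 1 per block, 0.02 SD/month | age-correlated analytes in both genotypes; these are what the second component tends to pick up |
| `subject_sd` | 0.5 | within-subject correlation ~0.2 over time; repeated sampling implies such correlation but nothing in the emulated design pins its magnitude, so this is a declared default |
| `noise_sd` | 1.0 | the unit in which effect sizes are stated |
| `n_mixtures`, `mixture_shift_sd` | 3, 0.3 | three multiplexed batches with modest additive per-analyte shifts, the pattern reference-channel bridging is designed to remove |
| `missing_rate` | 0.05 | MCAR; real missingness in proteomics is partly intensity-dependent (see Limitations) |

The subject intercept is drawn per *(subject, analyte)*. An earlier design
shared one intercept per subject across all analytes; that creates a rank-1
common factor spanning both blocks which covariance maximization latches
onto, and models analyte–analyte correlation rather than the intended
within-subject repeat-measure correlation. Analyte–analyte correlation is
deliberately not modeled (see Limitations).

`simulate_discrete_dag` forward-samples a known DAG: roots uniform over
`n_states`, children copy the sum of their parents' states (mod
`n_states`) with probability `cpt_strength` and are uniform otherwise.
This gives the network stage a recoverable skeleton with a one-knob
association strength.

## Preprocessing

The default chain per block is log2 → mixture bridging → missingness filter
→ zero-mean/unit-variance scaling, with scaling last. Two filter rules
coexist on purpose: the metabolite rule drops an analyte only when *more
than* half its values are missing, the protein rule at half *or more*; an
analyte missing in exactly half the samples survives one and not the other.
Bridging subtracts, per analyte, the mean over each mixture's samples (an
artificial reference channel), which cancels additive per-mixture shifts
exactly; it is an abundance-level analog of peptide-level reference-channel
normalization, not a reimplementation of it. SDs use the n−1 convention;
medians of even counts average the two central order statistics. Scaling
parameters are estimated on training data and applied to held-out data
(`apply_scaling`); scaling the full matrix before splitting is possible by
simply scaling before the split, but the pipeline's disease-score stage
always derives its scaling and imputation parameters from the training
subjects only.

## Multiblock sparse PLS-DA and the disease score

Blocks are treated symmetrically with the centered class-indicator matrix
as one more block; each component maximizes the design-weighted sum of
score covariances under unit-norm and per-block cardinality (`keepX`)
constraints. The design matrix defaults to fully connected with unit
weights.

Numerical choices:

- **Block update.** With the other blocks' scores fixed, the optimal
  loading under `‖a‖₂ = 1, ‖a‖₀ ≤ keepX` is the gradient
  `w = Xᵀ Σ C t` restricted to its `keepX` largest-magnitude entries and
  renormalized — the exact constrained argmax, so the objective is
  non-decreasing across iterations by construction. (A soft-thresholded
  variant shrinks the retained entries and settles on a measurably lower
  objective; it is not used.)
- **Initialization and multi-start.** The loading is initialized from the
  dominant left singular vector of `Xᵀ Y_c`. Because the sparse fixed
  point can stall in support-local optima on weak-signal data, the solver
  additionally starts from every joint combination of single-analyte basis
  vectors whenever the product of block widths is at most 64, and keeps
  the best converged objective. On 50 random small instances this matches
  exhaustive support enumeration to 1e-6 (the single SVD start alone
  failed 8 of 50). Wide blocks use the single SVD start; with planted
  effects of realistic size the gradient there is dominated by the true
  markers.
- **Deflation.** Each block, and the outcome, is deflated by regression on
  its own score (`X ← X − t (Xᵀt/tᵀt)ᵀ`), which makes within-block scores
  mutually orthogonal and is the convention that lets held-out projection
  reuse the stored regression vectors.
- **Sign.** Each component's sign indeterminacy is fixed by one *global*
  flip (all blocks together) anchored so the first block's
  largest-magnitude loading entry is positive. Per-block flips would
  change the sign of cross-block covariance terms and hence the objective.
  Under the default generator this makes higher scores disease-like.
- **Convergence.** Fixed point declared at a maximum loading change below
  `tol = 1e-6`, capped at 500 iterations with a warning.

The composite disease score of a sample is the sum of its first-component
scores across the omics blocks. Classification for tuning uses per-block
nearest-centroid decisions in component-score space combined by majority
vote (ties: smallest aggregate distance, then class order); weighted and
average votes and a dummy-regression "max" distance are available.

**Tuning.** `tune_keepx` evaluates a keepX grid by balanced error rate
under five-fold cross-validation repeated (default) twenty times, with
folds partitioning subjects, stratified by genotype. The chosen cell
follows the one-standard-error parsimony rule: among cells within one SE
of the lowest mean BER, the fewest-analytes cell wins. Plain arg-min on a
fold-noisy BER surface systematically admits spuriously large
cardinalities; even so, on ~10–15% of desk-scale cohorts a three-analyte
cell attains a genuinely lower CV BER than any informative-only cell, so
tuned selections can legitimately include an analyte with no planted
effect. The raw arg-min cell is always reported alongside.

**Splitting.** 70/30 by subject, stratified by genotype with
largest-remainder apportionment; every class keeps at least one subject on
each side. ROC AUC uses the rank (Mann–Whitney) formulation with ties
counting one half; the reported curve's trapezoidal integral equals the
rank AUC.

## Univariate screening and enrichment

Per-timepoint genotype differences use the classical pooled-variance
two-sample t-test (a Welch option exists but is off by default, matching
the named test). Analytes with fewer than two observed values in either
group are reported `tested = False` rather than given a fabricated
p-value. Fold changes for the network stage are per-MUT-animal deviations
from the WT mean on the *unscaled* log2 matrix — fold change on z-scores
is not interpretable. Enrichment is the one-sided (greater) Fisher exact
test of each term against the all-detected background, BH-adjusted across
terms; cluster enrichment flags terms with ratio > 3 and q < 0.1 by
default. Both the 0.05 and 0.1 FDR conventions are reachable via
`fdr_max`.

## Cluster maps

The module consumes any analyte × 2 embedding (UMAP computation is out of
scope; a PCA fallback is provided for pipelines and tests), clusters with
complete-linkage agglomeration on Euclidean distances, and picks k at the
largest discrete second difference of the within-cluster sum of squares
(ties → smallest k). A warning is issued when the maximal curvature is
less than half the WSS span — pronounced elbows concentrate most of the
curvature at one k, smooth single-cluster decays do not (measured ratios:
~0.2–0.3 for one Gaussian blob vs ~1.0 for well-separated blobs).

## Bayesian networks

Fold-change profiles are discretized per variable (equal-width default;
equal-frequency via quantile edges, right-closed so ties share a bin; the
maximum lands in the last bin). Twenty intervals with only ~9 animals
leaves mostly singleton bins; the module warns and supports coarser bins —
with so few samples per cell the marginal-likelihood penalty is severe and
learned graphs are sparse.

Structures are scored with BDeu (`α_ijk = ess/(r_i q_i)`, default
`ess = 1`, the common uniform-prior choice for the equivalent sample
size). Only observed parent
configurations are enumerated — unobserved ones contribute zero — keeping
high-arity discretizations tractable. Hill climbing starts from the empty
graph and greedily applies the best add/remove/reverse move that preserves
acyclicity and the parent bound (default 3), stopping when no move
improves the score by more than 1e-9; ties break lexicographically on
(move type, source, target), so the search is deterministic. Edge weights
are the raw score gain recorded at each edge's final add/reverse move,
min-max normalized to [0, 1] across edges; the raw deltas are exported
too, since a fixed edge-score threshold such as 0.001 is only meaningful
once the scale is chosen.
Subnetwork extraction keeps above-threshold edges, their endpoints, each
endpoint's incoming neighbors, and the parent edges justifying those
neighbors.

Arities are taken from the discretization (or declared explicitly);
inferring them from observed maxima under-counts states that happen not to
appear and changes the score.

## Pipeline and reproducibility

`pipeline.run_pipeline` chains simulate/load → preprocess → univariate +
enrichment → cluster map → disease score → network, persisting every
intermediate as TSV/JSON plus a manifest with the configuration, derived
seeds and headline numbers; rerunning a config reproduces the manifest
exactly. One global seed fans out to per-stage seeds by fixed offsets so a
stage rerun in isolation sees the same stream. The univariate, cluster and
network stages operate on the full preprocessed dataset; only the
disease-score stage holds subjects out.

## Validation surface and problem sizes

The test suite validates each stage against independent oracles: exhaustive
support enumeration with dense restarted alternating maximization for the
sparse optimizer; the dominant singular vector in the single-block
full-cardinality limit; hand-evaluated pooled-t, hypergeometric-tail and
step-up computations for the univariate statistics; a sequential
Dirichlet-multinomial predictive product for BDeu (exhaustive over all
3-binary-node datasets with n ≤ 6, enumerated through their configuration
counts); and recovery/null simulations on the generator (100 seeds for
marker recovery and held-out AUC, 200 cohorts for type-I calibration, 100
seeds for DAG recovery). Null calibration switches off batch shifts along
with the planted effects: with shifts on, the pooled t-test is
structurally conservative (the shift inflates the variance estimate but
cancels in the balanced genotype contrast), so leaving them on would
measure the batch structure rather than the statistic. Cross-validation in
bulk simulations uses 2 repeats rather than 20; the selection behavior at
both settings is reported above.

## Limitations

- Planted effects are additive, homoscedastic and independent across
  analytes; real serum omics have correlated analyte families, so passing
  recovery tests here does not guarantee marker identifiability under
  strong collinearity (where any member of a correlated family may be
  selected).
- Missingness is MCAR; abundance-dependent (MNAR) missingness would bias
  the median imputation and the missingness filters in ways this surface
  cannot detect.
- The generator emits log2-scale abundances directly and models the TMT
  batch structure as additive per-analyte shifts; spectra, peptides and
  reporter-ion artifacts are out of scope.
- BDeu hill climbing returns one member of a Markov equivalence class;
  edge orientations are not causally identifiable from the score, and with
  ~9 profiles per variable the learned graphs should be read as
  association sketches, not causal claims.
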