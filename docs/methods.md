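# Methods

`metabopanel` implements a matched case–control discovery pipeline for urinary
metabolite markers of gestational diabetes mellitus (GDM) in late pregnancy.
This note records the model assumptions, the defaults and why they were
chosen, what the synthetic cohort generator does and does not emulate, and the
numerical conventions that make runs reproducible.

## Study design being modelled

A nested case–control design: 46 GDM gravidas and a larger pool of healthy
controls provide randomly collected urine at ≥ 24 weeks' gestation, profiled
on an untargeted platform. Analysis is restricted to endogenous metabolites
(626 in the default design); xenobiotics and partially characterized
molecules are excluded before any statistic is computed.

## Case–control matching

Each case is paired to one control by minimizing a weighted standardized
dissimilarity score over four covariates — gestational age at the early (GA1)
and late (GA2) urine collections, maternal age, and pre-pregnancy BMI:

    score = ( 3·[(ΔGA1/SD_GA1 + ΔGA2/SD_GA2)/2] + 2·ΔAge/SD_age + ΔBMI/SD_BMI ) / 6

with Δ the absolute case–control difference and SD the pooled standard
deviation of cases plus the entire candidate pool ((n_g − 1)-weighted). The
score is a zero-covariance special case of the Mahalanobis distance, in SD
(Z) units. Design choices:

- **Selection policy.** Default is the globally optimal one-to-one assignment
  (min-cost bipartite matching via the Jonker–Volgenant solver in SciPy); a
  greedy policy (repeatedly take the smallest remaining pair, ties broken by
  (case id, control id)) is available for comparison. "Smallest scores, best
  match" is best honoured by the global optimum, and the optimum is verified
  against an exhaustive-permutation oracle for small instances in the tests.
- **Pooled SDs** are computed before selection, from cases plus the whole
  pool, since they must exist before any control is chosen.
- The age term uses Δage like the other terms (weight 2).

## Normalization

Raw peak areas are corrected for urine concentration, then median-scaled and
log-transformed (natural log throughout):

    index = ln( (peak / dilution) / median_samples(peak / dilution) ),
    dilution = osmolality_sample / median(osmolality)

The per-metabolite median is taken over all analyzed samples (cases plus
matched controls), blind to group, so matching runs before normalization.
Fluid-intake adjustment precedes median scaling; since the dilution factor is
a per-sample constant, the two orders differ only by a per-metabolite
constant that the median scaling removes — the choice is stated for
definiteness, not because it changes the index. Creatinine correction is a
recognised alternative not implemented here. Non-positive peak areas are
rejected with the metabolite named rather than imputed; normalizing an
already-normalized matrix is an error.

## Bivariate screen

- **Effect size** d = (mean GDM − mean CON) / pooled SD on the log index,
  with a two-sided pooled-variance t-test P (metabolites are treated as
  normal on the log scale). P values are reported nominal at 0.05; no
  multiplicity correction is applied at the screening stage, and outputs are
  labelled accordingly.
- **Demographics** use the test matching the variable's type: t-test
  (normal), Wilcoxon rank-sum (non-normal), Fisher exact (categorical).
- **Single-marker accuracy** is the in-sample optimal cutpoint: exhaustive
  search over midpoints between consecutive sorted unique values, in both
  orientations (high-is-case and low-is-case), maximizing unweighted accuracy
  = (sensitivity + specificity)/2. Ties resolve toward larger sensitivity,
  then smaller threshold, then the high orientation. In-sample optimisation
  makes these accuracies optimistic by construction; they are a ranking
  device, not an out-of-sample estimate. A constant marker scores 50% and is
  flagged.

## Consensus multivariate selection

Three importance criteria, computed on the normalized matrix:

1. **Forest permutation importance** — mean over 500 bootstrap trees of the
   drop in out-of-bag accuracy after permuting a feature's out-of-bag values.
   The forest is assembled from scikit-learn decision trees over explicit
   bootstrap draws (√p features per split, minimum leaf 2) so per-tree
   out-of-bag indices are available.
2. **Forest Gini worsening** — sample-weighted total Gini impurity decrease
   of the feature's splits, averaged over trees.
3. **Boosting relative influence** — per-feature share of split improvement
   in a 200-stage gradient-boosted ensemble of depth-2 trees on the binomial
   deviance (learning rate 0.1, 50% subsampling), normalized to sum to 100.

Ensemble sizes are conventional defaults, fixed and echoed into every report
for reproducibility. The top k = 30 metabolites under each criterion form
three sets; the **consensus candidates are their three-way intersection**,
with the ≥2-criterion overlap and the union reported as diagnostics
(`intersection ⊆ overlap ⊆ union` is asserted on every fit). An automatic
elbow option (maximum second difference of the sorted importance curve) can
replace the fixed k but is off by default. Boundary ties resolve by
metabolite id.

A behaviour worth knowing: at 46 cases per group, boosting influence
concentrates on the few strongest markers once they explain the training
deviance, so its top-30 set is systematically narrower than the two forest
criteria's; the three-way intersection inherits that narrowness. Markers
with |d| below roughly 0.5 are rarely recovered at this sample size.

## Classification tree

The final predictor is a depth-limited CART-style tree over a candidate
panel: greedy recursive partitioning, exhaustively searching panel features ×
midpoint thresholds for the split minimizing child-size-weighted Gini
impurity. Conventions, all part of the model contract:

- condition `x < t` is strict and traverses **left** (the true branch);
  a value equal to the threshold goes right;
- "five-level" means the root is level 1 and no path exceeds five node
  levels, i.e. at most four nested splits;
- minimum leaf size 5; growth also stops at pure nodes; no pruning;
- split ties resolve by (feature id, smaller threshold); features are
  scanned in name order;
- a sample's score is its leaf's training case proportion; ROC AUC is the
  rank-sum probability that a random case's score exceeds a random
  control's, ties counted ½.

Evaluation is resubstitution (apparent) performance — sensitivity,
specificity, unweighted accuracy and AUC on the training samples — because
that is the regime of the reported study results; no cross-validation is
applied by default. Greedy growth is myopic: under a depth bound, adding an
irrelevant feature to the panel *can* lower training accuracy when a noise
split displaces a useful one, so panel hygiene matters. Serialized trees
record the scale of the thresholds (log median-scaled, osmolality-corrected
index) explicitly.

Two fixed panels are compared under identical settings: the eight consensus
late-pregnancy metabolites (3-hydroxybutyrate, homocarnosine,
1,5-anhydroglucitol, 3-hydroxydodecanedioate, 3-hydroxybutyrylcarnitine,
3-methylhexanoylcarnitine, saccharopine, acetylcholine) and the seven
first-trimester model metabolites reused as a fixed feature list
(dihydroorotate, phenol glucuronide, nicotinate ribonucleoside, saccharopine,
lanthionine, argininate, 7,8-dihydroneopterin). The pipeline's own late panel
defaults to the consensus candidates it discovers on the data at hand.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, so
the pipeline is testable end to end without any external data:

- **Metabolites.** For controls, the log value of metabolite m is
  Normal(μ_m, σ_m) with μ_m drawn once from a wide abundance range
  (ln 10⁴…ln 10⁷) and σ_m uniform on 0.3…1.0 — raw-scale heterogeneity that
  stresses the median scaling but cannot influence the analysis, which is
  location/scale-invariant per metabolite. For cases, planted markers are
  shifted by d·σ_m; the default plants the eight consensus markers at their
  published effect sizes (0.815, −0.663, −0.383, 0.759, 0.628, 0.673, 0.822,
  0.704). All other metabolites are identically distributed in both groups.
- **Dilution.** Each sample has a log-normal multiplicative dilution factor
  (log-SD 0.3, a realistic spread for spot urine), applied to every raw peak
  area and mirrored in the subject's osmolality (reference 500 mOsm/kg), so
  the fluid-intake correction is both necessary and sufficient.
- **Demographics.** Group-specific normals with the published means/SDs
  (age 32 ± 4.7 vs 31.8 ± 4.2 y; BMI 31.5 ± 6.8 vs 29.9 ± 6.3 kg/m²;
  GA2 30.8 ± 3.6 vs 30.5 ± 3.0 wk, truncated at 24 wk for the late
  collection). GA1 has no published group statistics, so both groups use
  12 ± 2.9 wk, the reported gestational age of the early collection. Parity
  is Poisson with the published group means; race/ethnicity are drawn from
  common category frequencies identical across groups.
- **Independence.** Metabolites are independent given group — no
  metabolite–metabolite correlation is simulated by default because none is
  specified for the design; an optional equicorrelated block is available
  behind a config switch. This is the generator's most consequential
  simplification: real metabolomes are strongly correlated, which
  concentrates multivariate signal differently. Passing tests on synthetic
  cohorts therefore demonstrate correctness of the computations and sensible
  behaviour under the stated effect sizes, not expected performance on real
  urine profiles.
- Not simulated at all: mass-spectral peaks, retention times, missing
  values, limits of detection, batch effects.

Everything is drawn from one seeded generator; identical configs and seeds
give bit-identical cohorts.

## Reproducibility and numerics

- One run seed fans out to per-stage seeds by hashing `"{seed}:{stage}"`
  (SHA-256, reduced below 2³¹), so stages can be re-run in isolation.
- Reports and artifacts are plain CSV/JSON with sorted keys; a repeated run
  with the same seed is byte-identical.
- Degenerate inputs fail loudly with the offending metabolite or sample
  named: missing annotations, non-positive peak areas or osmolality,
  zero pooled SDs, single-class panels (warned, single-leaf tree).
- Problem sizes used by the test-suite recovery and calibration studies: the
  full default design (46/46 matched from a 138-control pool, 626
  metabolites) over 20 seeds for recovery and null calibration; reduced
  ensembles (120–150 trees, 60–100 boosting stages) where only determinism
  or relative behaviour is being asserted.

## Known limitations

- Resubstitution metrics overstate out-of-sample performance; the package
  reports them because they are the design's evaluation regime, and labels
  them apparent.
- The consensus intersection is conservative at n = 46/group: weak markers
  (|d| ≲ 0.5) are usually lost, and boosting's concentration narrows the
  intersection further (see above).
- In-sample single-marker accuracies of pure-noise markers reach ~67–72% at
  this sample size (max over 626 markers), so single-marker rankings near
  70% are not evidence of signal on their own.
- The early-pregnancy panel metabolites are carried as null columns in the
  default synthetic design (no late-pregnancy effect sizes exist for them),
  so synthetic early-panel metrics reflect noise fitting, not the panel's
  real performance.
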