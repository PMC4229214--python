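# Methods

This note documents the statistical procedures `mmsurv` implements,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Burden signatures

A macro mutation signature (MMS) for GO term *j* counts, per sample,
the somatic mutation records on the term's member genes.  Three rules
define the quantity precisely:

* every record counts — two mutations on one gene contribute 2, and a
  gene annotated to several terms contributes to each of them;
* TP53 is excluded from every term (its ~70% mutation prevalence would
  otherwise make any term containing it a TP53 proxy); it instead
  enters the Cox model as its own binary covariate;
* the count is capped at 2 at matrix-construction time, so every
  downstream consumer (screen, permutation null, tree) sees capped
  values in {0, 1, 2}.

Variant classes are recorded but not filtered by default: the emulated
study counted all validated mutations, silent ones included.  A
`filter_classes` method exposes the alternative.  Terms are screened
only when their gene-set size lies in [50, 500]: smaller sets give
burdens too sparse to test, larger ones are too broad to interpret.
Gene identity is by upper-cased HGNC symbol; mutated genes absent from
the annotation are dropped with an aggregate logged count.

## Survival tests

`survival_stats` implements the three estimators directly in NumPy.
The permutation null re-runs the full screen hundreds of times
(~10^5 fits per FDR estimate), which is why the module trades
generality for per-fit speed and shares the sorted event-time
bookkeeping (`SurvivalData`) across all tests of one clinical
arrangement.  Conventions follow the R `survival` defaults, against
which the implementation was verified exactly during development
(frozen cross-check values live in the test suite):

* **Kaplan-Meier:** product-limit; censored observations tied with an
  event time count as at risk at that time.
* **Weighted log-rank (G-ρ family):** at each distinct event time the
  per-group observed-minus-expected death counts are weighted by
  `S(t-)^ρ`, with S the left-continuous pooled KM estimate.  The
  statistic is `U' V^- U` with a pseudo-inverse covariance, so the
  test stays defined when a small burden group contributes no events;
  df equals the number of non-empty groups minus one.  ρ = 0 is the
  classical log-rank; ρ = −2 is used for heavily right-censored
  cohorts, where late deaths carry weights `S(t)^-2 > 1`.
* **Cox proportional hazards:** Efron tie correction (with a
  vectorized fast path when all event times are distinct);
  Newton-Raphson with step-halving, convergence at relative
  log-likelihood change < 1e-9 or 25 iterations; covariates are
  centered before fitting; two-sided Wald p-values.  Constant
  covariate columns are unidentifiable: they are flagged, pinned at
  β = 0 and reported with p = 1 while the remaining coefficients are
  estimated normally.

## Screening and selection

Per term, the log-rank uses the factorized burden levels actually
present (empty levels drop with the df), while the Cox model enters
the burden as a single numeric 0/1/2 covariate next to age at
diagnosis (years) and TP53 status — the two tests deliberately make
different assumptions, and the composite p-value
`CP = sqrt(p_rank · p_cox)` (the geometric mean, always between the
two inputs) rewards signatures that do well on both.  Constant burden
columns are flagged degenerate (p ≡ 1) and excluded from selection
rather than failing the screen.

Selection is two-stage: the strict joint rule
`p_rank < 0.05 ∧ p_cox < 0.05 ∧ CP < 0.025`, split by coefficient sign
into protective ("positive") and hazard-increasing ("negative")
predictors; then a relaxed rule admits additional negative predictors
with `p_rank < 0.01`, reflecting that the strict rule is conservative
for small poor-prognosis subgroups.  Ranking is CP ascending with the
term id breaking ties (the tie rule is ours; none was specified).

## Permutation FDR

The null model re-assigns whole clinical records (time, event, age) to
samples uniformly at random, keeping the mutation profiles — and hence
the burden matrix — fixed, and re-runs the screen per shuffle (default
500; the calibration tests use 100).  The FDR of a selection rule is

```
FDR = P_null(joint rule ∧ sign) / P_obs(joint rule ∧ sign)
```

with both fractions over (permutation × term) and term results
respectively, clamped to [0, 1]; a zero denominator yields an
explicitly flagged undefined estimate.  The sign restriction matters
because the null coefficient distribution is itself asymmetric.  Two
genuinely open points and our resolutions:

* TP53 status derives from the mutation profile but is used as a
  clinical covariate.  Since the mutation data stay fixed under the
  null, TP53 stays with the sample by default; `permute_tp53=True`
  implements the alternative reading (TP53 travelling with the
  clinical record).
* The joint three-threshold rule is applied in both numerator and
  denominator; the estimator is exposed for either coefficient sign.

The estimator is a ratio of small discovery fractions.  With few
screened terms the observed fraction is integer-granular (k
discoveries out of n terms), so single-cohort estimates are coarse;
calibration statements in the tests are therefore made over repeated
simulated cohorts.

## Prognosis tree

The tree is fixed, not learned: node 1 sums each sample's capped
burdens over the hazard-increasing predictors and labels the sample
poor when the sum reaches the burden threshold (default 2 — the same
dose at which single-term effects appear, and deliberately the same
value for both nodes); node 2 applies the identical rule to the top-k
protective predictors (k = 5 or 10 in the emulated study; any k up to
the number of available positive predictors is accepted) to split a
good group off the remainder.  Because the poor split runs first,
poor-group membership is independent of k, and increasing k can only
move samples from intermediate to good.  Groups are compared with the
k-group log-rank; ρ is forwarded for heavily censored cohorts.  No
automatic threshold adjustment is attempted for cohorts with
systematically higher mutation loads.

## Expression screen and term similarity

The expression screen fits one Cox model per gene with covariates
[expression, age] — age only, no TP53, matching the convention of the
emulated expression analysis — and returns genes with Wald p below the
threshold (default 0.01).  Expression values are fitted raw by
default; `standardize=True` z-scores each gene, which rescales β but
not its p-value.

Wang semantic similarity encodes each GO term by the S-values of its
ancestors: `S_A(A) = 1` and `S_A(t) = max over paths of
(product of relation weights)`, with weights 0.8 (is_a) and 0.6
(part_of), the method's published defaults; both weights are
configurable but must lie strictly inside (0, 1), which guarantees
decay and makes similarity 1 only for identical terms.  The S-values
are computed by a max-product Dijkstra over the ancestor subgraph.
Similarity is the shared-ancestor S-value mass over the total mass.
Cross-namespace pairs error in the scalar function and yield NaN in
the matrix function, so mixed term lists can be compared in one call.
Only is_a and part_of edges are used; others are dropped at OBO read
time with a warning.

## Synthetic cohorts

Defaults are the emulated study conditions: 320 samples; Poisson(50)
mutation records per sample drawn uniformly over 18,920 genes
(the annotated-gene count of the emulated study; at this coverage a
50–500-gene term has mean capped burden ~0.4, mostly 0 or 1 —
the dose regime the cap is designed for); TP53 spiked in with
probability 0.70; 100 terms with log-uniform sizes in [50, 500],
overlap allowed; age ~ Normal(60, 10) truncated at 18; survival
exponential with hazard
`(ln 2 / 44) · exp(Σ β_t · min(burden_t, 2) + 0.02 · (age − 60))`
per month (baseline median OS 44 months, typical of the disease) and
independent exponential censoring at 0.01/month (~40% censored).
A small age effect is always planted so the age covariate is
non-trivial in tests.  Planted effects act on exactly the capped
burden the screen tests, so recovery exercises the pipeline, not
model misspecification.  Progression-free survival is generated as a
faster (2×) exponential with the same linear predictor under the same
censoring process.

What the generator does **not** emulate: mutational context
(trinucleotide signatures), copy number, the GO DAG's real topology
(the synthetic ontology is a flat star), platform effects in
expression, and non-proportional hazards.  Passing tests therefore
show the pipeline recovers effects of the assumed form at the assumed
scale; they say nothing about hazards that violate proportionality or
effects not mediated by capped burden.

## Problem sizes used in the automated checks

Calibration and recovery checks run at the study scale (n = 320, 100
terms) with 100 permutations and 10–20 simulation repeats; the
two-group log-rank null calibration uses 2000 replicates of n = 50+50.
Unit tests use a scaled cohort (n = 120, 20 terms, 10,000 genes) that
preserves the per-term burden regime.

## Known limitations

* The Cox implementation supports neither time-varying covariates,
  stratification nor robust variance — none are needed here.
* The log-rank pseudo-inverse makes degenerate group structures return
  a defined (conservative) statistic rather than an error; the df is
  not reduced for rank deficiency beyond dropped empty groups.
* The permutation FDR inherits the granularity of small discovery
  counts (see above); with ~100 terms a single-cohort estimate can
  differ from the realized false-discovery proportion by a factor of
  2 when only 1–2 chance discoveries occur.
* Recomputing composite p-values from a summary table printed at two
  significant digits reproduces the printed CP at that precision for
  most but not all rows (17 of 22 in the packaged table); the
  remainder are off by one unit in the second digit purely from input
  rounding.
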