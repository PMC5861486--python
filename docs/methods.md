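# Methods

## Dose–response model

Mono-therapy viability is modelled by the three-parameter Hill curve
E(d) = E_inf + (1 − E_inf)/(1 + (d/EC50)^h) with the untreated response
fixed at 1. Fitting is deterministic least squares: a coarse grid over
E_inf × log10(EC50) × h (5 × 7 × 5; E_inf descending over [0, 1],
log10(EC50) within two decades of the tested range, h log-spaced over
[0.2, 10]) seeds Nelder–Mead refinements from the eight best grid
points, followed by one polishing restart from the incumbent. The
descending E_inf grid makes degenerate flat curves resolve to the
no-effect convention E_inf = 1 (an all-ones curve is equally well fitted
by E_inf = 0 with EC50 far above the tested range; the tie must be
broken deliberately). Bounds: E_inf ∈ [0, 1], h ∈ [0.2, 10].

Derived summaries:

* **IC50** — the dose with E(d) = 0.5, in closed form
  EC50·(0.5/(0.5 − E_inf))^(1/h); when E_inf ≥ 0.5 the curve never
  reaches half viability and the top tested dose is returned as a
  finite, order-preserving sentinel.
* **DSS** — with inhibition(d) = 100·(1 − E_fit(d)) evaluated on a
  1000-point trapezoidal grid in log10(dose) over the tested range, the
  area A of inhibition where it exceeds the activity threshold t
  (default 10%) is normalized as DSS = 100·(A − t·Δx)/((100 − t)·Δx),
  clipped to [0, 100]. Computed from the fitted curve, not the raw
  points, so noise does not enter the integral.

## Loewe surface and scores

The expected additive viability at (d_A, d_B) solves
d_A/D_A(E) + d_B/D_B(E) = 1 with D_i(E) = EC50_i·((1−E)/(E−E_inf,i))^(1/h_i).
The residual is monotone increasing in E, so the equation is solved by
vectorized bisection on E ∈ (max(E_inf)+1e−9, 1−1e−9), at most 100
iterations with early exit at residual ≤ 1e−8 (the interval contracts
to machine precision well before 100 halvings). When the doses exceed
both drugs' reachable effect there is no sign change and the nearer
bracket endpoint is returned, capping E at the viability floor — the
continuous limit of the implicit equation. Zero doses are handled
exactly: both zero → 1, one zero → the other drug's Hill response.

Scores over an n_A × n_B matrix (combination wells only; mono rows
carry no combination information): synergy S = 100·mean(E_loewe −
observed), addition A = 100·mean(1 − E_loewe). The mean×100 summary
matches the typical scale of published Loewe synergy distributions
(mean ≈ 4.5, sd ≈ 21 on large screens). Observed viabilities are
clipped to [0, 1.5] at read time — values above 1 (stimulation) are
kept, not truncated to 1. Mono-curve fits are cached by curve content
because one cell line's mono panel is shared across its combinations.

## Features

Blocks, in order: mutation, expression, cnv_amp, cnv_del (each |panel|
wide), targets (|target universe|), mono (6), addition (1), similar (8),
sl (1); total 4·|panel| + |targets| + 16. Conventions:

* Expression is z-scored per gene across the cell-line panel (the
  normalization method is a free choice; z-scoring keeps the
  under/over-expressed rendering of mined rules anchored at zero).
* Mono features use sums and *absolute* differences so the vector is
  invariant under swapping the two drugs, as are all other blocks
  (targets are the union; genomic blocks do not depend on drug order).
* The similar-sample block holds mean and median training-fold synergy
  for four groups: same cell line, sharing ≥1 drug, same unordered
  pair, sharing ≥1 drug AND same cell line. Only training-fold scores
  enter, and a training sample is excluded from its own groups, so no
  target information leaks into any feature. An empty group falls back
  to the global training mean/median.
* SL score: sum of confidences over SL pairs in which one gene is
  perturbed in the cell line and the other is targeted by either drug.
  "Perturbed" is operationalized as mutated or copy-number-altered;
  each unordered pair counts once even if both orientations qualify.
* Missing genomic entries are imputed as mutation 0, expression 0, CNV
  NEUTRAL with a logged warning; profile genes outside the panel are
  ignored (the panel is a dimension-reduction device).
* Duplicate experiments are collapsed by (cell line, unordered pair),
  first occurrence kept; replicate averaging is available behind a
  config flag but off by default.

## Models and evaluation

The 80:20 train/test split and the 5 CV folds inside the training set
are drawn once per seed. Grid search is exhaustive: each point is
scored by mean held-out-fold Pearson r (regression) or positive-class
F1 (classification); ties keep the first point in grid order; the
winner is refitted on the full training set. Degenerate folds (a
single-class fit set, or a metric undefined on the held-out fold) are
skipped rather than crashing; if the drop-zone threshold removes one
class from the training set entirely, the classifier degrades to a
constant majority-class predictor with a warning.

Default family grids: elastic net α ∈ 10^{−4..0} (5 log steps) ×
l1_ratio {0.1, 0.5, 0.9}; ridge α ∈ 10^{−4..2} (7); RBF kernel ridge
α ∈ 10^{−4..0} × γ ∈ 10^{−4..1}; forests trees {100, 500} ×
max-feature fraction {sqrt, 0.3, 1.0} × min leaf {1, 5}; logistic and
SVM C ∈ 10^{−4..2}. The *pipeline* defaults use a reduced forest grid
(200 trees, max features {sqrt, 0.3}, min leaf {1, 5}) sized so a full
default study trains in minutes on one CPU; the full grids remain
available through `ModelSpec`.

Evaluation: overall test Pearson r; r restricted to confidently
predicted samples (|prediction| > 10/15/20, with subset sizes);
per-cell-line r where a cell line has ≥ 3 test samples; the 1-based
predicted rank of the observed-best combination per cell line, with
prediction ties broken pessimistically (the worst rank among ties);
classification F1 after drop-zone labelling (score > +t positive,
< −t negative, the rest dropped — at t = 0 exact zeros are dropped),
with training restricted to retained samples at the same threshold.

## Rule mining

Every root-to-leaf path of a tree-ensemble regressor whose leaf
predicts ≥ s_min (default 15 score units) is collected; repeated splits
on one feature merge to the tightest interval; paths are truncated to
their first L = 4 conditions. Binary features canonicalize to =1/=0;
expression conditions with upper bound < 0 render "underexpressed" and
lower bound ≥ 0 "overexpressed", carrying the median of the
contributing tree thresholds as the representative numeric bound (used
for support counting and the two-group test). Signatures identical
after canonicalization are counted across trees; rules with sample
support < m = 20 are dropped, the rest are evaluated by a two-sided
Welch t-test (Satterthwaite degrees of freedom) between satisfying and
non-satisfying training samples, ranked by tree frequency with smaller
p as tie-break, and the top K = 10 returned.

The pipeline's `rules` stage trains a dedicated shallow random forest
(600 trees, depth 3, min leaf 10, max features 0.6) on the
genomic/target/SL blocks and mines with `interpretable_only=True`,
which keeps only fully canonical signatures. Continuous-threshold
conditions (SL score, raw expression bounds ≥ 0) almost never repeat
across bootstrapped trees — they fragment every signature — and
conditioning a rule on an SL cutoff biases its two-group contrast, so
the forest is allowed to *use* the SL feature while the reported rules
are restricted to target/genomics conditions. Depth-3 trees keep paths
rule-sized, which is what lets identical signatures recur.

## Synthetic study generator

The generator emulates a combination screen end to end: a gene universe
(default 80 genes) with a 60-gene panel arranged into 6 overlapping
gene sets; 20 cell lines with Bernoulli mutations (rate 0.05) and CNV
calls (0.03 amplification, 0.03 deletion) and N(0,1) expression; 15
drugs with 1–3 panel-gene targets; 50 SL pairs (half anchored at a
drug-target gene so the SL channel carries signal) with confidences
U(0.3, 1); per-drug Hill curves with E_inf ~ U(0, 0.6), log10 EC50 ~
U(−1, 1), h ~ U(0.8, 3), and a fixed 5-dose plate per drug log-spaced
±1.2 decades around its EC50. Drug sensitivity couples to genomics:
E_inf drops by 0.2 (floored at 0) when a target gene is mutated or
amplified in the cell line.

Planted synergy for each (cell line, pair):
s_true = 10·(SL score) + 20·1[rule] + N(0, 5), where the rule fires
when a drug in the pair targets the designated gene g* (shared by three
drugs) and the z-scored expression of a second, untargeted gene g' lies
below −0.5. The threshold is applied to the *z-scored* expression —
exactly what featurization emits — so the planted mechanism is
expressible in feature space; with 20 cell lines a raw-scale cutpoint
would shift by up to ~0.3 z-units per gene and decouple the mechanism
from its feature-space definition. s_true enters as a uniform viability
shift (−s_true/100) on the combination wells plus N(0, 0.02) well
noise, so the Loewe stage recovers s_true in expectation; mono rows get
the same well noise and are measured once per (cell line, drug), as in
a screen with one mono panel per plate.

What the generator does *not* emulate: correlated gene–gene expression
structure, realistic mutational signatures, dose-dependent (surface-
shaped) synergy, antagonistic mechanisms (negative scores arise only
from the N(0,5) residual, so the negative class is thin at high
thresholds), inter-lab replicate variance, and pharmacokinetics.
Passing tests therefore demonstrate correct recovery of the planted
mechanisms under this idealized model, not performance on real screens.

## Numerical and design notes

* Bisection tolerances: residual 1e−8, bracket floor/ceiling offsets
  1e−9; Hill fitting Nelder–Mead xatol 1e−8 / fatol 1e−12.
* The 5-point mono refit has intrinsic estimator variance: with
  σ = 0.01 well noise on the mono rows, the recovered synergy of an
  exactly additive matrix has mean absolute value ≈ 0.5 score units
  (a maximum-likelihood refit started at the true parameters shows the
  same spread, so this is statistics, not optimization). Per-matrix
  additivity-null deviations up to ~1.5 units at that noise level are
  expected; averages over replicates are unbiased to ≈ 0.3 units.
* Determinism: every stochastic component (simulation, split, forests)
  is seeded from the run seed; reports and artifacts are bit-for-bit
  reproducible, and the config hash excludes storage locations.
* Problem sizes: the test suite exercises the default 20 × 15 study
  across 10 seeds for rule recovery and 5 seeds for model comparison
  (ERT vs ridge, F1 by threshold); the acceptance script runs 3
  model-training studies and 5 mining studies. These sizes keep a full
  run in the minutes range on a single CPU while leaving the planted
  effects comfortably detectable.
* Known limitations: the Loewe cap at the viability floor max(E_inf)
  understates combinations whose joint effect exceeds either single
  agent's floor; IC50's sentinel cap makes the feature
  dose-range-dependent; rule p-values are reported raw, without
  multiple-testing correction across mined rules.
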