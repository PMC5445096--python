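# Methods

This note documents the models and procedures implemented in `hyqsar`, the
defaults that matter, and what the synthetic experiments do and do not show.

## Molecular graphs

SMILES strings are parsed with RDKit into heavy-atom graphs (hydrogens stay
implicit, as SMILES itself suppresses them; an `explicit_h` flag materializes
them when atom counts should include hydrogens). Aromaticity and R/S
assignment follow RDKit's perception; formal charges and stereo tags are kept
per atom. Unparsable SMILES raise an error naming the offending position;
valence violations are rejected at sanitization.

## Atom-level activation network (feature learning, step 1)

Each atom is a neuron. The connection matrix is built directly from topology:

- bonded pair → excitatory weight by bond order
  (single 0.10, double 0.20, triple 0.30, aromatic 0.15),
- non-bonded pair → a weak constant inhibition (−0.01), the "competition"
  part of the design,
- diagonal → 0; a separate self-feedback term β (default 1) enters the
  update instead.

Initial activations encode atom nature: per-element values in (0,1)
(electronegativity/4: C 0.636, N 0.761, O 0.860, S 0.645, halogens per
element, fallback 0.5), multiplied by (1±δ) for R/S stereocenters (δ = 0.05)
and shifted by +0.05 per unit formal charge, then clipped into (0,1). The
synchronous update is

    a_i(t+1) = σ( g · ( β·a_i(t) + Σ_j w_ij · a_j(t) ) ),   σ(x) = 1/(1+e⁻ˣ)

with gain g = 1, iterated until the max-norm state change falls below
ε = 1e−6 (at most 1000 iterations; non-convergence is flagged, not raised).
Every visited state is recorded: the A×R dynamic matrix, column 0 being the
initial state. A classical IAC increment rule
(Δa = (1−a)·net for excitation, a·net for inhibition, minus decay toward a
resting level) is available via `update_rule="iac"` for users wanting the
textbook dynamics; the sigmoid rule is the default because it is bounded and
convergent without clipping.

Because the update is a contraction under the default weights, the
equilibrium state is nearly independent of the initial state — so the
information carried by stereo tags and element identity lives largely in the
*transient* columns. That is precisely why the whole trajectory, not just the
fixed point, is kept.

Datasets are padded to a common (A_max, R_max): padding columns repeat each
molecule's equilibrium column, padding rows are zero, so every molecule
flattens to the same length. Padding is exactly invertible from the stored
per-molecule (A, R).

## Bottleneck reduction (feature learning, step 2)

An auto-associative network n–c–y–c–n (n the flattened trajectory length,
codification width c = max(10, 2y) by default, bottleneck y = 3) with sigmoid
hidden layers and linear output is trained to reproduce its input. Training
runs in cycles of 3000 weight updates; it stops when the full-data
reconstruction RMS reaches the target (0.005 in the production profile; the
test profile uses 0.05), when a configured number of cycles elapses without
improving the best RMS ("cycles past best", production 1000, test profile
50), or at the cycle cap. The weights (and codes) returned are those of the
best cycle, so the best-RMS sequence is non-increasing by construction.

Two trainers are provided: seeded minibatch gradient descent (default;
lr 0.05, batch min(16, n), gradients of the per-sample summed squared error)
and a Monte Carlo trainer (Gaussian weight perturbation σ = 0.02 with greedy
acceptance on a minibatch loss) honoring the stochastic-search description of
the original reduction tool. Weights initialize uniform(−0.5, 0.5) scaled by
1/√fan-in — without the scaling, sigmoid units saturate at realistic input
lengths (n ≳ 100) and training stalls. One network is trained per dataset
(not per molecule), which is what makes codes comparable across molecules;
training order is fixed by sorted molecule ids so input order only permutes
output rows. Codes are the bottleneck activations, named X1…Xy.

## Two-phase descriptor selection

Phase 1 (filter): drop columns with variance < 1e−8; for each pair with
|Spearman| > 0.95 keep the member more rank-correlated with the target; keep
the top-200 survivors by |Spearman| to target. Deterministic, ties broken by
column order.

Phase 2 (wrapper): 25 restarts of greedy forward selection. Each step adds
the descriptor minimizing 5-fold cross-validated RAE of a fast internal
linear model (closed-form least squares); selection stops when the relative
RAE improvement falls below 1% or at 15 descriptors. Each restart reshuffles
candidate order and fold assignment from a seed derived as
`(base·1000003 + restart) mod 2³¹`, so restarts can land on different local
optima; duplicates are merged keeping the best score and results are ranked
by RAE. Downstream analyses typically keep the two lowest-RAE subsets.

This filter/wrapper split is an openly declared approximation of the
two-phase selection tools used in the field, matching their interface
(multiple RAE-ranked candidate subsets) rather than their proprietary
internals.

## QSAR harness

**Discretization.** Published threshold rules ship as constants:
HIA < 0.7 → "Not Absorb", ≥ 0.7 → "Absorb"; logBB ≤ −0.7 → "BBB+",
(−0.7, −0.3] → "Gray area", > −0.3 → "BBB−" (implemented exactly as printed,
although this orientation inverts the conventional chemical reading — crossing
compounds usually have *high* logBB; relabel with a custom rule if needed);
ee ∈ [0,10] ∪ [90,100] → "High-enantiopurity" (boundaries inclusive to High),
(10,90) → "Low-enantiopurity". Values outside a rule's declared range raise
with the offenders listed.

**Splits.** Seeded shuffle, floor(n·fraction) training rows. Classification
uses stratified splits (per-class floor allocation, remainders by largest
fractional part, every class keeping at least one member on each side);
regression uses plain random splits — mirroring the tooling convention the
experiment design follows. Classes with a single member cannot be stratified.

**Learners.** Five families, era-default parameters recorded in
`LearnerSpec`: linear regression (least squares with greedy backward
elimination by the Akaike criterion; indicator regression for
classification), decision stump (exhaustive single split: squared error for
regression, class entropy for classification), MLP (one logistic hidden
layer of width ⌈(descriptors+classes)/2⌉, SGD back-propagation, lr 0.3,
momentum 0.2, 500 epochs — scikit-learn backend), random forest (10 unpruned
randomized trees, K = ⌈log₂ m + 1⌉ attributes per node — scikit-learn
backend), and random committee (ensemble of extremely-randomized trees
differing only in seed; the prediction is the arithmetic mean of member
outputs, held exactly). All stochastic learners are seeded.

**Metrics.** Regression: Pearson CC (a constant prediction scores CC = 0
with a warning), RAE = 100·Σ|ŷ−y| / Σ|y−ȳ_train|, RRSE =
100·√(Σ(ŷ−y)²/Σ(y−ȳ_train)²) — both relative to the training-mean baseline,
which scores exactly 100%. Classification: predicted class = argmax
probability (ties to the earlier class in rule order); %CC; one-vs-rest ROC
areas by the midrank statistic, averaged with prevalence weights (a class
covering every sample contributes a neutral 0.5); confusion matrix with
actual classes as rows; RAE/RRSE on probability-vs-indicator residuals
against the training class-frequency baseline.

**Hybridization.** Combined subsets are ordered unions (first subset's names,
then the second's unseen names), provenance-tagged with their parents so the
experiment summary can count scenarios where the union strictly beats both
parents. For reaction datasets (ee), substrate and ligand code tables are
joined row-wise per (substrate, ligand, target) pair, substrate columns
first; duplicate pairs are preserved.

**Random-replacement test.** To ask whether a descriptor group genuinely
contributes to a combined model, the group is replaced in each of 100
replicates by descriptors drawn uniformly from the remaining pool (fixed
subset and an exclusion list removed), the model retrained under identical
split/learner settings, and the CC recorded. Reported: the CC distribution,
its mean, and the empirical p-value (fraction of replicates reaching the
reference CC).

**Confidence intervals.** Paired metric series are compared by Student-t or
seeded percentile-bootstrap (10,000 resamples) intervals on the mean
difference; significance means the interval excludes zero. An (essentially)
constant difference yields a degenerate point interval, flagged rather than
raised.

## Descriptor analytics

Compound similarity: Pearson correlation between two compounds' code vectors,
affinely rescaled to [0,1] via (r+1)/2 (order-preserving and
dataset-independent; per-dataset min–max rescaling available by flag).
Constant code rows are rejected by compound id. Descriptor redundancy:
pairwise Spearman (midrank ties) or Pearson matrices; constant columns get
zero entries with a warning. Mutual information: equal-frequency
discretization with B = ⌈√n⌉ bins capped so joint cells average ≥ 5 samples,
Miller–Madow bias correction ((m_joint − m_i − m_j + 1)/(2n ln 2) bits,
subtracted when positive), normalized as symmetric uncertainty
U = 2·MI/(H_i+H_j) ∈ [0,1] — without the cap and correction the plug-in
estimate at √n bins reports U ≈ 0.12 for *independent* columns at n = 10⁴,
swamping real signal. Coverage profiles: 10-bin histograms over each
descriptor's range plus (value, target) scatter exports, no plotting
dependency.

## Synthetic data

The generator emulates the statistical structure the experiments assume, not
real medicinal chemistry. Molecules are random bonded trees over a
configurable alphabet (default C, N, O, S, Cl) with valence caps
(C4, N3, O2, S2, Cl1), occasional double bonds, and an optional single
benzene ring (probability 0.3), 3–12 atoms, emitted as canonical SMILES via
RDKit. Descriptor tables use simple graph statistics (atom count, heteroatom
count, ring count, branch count, mean bond order) as informative columns plus
standard-normal decoys; the target is Σ coefficients·informative + N(0, σ²).
Defaults are the planted-signal study conditions: 300 molecules, 2
informative columns with coefficients (2, −1), 50 decoys, σ = 0.1.
Everything is deterministic from one root seed.

What passing tests show: the pipeline recovers planted linear signal among
decoys, separates informative from random descriptor groups, and reproduces
its own runs bit-for-bit. What they do not show: performance on real
compound collections, whose descriptors are correlated, non-Gaussian and
non-linearly related to the endpoint, and whose class imbalance is more
severe than the generator's.

## Experiment grid

`run_experiment` executes every (subset × learner × split × task) scenario.
Per-scenario seeds derive from `root_seed + crc32(scenario key)` so adding
scenarios never perturbs existing ones; a failing scenario is logged and
skipped without aborting the run. Summaries flatten all reports to one row
per scenario, count combined-beats-both-parents scenarios per task, and pick
the best model per (dataset, task) — by CC for regression, %CC for
classification, ties broken by lower RRSE then input order.

## Problem sizes of the packaged experiments

The packaged tests and the acceptance script run on deliberately small,
seeded instances chosen to exercise every code path while staying cheap: 25
molecules for encoder properties, 30 molecules (c = 10, y = 3, target RMS
0.05) for reducer convergence, 300 molecules × 52 descriptors × 10 seeds for
feature recovery, 200 molecules with 100 replicates for the replacement
experiment, and a 5 × 3 × 2 grid (30 scenarios) for the end-to-end check.
The production reduction profile (target RMS 0.005, 1000 cycles past best)
remains the config default.

## Known limitations

- The original feature-learning tools' exact initial-value tables, stereo
  correction and Monte Carlo scheme are not public; the implementations here
  are declared approximations with every constant configurable.
- Classification RAE/RRSE assume probability residuals (the convention of
  the reference tooling); tools computing 0/1-loss residuals will differ.
- The wrapper's internal learner is linear; strongly non-linear planted
  signal can defeat phase-2 ranking (use the stump learner then).
- No class rebalancing: heavily imbalanced classification tasks show the
  expected minority-class precision decay.
- MLP training is backend-dependent to scikit-learn's SGD details; bit-level
  parity across scikit-learn versions is not guaranteed (seeded runs within
  one environment are exact).
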