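# Methods

## Data model

A panel holds an m × n integer genotype matrix (0 = homozygous major,
1 = heterozygous, 2 = homozygous minor) and a binary phenotype
(0 = control, 1 = case). All user-facing SNP indices are 1-based,
matching the optimizer's search space [1, n]; the 0-based layout never
leaks through the API. Missing genotypes use the in-memory sentinel −1
and the on-disk token `NA`, and are only legal before quality control.
The interchange format is the tab-separated layout emitted by common
penetrance-table simulators: a header of SNP names plus a final `Class`
column, one row per sample (a comma-separated dialect is also read and
written).

## Quality control

Filters run in the order: samples with genotype missing rate ≥ 2%
(default) are dropped; then SNPs are dropped when the missing rate is
≥ 5%, the Hardy–Weinberg equilibrium p-value in controls is < 1e-4, or
the minor allele frequency is < 0.1. HWE uses the 1-df chi-square
goodness-of-fit test against expectations from the estimated allele
frequency; monomorphic SNPs return p = 1 by convention. Remaining
missing genotypes are imputed to the per-SNP major-allele homozygote so
the scoring formulas never see incomplete tables.

One deliberate refinement: the SNP-level HWE and MAF statistics are
computed on the column with missing entries already replaced by the
major-allele genotype — i.e. on the column exactly as it will leave the
filter. This makes `qc_filter` idempotent and lets every retained SNP
verifiably satisfy the thresholds on direct re-check; computing the
statistics before imputation can flip a borderline SNP across a
threshold after imputation, breaking both properties.

## Scores

All scores are computed from the 3^k × 2 genotype-by-status table of a
combination (lexicographic genotype order, first SNP varying slowest).

* LR: G = 2 Σ o_ij ln(o_ij / e_ij), with e_ij the independence
  expectation; 0·ln 0 ≡ 0 throughout, so empty cells and empty rows
  contribute nothing.
* K2: the negative logarithm of the classic product form, evaluated as
  Σ_i [lnΓ(N_i + 2) − Σ_j lnΓ(N_ij + 1)] (J = 2, and lnΓ(J) = 0 drops
  out). Log-gamma keeps the value finite for row sums in the thousands,
  where factorials overflow.
* MI: H(A) + H(Y) − H(A, Y) in bits. Base 2 was chosen for test
  readability; any fixed base preserves the ranking.
* GINI: Σ_i P_i (1 − Σ_j P²_ij) with empty genotype rows skipped;
  bounded by 0.5 for two classes.

The optimizer minimizes, so `oriented_score` negates LR and MI (whose
large values mean strong association) and passes K2 and GINI through.
The linear mixed fitness of a score pair is the sum of min-max
normalized oriented components. Its bounds are estimated once from the
initial population's tables and then frozen; later out-of-range values
are clamped to [0, 1] per component, and a component whose score never
varied during calibration is flagged constant and contributes 0. This
keeps the mixed fitness a fixed function during the run — recalibrating
bounds mid-search would silently re-rank previously evaluated
combinations.

## Optimizer

Positions are real k-vectors in [1, n]^k. Decoding rounds half-up,
clamps to [1, n], and repairs duplicate indices by redrawing uniformly
among unused indices (seeded); the decoded combination is sorted.

Each generation, individual a_i draws a scale t from the success-history
memory (Cauchy with location at a random slot and scale 0.1, truncated
above at 1, redrawn while non-positive), picks a_pbest uniformly from
the top ⌈0.11·N⌉ individuals (minimum pool 2), a_r1 from the population
(≠ i) and a_h from the archive (from the population, ≠ r1, while the
archive is empty), and proposes

    candidate = a_i + offset,   ‖offset‖₂ = t · (‖a_pbest − a_i‖₂ + ‖a_r1 − a_h‖₂)

with the offset direction uniform over a 2-D circle (order 2, both
coordinates) or, for k ≥ 3, alternating by generation parity between a
random coordinate pair (2-D style) and a random triple (3-D style);
unselected coordinates are copied from the parent. Distances are taken
over the full k-vector even when only a subspace is perturbed. A
coordinate leaving [1, n] is reset to the midpoint between the violated
bound and the parent coordinate, which keeps repaired points interior
instead of piling up on the boundary.

Selection is greedy and strict (ties keep the parent). Winners are
appended to the archive, which is capped at round(2.6 × current
population size) with uniformly random eviction. Per generation, the
winning (Δf, scale) pairs update one memory slot with the
improvement-weighted Lehmer mean Σ w s² / Σ w s, the cursor advancing
circularly; generations without a success leave the memory untouched.
The population size follows the linear reduction schedule
round(((min − init)/budget)·FES + init) from 50 down to 4, removing the
worst-fitness individuals, after which the archive cap is re-enforced.

Every candidate evaluation increments the budget counter exactly once.
A memoization cache keyed by the sorted combination avoids recomputing
scores, but cache hits still consume budget — the budget counts
proposals, not distinct tables. The loop stops, mid-generation when
necessary, as soon as the budget is exhausted. Identical seeds give
bitwise-identical traces (one `numpy` Generator drives every random
choice, including fold assignment downstream). Default budgets: 20000
evaluations at order 2, 20000·k at order ≥ 3.

Per-generation traces record the evaluation count, population size,
best fitness/combination so far, and the memory slots; results carry
the best combination, its fitness, and the K best distinct combinations
ever evaluated.

## Simulator

A penetrance model is k minor-allele frequencies plus a 3^k table of
disease probabilities f(g), stored as JSON (`label`, `order`, `mafs`,
`table` row-major with the first SNP slowest) so published tables can
be transcribed verbatim. Genotype probabilities are Hardy–Weinberg
products across independent loci; prevalence K = Σ P(g) f(g);
heritability is the variance ratio h² = Σ P(g)(f(g) − K)² / (K(1−K)),
the definition used by the GAMETES simulator family; marginal
penetrances condition on one locus.

Datasets are drawn by rejection sampling: functional genotypes under
HWE, disease by Bernoulli(f(g)), individuals routed into the case and
control pools until both are full (bounded attempts, scaled by the
rarer of K and 1−K, with an explicit infeasibility error). Noise SNPs
are independent of status, each with its own MAF drawn uniformly from
(0.05, 0.5) by default. Functional SNPs are placed at random recorded
positions (fixable for regression tests), and rows are shuffled.
Default panel: 400 cases + 400 controls, 1000 SNPs.

The built-in models are synthetic fixtures, not transcriptions of any
published table: a parity (XOR) pair at MAF 0.5 with penetrance 0.1
(K = 0.05, h² = 1/19 ≈ 0.0526, no marginal effect), a two-locus
multiplicative model with marginal effects, a third-order parity model,
and a third-order additive model (MAF 0.25, h² ≈ 0.127, strong marginal
effects). The parity builder accepts a baseline penetrance: with
baseline 0 every case carries an odd-parity genotype whatever the
penetrance, so balanced case–control panels are equally easy at any
heritability; a nonzero baseline (0.05 in the power-response tests)
makes the in-sample effect actually scale with h², which is what a
power-versus-heritability study needs.

What the simulator does not emulate: linkage disequilibrium between
SNPs, covariates and population structure, genotyping error, and
quantitative traits. Passing tests therefore demonstrate correct
behaviour under idealized independence assumptions, not performance on
real cohorts.

## Evaluation

Power1 counts replicates whose returned best combination equals the
embedded truth (set equality). Power2 additionally requires the truth
combination's G-test p-value below 1/C(n, k); Power3 additionally
requires a multifactor-dimensionality-reduction classifier on the truth
to reach mean 10-fold stratified cross-validated prediction error below
0.45. Both follow-up tests evaluate the truth combination conditional
on a Power1 success, so the three criteria are nested by construction.
The G-test's degrees of freedom count only occupied genotype rows
(minus one), preventing sparse high-order tables from inflating df; a
fully degenerate table gets p = 1. The MDR rule labels a training cell
high-risk iff its case:control ratio strictly exceeds the overall
training ratio (compared by cross-multiplication, so empty cells and
exact ties are low-risk), and classifies held-out samples by cell
label; balanced accuracy is pooled over folds.

Cross-method comparison uses a paired two-tailed t-test on per-model
power vectors (all-zero differences defined as t = 0, p = 1) and a
Friedman rank test with the standard tie correction (higher power gets
the higher rank; a fully tied matrix yields statistic 0, p = 1). The
in-package Friedman implementation is cross-checked against an
independent reference implementation in the test suite.

## Problem sizes used in tests and the acceptance script

Exhaustive-search agreement is checked on 30-SNP, 200-sample panels at
a 5000-evaluation budget (order 2, all four scores) and on 20-SNP,
400-sample panels at 12000 evaluations (order 3) — budgets at least ten
times the number of combinations, where the search should essentially
always reach the global optimum. Power-versus-heritability uses
100 + 100 samples, 30 SNPs, 50 replicates per h² level. The acceptance
script measures 2-order power on 100-SNP panels (50 replicates, budget
20000) and 3-order power at the full 500-SNP, 2000-sample scale
(12 replicates, budget 60000).

## Known limitations

* The spherical move uses only the *magnitude* of the difference to the
  elite individual, with a freshly random direction: there is no
  directional pull toward pbest and no crossover-style inheritance of
  its coordinates. On 2-order problems the alternating subspace moves
  still recombine well, and detection matches exhaustive search on
  covered panels. On 3-order problems over large panels (hundreds of
  SNPs), however, the exact truth triple occupies ~1/C(n, 3) of the
  space and the search reaches "two truth SNPs + one wrong" local
  optima from which escape requires landing a precise two-coordinate
  jump; measured third-order detection at 500 SNPs / 60000 evaluations
  is well below 100% and insensitive to the model's effect size.
  Users targeting high-order interactions genome-wide should budget far
  more evaluations, pre-filter the panel, or run multiple seeds and
  pool the top-K lists.
* Pure (no-marginal-effect) interactions create needle landscapes: with
  no marginal gradient, detection probability on large panels is
  governed by how much of the combination space the budget covers.
* LMSE bounds frozen at initialization are estimates; components are
  clamped rather than re-normalized when later scores fall outside the
  initial range.
* The QC HWE test is the asymptotic chi-square, not the exact test;
  at very low minor-allele counts the exact test would be preferable.
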