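# Methods

## Statistical model

The theory underlying `snba.power` and `snba.simulation` is a two-group
comparison with known noise variance. The tested units ("atoms") are the
edges of a network; per atom j, group 1 observes μ_j + ε and group 2
observes μ_j + Δ_j + ε, with ε i.i.d. N(0, σ²). σ² is understood to
absorb both measurement noise and inter-subject variability, and is the
same for all atoms. Affected atoms carry a common positive shift
Δ_j = Δ; the alternative is one-sided (H_j: Δ_j > 0). Group sizes are
equal (n each) in the theory; unequal n₁, n₂ enter only through the
data-analysis tests in `snba.inference`.

The m atoms are partitioned into s disjoint subsets S_i of sizes m_i.
The atom-wise analysis (AWA) tests every atom's group mean difference
D_j; the subset-wise analysis (SWA) tests the subset means
T_i = (1/m_i) Σ_{j∈S_i} D_j, whose null SD is σ√(2/(n·m_i)). Both
families are corrected by Bonferroni at a global level α (or by the
Benjamini–Hochberg step-up at an FDR level q). All closed forms in
`snba.power` follow from these two Gaussian families; `pi_star` solves
Pow_SWA(π) = Pow_AWA in closed form and reports out-of-range solutions
(π* < 0 at very small Δ√n/σ, where the SWA dominates at every
proportion) with a flag rather than clipping silently.

Two monotonicity facts worth stating because they are easy to get
backwards: writing b = Δ√(n/2)/σ and a = Φ⁻¹(1−α/s) − Φ⁻¹(1−α/m) ≤ 0,
π* = (1 + a/b)/√m_i. Hence π* ≤ 1/√m_i always (strictly when s < m),
and π* is *increasing* in b: the grouping advantage (a smaller π*) grows
as noise grows and as effect size or sample size shrink.

## Tests on real data

For measured connectomes σ is unknown and the summary statistics need
not be Gaussian, so `snba.inference` offers:

* pooled-variance Student t (via `scipy.stats.ttest_ind`);
* Wilcoxon–Mann–Whitney (via `scipy.stats.mannwhitneyu`): exact null
  distribution when n₁+n₂ ≤ 12 and there are no ties, otherwise the
  normal approximation with tie and continuity corrections. Rank tests
  are the default for the truncated and effective-mean summaries, whose
  null distributions are unknown;
* a Hotelling-type statistic for p-variate summaries. The pooled
  covariance uses (n−1)-weighting,
  Sp = [(n₁−1)C₁ + (n₂−1)C₂]/(n₁+n₂−2), scaled by (1/n₁+1/n₂), and
  f = (n₁+n₂−p−1)/((n₁+n₂−2)p) · tᵀC⁻¹t is referred to
  F(p, n₁+n₂−p−1). At p = 1 this reduces exactly to the squared pooled
  t, which the test suite verifies to 1e-10. The covariance condition
  number is checked against a configurable bound (default 1e12) and a
  singular matrix raises with advice (fewer components or more
  subjects).

Degenerate units (identical values in both groups) get p = 1 with a
warning rather than an error, so a single flat edge cannot abort a
whole-matrix analysis.

Sidedness defaults differ by context, deliberately: the power theory and
the simulation engine are one-sided (positive effects only, matching the
model above); the data-analysis pipelines default to two-sided, since a
real comparison must detect both increased and decreased connectivity.

## Multiplicity

`snba.multiplicity` implements Bonferroni and the BH95 step-up directly
(a handful of numpy lines each) because the Monte-Carlo engine needs a
row-wise vectorized BH over thousands of replicate p-value families;
`statsmodels.stats.multitest` serves as an independent cross-check in
the test suite, and a brute-force step-up oracle verifies the decision
rule on all small families. Adjusted p-values use the monotone
cumulative-minimum transform, so `p_adj ≤ level` reproduces the raw
threshold decisions exactly; the threshold forms are also exposed
because the two-stage propositions are stated in threshold terms.
Per the standard convention, the false discovery proportion is defined
as 0 when nothing is rejected.

## Two-stage procedure

`two_stage_analysis` selects blocks by the SWA at a configured level,
then tests the atoms of each selected block, corrected over that block's
m_i atoms at the stage-2 level (a `union` option corrects over all
selected blocks' atoms together, which is more conservative). The
procedure controls false positives *weakly* — under the global null a
stage-2 rejection requires a stage-1 false selection first, so the
probability of any stage-2 false positive is at most the stage-1 FWER —
but not strongly; the simulation suite asserts only weak control.

`prop1_condition(α, s, m_i)` evaluates Φ⁻¹(1−α/s) ≥ √m_i·Φ⁻¹(1−α/m_i).
When it holds, a stage-1 Bonferroni-significant subset mean forces at
least one atom through the stage-2 Bonferroni test (if all m_i atom
differences were below the stage-2 critical value σ√(2/n)Φ⁻¹(1−α/m_i),
their mean would be below the stage-1 critical value). The condition is
restrictive for m_i ≥ 4 at ordinary family sizes — e.g. at α = 0.05 it
needs s ≥ 18 for m_i = 2 but s ≈ 14,000 for m_i = 4 — and
`simulate_prop1` verifies the zero-counterexample claim by conditioning
on stage-1 significance. Inside selected subsets, stage-2 detection
dominates the global AWA deterministically (the stage-2 critical value
is smaller because m_i < m), which the paired simulation confirms.

## Monte-Carlo engine

Because the atom-wise and subset-wise z statistics depend on the data
only through the per-atom group mean differences D_j ~ N(shift_j,
2σ²/n), `snba.simulation` draws the D_j directly instead of simulating
n subjects per group — distributionally identical for every quantity
reported and an order of magnitude faster. Replicates are chunked to
bound memory at a few million draws at a time; all routines accept a
seed (or share a `numpy.random.Generator`) and are bit-reproducible.

Default study conditions for the power-curve grid: raw effect
Δ ∈ {1, 2}, subset sizes m_i ∈ {4, 8, 16}, σ = 1, n = 20, α = 0.05,
s = 32 subsets of which s1 = 8 are affected, π on the grid k/m_i (the
simulation only visits proportions with an integral affected count
k_i = π·m_i; other π are handled analytically). Average power is the
mean fraction of affected atoms (AWA) or affected subsets (SWA)
detected, reported with its Monte-Carlo standard error alongside the
closed-form values. Cells with no affected units report NaN power.

## Synthetic studies

`snba.synth.generate_study` emulates a structural-connectivity study:
per subject a density matrix (baseline 10 + N(0, σ²) per edge, planted
blocks shifted by Δ in group 2) and an FA matrix with values in
(0.05, 0.95) drawn through a Gaussian copula, independent of the density
noise by default (`fa_corr` couples them for stress-testing the
truncated summaries). Affected atoms are sampled uniformly without
replacement within each chosen block. Negative densities are clipped at
0 and counted; with the default baseline/σ ratio of 10 clipping is
(and should be kept) negligible, since the Gaussian theory above is the
reference. `demo_lobe_partition` provides 83 ROIs in 13 groups (six
bilateral cortical lobes of 9/6/7/5/4/3 regions plus 15 subcortical),
giving the 91 blocks of the intended application scale.

What the generator does *not* emulate — and hence what passing tests do
not certify about real connectomes: spatially correlated noise between
edges, heavier-tailed weight distributions, subject-level global scaling
differences, parcellation mismatch across subjects, and any dependence
of FA on fiber density beyond the optional copula knob. The error-rate
guarantees shown are for independent Gaussian noise; rank tests give
level-robustness, not variance-reduction optimality, under departures.

## Numerical choices

* Matrix symmetry tolerance 1e-8 (absolute, configurable); matrices are
  stored as (A + Aᵀ)/2 after validation.
* Self-connections A(r, r) are excluded by default; an
  `--include-diagonal` option adds them as extra atoms of diagonal
  blocks (the application convention for matrix diagonals is not
  universal, so it is a switch rather than a guess).
* FA truncation is strict (>) by default and configurable; the
  truncated statistic is offered both as a count and as a proportion
  (count / m_i).
* Effective mean over an empty truncation set is 0 with a warning.
* Block order (group order, diagonal-first within pairs of equal first
  group) fixes all output row orders; atom order is row-major within a
  block; ties in BH are rejected together.
* Default levels: FWER 0.05 (Bonferroni), FDR 0.1 (BH95).

## Problem sizes in the shipped checks

The test suite runs the power grid at 10⁴ replicates per cell, the
error-rate simulations at 2,000 replicates, the Proposition-1 check on
10⁵ conditioned significant subsets, and the end-to-end recovery study
on 100 generated 83-node studies (n₁ = 14, n₂ = 12, three planted blocks
at Δ = 1.5σ with π ≥ 1/√m_i); the whole suite completes in well under a
minute on one core. `scripts/acceptance.py` uses 2,000 replicates per
target. Larger runs only tighten the Monte-Carlo error bars.

## Known limitations

* The closed-form theory assumes known σ and equal group sizes; power
  under estimated variance (noncentral t) is out of scope, as is an
  analytic treatment of FDR-corrected power (simulation only).
* Correlated-noise simulations are not provided (the model is
  independent white noise); positive within-block correlation would
  change the SWA null variance and is exactly the situation where the
  mean summary borrows the most strength.
* Stage-2 p-values are not selection-adjusted; the two-stage procedure
  is exploratory beyond weak control.
* Network-topological summaries (degree distributions, small-world
  indices, modularity) are not implemented as block statistics.
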