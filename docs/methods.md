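# Methods

This note records the statistical models implemented in `tcross_gs`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Phenotype model

Trials are unreplicated: each hybrid (pollinator × tester) is observed once
per location. Three quantities are derived per trait.

**BLUEs.** The two-way additive fixed model
`value = μ + hybrid_i + location_l + ε` is solved by least squares on a
dummy design (full hybrid indicators absorb the intercept, drop-first
location indicators). A hybrid's BLUE is its model prediction averaged over
*all* observed locations, so hybrids missing a location are adjusted onto a
common scale; with complete balanced data this reduces exactly to the
hybrid's raw mean. With a single location the observed values are returned
unchanged and variance estimation is refused (location and residual effects
are confounded). Hybrids are treated as fixed here and as random for
variance components — the only combination under which location-adjusted
hybrid estimates and genetic variance components are both defined.

**Variance components.** REML with hybrid random and location fixed. The
restricted likelihood is profiled on γ = σ²_g/σ²_ε, using the analytic
block inverse (I + γJ)⁻¹ = I − γ/(1+γn_i)·J per hybrid, and minimized by
bounded scalar search on log₁₀γ ∈ [−12, 12]; the γ = 0 boundary (no genetic
variance) is evaluated explicitly and wins ties. When the search hits the
upper bound — data with essentially zero within-hybrid residual, where the
restricted likelihood is unbounded in γ — the genetic variance is instead
estimated from the adjusted hybrid effects directly (OLS on hybrid +
location dummies, sample variance of the hybrid coefficients). Estimates
are therefore non-negative by construction. statsmodels' MixedLM serves as
an independent oracle in the test suite; it was not used as the
implementation because its default optimizers mis-converge precisely at
these boundary cases (verified against a brute-force restricted-likelihood
grid).

**Heritability and GCA.** Broad-sense heritability is
`H² = σ²_g / (σ²_g + σ²_ε/n) × 100` with *n* the number of locations — the
residual variance of a mean over *n* trials. GCA of a pollinator is its
tester-mean BLUE minus the grand mean of all hybrid BLUEs; values are
centered deviations and sum to zero whenever every pollinator carries every
tester. This definition is validated by construction: in a purely additive,
noiseless simulation it recovers the true breeding values up to an affine
transform (correlation 1).

## Marker quality control

Filters apply to markers only, in a fixed order: (1) fraction of missing
calls strictly above `max_missing` (default 0.20), (2) monomorphic (a
single distinct non-missing call), (3) minor-allele frequency strictly
below `maf_min` (default 0.05), computed on non-missing calls with each
fully scored inbred line contributing two alleles. The order matters only
for attribution — each removed marker is charged to the first rule that
fires — and was chosen because MAF estimates are unreliable on
high-missingness markers. Boundary markers (exactly 20% missing, MAF
exactly 0.05) are retained. Imputation replaces missing calls with the
marker's mean coded value, which preserves the marker mean and MAF exactly
and makes the pipeline idempotent.

## Population structure

For additively coded calls x ∈ [−1, +1] the within-individual allele
frequency is p = (x+1)/2 and the per-locus Rogers term
√(½[(p_i−p_j)² + ((1−p_i)−(1−p_j))²]) collapses to |x_i − x_j|/2, so the
distance matrix is a scaled Manhattan distance — exact for homozygous,
heterozygous and mean-imputed fractional calls alike.

PCoA is classical scaling: eigendecomposition of −½·J·D²·J. Rogers
distances need not be Euclidean, so negative eigenvalues can occur; they
are excluded from both the returned coordinates and the explained-variance
denominator (a requested axis count above the positive rank is truncated
with a warning). K-means runs on the leading PCoA coordinates (default 4
axes) rather than the raw marker matrix — the ordination-space choice is
configurable since the literature uses both. Lloyd iterations with
k-means++ seeding and 50 restarts by default; the Caliński–Harabasz index
`[B/(k−1)]/[W/(n−k)]` selects k over a range, ties breaking to the smallest
k. Both the index and the ordination are cross-checked in tests against
sklearn and scikit-bio implementations.

## RR-BLUP

The model is `y = Wβ + Xa + e` with an always-present intercept in W,
marker effects a ~ N(0, σ²_a·I), σ²_a = σ²_G/N_m, and e ~ N(0, σ²_e·I).
The variance ratio δ = σ²_e/σ²_a is estimated by REML on the spectrum of
the fixed-effects-projected genomic cross-product S·XXᵀ·S — an EMMA-style
profile that costs one n × n eigendecomposition, the right shape when lines
(hundreds) are far fewer than markers (tens of thousands). The scalar
search runs on log₁₀δ ∈ [−10, 10] with tolerance 1e−8. Given δ, fixed
effects are GLS against H = XXᵀ + δI and marker BLUPs are
a = XᵀH⁻¹(y − Wβ̂) — Henderson's mixed-model solution, identical to ridge
regression at fixed penalty λ = δ (the `ridge_fixed_lambda` helper exposes
that closed form and doubles as a test oracle). Markers keep their −1/0/+1
mean-imputed coding; no re-centering beyond the fitted intercept.

Numerical notes. Eigenvalues of the projected kernel are clipped at zero;
H is solved by Cholesky. On noiseless data the REML estimate of δ sits at
the search floor only about half the time — the standard boundary behavior
of variance-ratio estimators — so exact interpolation of training data is a
property of the λ → 0 limit, not of every finite-sample REML fit; the test
suite checks both statements separately. A constant response or a
rank-deficient fixed-effect design is rejected outright.

## Cross-validation

Each round draws round(f·N) training lines without replacement from the
scenario's sampling frame, fits RR-BLUP, predicts the held-out validation
lines and records r_GPA = Pearson r(ŷ, y). The summary is the mean over
rounds with the standard error of that mean — defined here as the sd of the
per-round accuracies divided by √rounds, recomputable from the stored
per-round vector. Rounds
with a degenerate validation set (zero variance in either vector) are
excluded from the summary and counted.

Scenario definitions: *whole_population* samples training and validation
from all lines; *within_cluster* restricts both to one cluster (refused
below 15 lines, where both sets become uninformative);
*cross_cluster_train* samples training from all lines but sizes it to match
the corresponding within-cluster run — accuracy comparisons between the two
are then size-controlled — and validates only inside the target cluster;
*structure_covariate* adds drop-first cluster indicators to the fixed
effects of both fit and prediction. With covariates present, predictions
include the covariate contribution; on data whose only signal is a
between-cluster mean shift this leaves the between-cluster correlation
intact while the marker-effect variance collapses — the covariate gives no
accuracy improvement rather than an accuracy collapse, which is what the
no-improvement checks in the test suite assert.

Reproducibility: round r of a run with master seed s uses the stream
`SeedSequence([s, r])`; sweep fraction i runs under the derived master seed
`SeedSequence([s, 1_000_000 + i])`. Any single round is re-runnable in
isolation, and identical seeds give bit-identical results.

## Synthetic studies

The generator emulates the motivating design: fully inbred pollinators
(calls ±1; fractional codes arise only from downstream imputation) in
subpopulations whose per-locus allele frequencies follow a Balding–Nichols
model around a shared ancestral frequency drawn uniform on [0.1, 0.9];
F = 0 reproduces the ancestral frequency exactly. Phenotypes are
y = μ + GCA_p + tester_t + SCA_{p,t} + location_l + ε with sparse additive
QTL (GCA_p = Σ x_{p,q}a_q), fixed tester and location offsets spread
symmetrically about zero and scaled to the GCA standard deviation, SCA
drawn at a configurable fraction of the GCA variance (default 0.1 — a
modelling choice reflecting that testcross GCA variance dominates SCA in
hybrid canola), and a
residual variance solved from the *realized* hybrid genetic variance so the
realized H² equals its target exactly. An optional per-subpopulation sign
vector flips the marker–QTL linkage phase inside chosen subpopulations, the
device used to study cross-subpopulation training. One master seed feeds
named per-stage RNG streams (ancestral frequencies, subpopulation
frequencies, genotypes, missingness, QTL, SCA, residual), so outputs are
bit-identical given a seed.

Defaults are the study conditions: 475 lines in subpopulations of
286/147/42, 24,403 markers, 2 testers, 4 locations; fst = 0.1 (moderate
crop-subpopulation divergence, cleanly separable in PCoA), 100 QTL, 2%
missing calls.

Under ±1 inbred coding the per-locus genetic variance is
4p(1−p)a² — equivalently 2p(1−p)(1+F)a² at F = 1 — and the empirical GCA
variance converges to Σ_q 4p_q(1−p_q)a_q², which the test suite verifies at
n = 2000 lines.

**What the generator does not emulate.** Markers are unlinked: there is no
linkage map, no LD between markers, and QTL are themselves panel markers.
Prediction accuracy therefore scales like √(N·h²/(N·h² + M)) with M the
*full* marker count, whereas in real genomes LD compresses M to a much
smaller number of effective segments — that is why a real 24k-marker panel
on 475 lines can reach accuracies near 0.8 while an unlinked 4,000-marker
simulation at the same population size sits near 0.3. Passing tests
demonstrate correct machinery and the right qualitative responses
(monotonicity in heritability and training size, the high-fraction plateau,
phase-flip collapse), not the absolute accuracy levels of LD-rich data.
There is also no genotype × environment interaction, no epistasis beyond
the single SCA term, and no multi-generation breeding.

## Problem sizes in tests and the acceptance script

Test simulations use 60–475 lines, 100–3,000 markers and 3–100 CV rounds;
the acceptance script runs the full 475-line population shape at 4,000
markers with 60-round cross-validations, plus one 475 × 24,403 distance +
ordination pass in the acceptance test. These sizes are the package's
choices for fast, deterministic verification; every operation accepts
full-scale data (the 475 × 24,403 distance/PCoA stage runs in seconds, and
the REML core scales with lines, not markers).

## Known limitations

* GCA centering is global (grand mean of all hybrid BLUEs); per-tester-pool
  centering would differ if tester effects were strongly unbalanced.
* The within-cluster/cross-cluster training-size match is this package's
  convention for size-controlled comparisons; other conventions exist.
* REML variance components assume homoscedastic residuals across locations;
  unreplicated designs cannot separate genotype × location interaction from
  residual, so both land in σ²_ε.
* The VCF importer handles biallelic SNPs only; multi-allelic records are
  skipped and counted.
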