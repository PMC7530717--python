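# Methods

This note documents the models, numerical choices and open design decisions
behind `cismr`, and what the simulation results do and do not demonstrate.

## The generative model

Phenotypes are simulated in one *cis* region under a two-exposure model.
With `X` the raw dosage matrix of a cohort:

```
y_E = X β_E + C + ε_E          (observed exposure)
y_U = X β_U + C + ε_U          (unobserved, pleiotropic exposure)
y_O = y_E b_E + y_U b_U + C + ε_O
```

Nonzero per-allele effects are drawn fresh each replicate from U(−0.5, 0.5)
on the causal sets `s_E`, `s_U` (k = |s_E| = |s_U| ∈ 1..10).  `C` is a
per-individual confounder shared by all three traits within a cohort,
`C ~ N(0, var = 0.5)`; all noise terms are standard normal.  The notation
N(0, 0.5) is read as *variance* 0.5, consistent with ε ~ N(0, 1) having
variance 1; the confounder variance is an exposed parameter, since a
reading as SD = 0.5 is also defensible.

Causal sets and effects are shared across cohorts; `C` and the noise are
redrawn per cohort.  Pleiotropy modes:

* **ld** — each member of `s_U` is drawn from the variants with
  0.25 < r² < 0.95 to at least one member of `s_E`, disjoint from `s_E`.
  A draw of `s_E` whose moderate-LD pool is too small is resampled
  (an infeasibility error after 50 attempts).
* **overlap** — `s_U = s_E`.
* **mixed** — `⌈f·k⌉` members of `s_U` copied from `s_E`
  (`f` = overlap fraction), the rest from the moderate-LD window.

## The genotype simulator

Cohorts are expanded from a synthetic haplotype panel by Li–Stephens-style
mosaic copying (switch to a random panel haplotype with probability 0.005
per inter-variant interval; per-site mismatch 0.002).  The panel itself is
a founder-mosaic model chosen to emulate the qualitative LD features of a
dense, sequencing-based European reference panel expanded to cohort scale:

* 100 kb LD blocks, 16 founder haplotypes per block; every panel haplotype
  copies one founder per block;
* founder allele patterns evolve along the chromosome as a Markov chain
  (renewal probability 0.01 per variant, per-founder flip 0.008), giving a
  decaying r² continuum: abundant near-duplicate pairs (r² > 0.95), a
  moderate-LD pool whose density behaves like ~1/r² on (0.25, 0.95), and
  weakly linked distal pairs;
* renewal frequencies are drawn U-shaped (Beta(0.35, 0.35)), skewing the
  site-frequency spectrum towards rare minor alleles;
* four subpopulation groups run parallel founder chains against shared
  frequency targets, and cohort individuals copy within their group.  The
  resulting frequency drift produces weak long-range background LD
  (cross-block r² ≈ 0.005), the structure-induced correlation real cohorts
  carry and that matters for estimators assuming independent instruments.

Default scale: 1000 variants after the MAF ≥ 0.01 filter (the full ~3100
variants of a densely genotyped megabase are available via configuration),
cohorts of 15000 (outcome), 5000 (exposure) and 5000 (LD reference).

What the generator does **not** reproduce: coalescent genealogies,
recombination-map variation, mutation-age/frequency correlation beyond the
imposed spectrum, X chromosomes, multi-allelic sites, genotyping error.
Passing simulation benchmarks therefore demonstrates behaviour under
realistic LD *structure*, not under every idiosyncrasy of real panels.
In particular the real-data variant density (~3 per kb) is about three
times ours, which plausibly explains why the clumping-vs-conditional
IV-selection contrast, though reproduced directionally, is smaller here
than on real-LD simulations.

## Association scans and instrument selection

Marginal scans regress the phenotype on one standardized dosage column at a
time (within-cohort mean 0, variance 1), classical SEs, t-distribution
p-values with n−2 df.  Exposure scans additionally standardize the
phenotype, matching eQTL-style summary statistics.  Monomorphic variants
yield flagged NaN records, never silent drops.

Conditional-joint selection reconstructs joint models from marginal
statistics plus reference LD on the correlation scale: the marginal effect
of variant j is recovered exactly from its z-score as
`r_j = z_j / √(z_j² + n − 2)`, and a joint fit of set S uses
`β_S = R_S⁻¹ r_S` with residual variance `(1 − r_S'β_S)·n/(n−|S|−1)`.
Stepwise forward selection admits, per step, the candidate with the
smallest conditional p-value if it passes p < 5×10⁻⁸ and stays below the
collinearity cap (r² < 0.9 with every selected variant, the GCTA default —
the threshold is not stated in the method description we follow, so the
tool default is adopted and exposed).  Ill-conditioned candidates (Schur
complement < 10⁻³) are dropped with a warning.  Ties in p break by variant
position, then id.  The per-fit effective sample size is the minimum n over
the involved variants (conservative).  Clumping greedily keeps the
best-p variant and removes everything at r² > 0.1 to it; no joint fit.

## The ridge joint model

The design has one genetic-exposure column `X β̂_E / m_E` (standardized
dosages, conditional betas at the IV positions) and the tag block
`X_T / √m_T`.  Numerical choices:

* **Penalty.** λ is expressed relative to the mean diagonal of the design
  Gram matrix (so its strength tracks the per-column signal scale; for the
  tag block that diagonal is n/m_T).  Default λ = 0.1, chosen in a design
  experiment on this package's own simulator as the smallest penalty that
  keeps the null Wald statistic well-behaved while preserving power; both
  smaller and larger values are one keyword away.  The penalty applies to
  all coefficients (the equation treats the coefficient vector uniformly);
  `penalize_exposure=False` switches to a tag-only penalty.
* **Inference.** SE from the ridge sandwich covariance
  `σ̂² A⁻¹ X'X A⁻¹`, `A = X'X + λI`; residual df = n − tr(A⁻¹X'X);
  t-reference with that df (indistinguishable from normal at these n).
* **Estimate scale.** The 1/m_E column scaling multiplies the raw first
  coefficient by m_E; the reported estimate and SE are divided back by m_E
  so the causal effect reads in outcome units per SD of the (genetically
  predicted) exposure, independent of the IV count.  The Wald statistic is
  invariant to this.
* **Attenuation (limitation).** Tags are collinear with the exposure
  predictor by construction, so the ridge *point estimate* is shrunk
  towards zero in heavily tagged regions — the tag-free OLS limit recovers
  the causal effect exactly, the full model keeps the sign but can
  attenuate severalfold.  Hypothesis testing is unaffected because the
  decision runs through the calibrated p-value, but reported effect sizes
  should be read as conservative.
* **Statuses.** No IVs → `too_few_ivs`; singular λ=0 systems →
  `no_solution`; failures are recorded, never dropped.

## P-value calibration

The raw ridge Wald p-value is miscalibrated (its null law depends on k, the
tag count and λ), so final p-values are the probability integral transform
through a Beta(a, b) distribution fitted by maximum likelihood to raw null
p-values.  The calibration null for a scenario with k causal variants and
pleiotropy strength b_U is the *pleiotropy-through-LD* null (b_E = 0, same
k, same b_U, same IV selection) — the null consistent with the model's
assumption that pleiotropy acts through variants in LD with the IVs.
LD-mode null scenarios are thus their own calibration set (their measured
FPR ≈ α up to beta-fit error, which at 200 replicates puts the maximum
over four scenarios near 0.06), while overlap-mode scenarios borrow the
LD-mode fit and honestly reveal the method's failure mode when the IV
itself is pleiotropic.  Degenerate fits fall back to the empirical CDF
with a warning.  In real-data use the recommended null set is the ensemble
of all tested exposures, under the assumption that most are null.

## Comparators

* **IVW** — fixed-effect meta-analysis of per-IV Wald ratios β'_O/β'_E with
  the two-term SE `√(se_O²/β'_E² + β'_O² se_E²/β'_E⁴)`.  An
  auditability flag reproduces a published variant with the inverted ratio
  and a β'_E² second-term denominator.
* **MR-Egger** — WLS of β'_O on β'_E with intercept, weights 1/se_O².
* **LDA-MR-Egger** — the same regression by GLS with error covariance
  D·R·D (R = signed IV LD, D = diag(se_O)).
* **MR-PRESSO** — leave-one-out IVW residual sum of squares against a
  parametric simulated null; per-IV outlier tests Bonferroni-corrected at
  0.05; IVW on the survivors; `too_many_outliers` below two survivors.
  A dominant outlier contaminates every leave-one-out fit and can flag all
  IVs — a real, documented failure mode, not a bug.
* **Colocalization** — per-variant Wakefield approximate Bayes factors for
  each quantitative trait (prior effect SD 0.15·sdY; sdY estimated from
  varbeta/MAF/n, fixed to 1 for standardized traits, or passed explicitly),
  single-causal-variant hypothesis sums with priors
  p1 = p2 = 10⁻⁴, p12 = 10⁻⁵, declared at PP4 > 0.9 (strict).

Applicability: IVW and the ridge joint model run from one IV; the Egger
family and MR-PRESSO need three.

## Benchmark design

The full grid is k ∈ 1..10 × b_E ∈ {0, 0.05, 0.1, 0.2, 0.4} ×
b_U ∈ {0, 0.4} — 100 scenarios per pleiotropy mode; the desk-scale default
runs k ∈ {1, 3, 5, 10} with 200 null / 150 causal replicates per scenario,
cohort sizes kept at 15000/5000/5000.  One simulated region is shared
across replicates (and, in the headline summary, across scenarios);
architectures, effects and phenotypes are redrawn every replicate.
Per-scenario results with 100 or fewer successful estimates are flagged
unreported.  AUC uses the rank (Mann–Whitney) formulation with half-ties;
decision scores are PP4 for colocalization and 1 − p otherwise.

Seeds: a master seed spawns per-scenario and per-replicate substreams; all
simulation is bitwise reproducible given the master seed.

## Known limitations

* Quantitative outcomes only; no binary-trait likelihood.
* Single-region analyses; genome-wide runs are plain loops.
* Point-estimate attenuation in heavily tagged regions (above).
* The overlap-mode false-positive rate depends on how much of an IV's
  signal its tags absorb, which in turn tracks the panel's near-duplicate
  density; with our generator it comes out somewhat higher than on
  real-LD simulations.
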