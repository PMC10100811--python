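# Methods

## The animal model for per-ASV heritability

For one ASV, the response vector `y` holds the natural log of
(relative abundance + pseudocount) across all rumen samples.  The model is

    y = Xb + Za + Wm + e

* `b` — fixed effects: intercept, year-season (dummy-coded, reference =
  lexicographically first level), group (dam vs lamb) and age in days as a
  centered covariate.  Aliased columns are dropped to full rank by pivoted
  QR and the dropped names logged.
* `a ~ N(0, A σ²ₐ)` — additive genetic effects over *all* pedigree animals
  (including unsampled sires), with `A` the numerator relationship matrix.
* `m ~ N(0, I σ²ₘ)` — maternal environment, one level per dam that appears
  as the mother of a sampled animal.  A sampled animal whose own dam is
  unrecorded (all founder ewes) gets an all-zero `W` row, i.e. no maternal
  effect; the additive and maternal effects are uncorrelated.
* `e ~ N(0, I σ²ₑ)` — residual.

Heritability is `h² = σ²ₐ / (σ²ₐ + σ²ₘ + σ²ₑ)`; an ASV is screened as
heritable when `h² > 0.2` **and** `p < 0.05`, both strict, applied to the
point estimate (the confidence interval is recoverable from the SE).

### Relationship matrices

`A` is built by the tabular method (`a_ii = 1 + ½ a_{sire,dam}`,
`a_ij = ½(a_{j,sire(i)} + a_{j,dam(i)})` in parents-first order), which
also yields the inbreeding coefficients `F_i = a_ii − 1`.  `A⁻¹` is built
directly by Henderson's rules with the inbreeding-aware Mendelian-sampling
variances (`d_i = ½ − ¼(F_s + F_d)` for two known parents, `¾ − ¼F_p` for
one, 1 for none).  Both are validated in the tests against a gene-dropping
simulation (unique founder alleles, vectorized Mendelian transmission,
relationship = 2 × kinship) and dense matrix inversion.

### REML

The restricted likelihood of `y ~ N(Xb, σ²ₐ ZAZ' + σ²ₘ WW' + σ²ₑ I)` is
maximized over the variance triple with average-information (AI) updates.
Numerical policy:

* start at `(0.3, 0.2, 0.5) × s²` with `s²` the OLS residual variance;
* an AI step that leaves the feasible region is retried as an active-set
  step (offending components pinned at the floor, reduced AI system
  re-solved), then with step-halving; if the likelihood still decreases,
  an expectation-maximization step (Johnson–Thompson form) with halving is
  used instead — EM steps cannot decrease the likelihood;
* variances are floored at `1e-8 × s²` (relative, so `h²` is exactly
  invariant to rescaling `y`); components at the floor are flagged
  `boundary`;
* convergence when the maximum parameter change relative to the total
  variance falls below 1e-8 or |Δ log L| < 1e-10, with `max_iter = 200`;
  non-convergence is flagged on the result, never silent.

The asymptotic covariance of the estimates is the inverse of the final AI
matrix.  `SE(h²)` follows by the delta method with gradient
`((σ²ₘ+σ²ₑ)/T², −σ²ₐ/T², −σ²ₐ/T²)`, `T` the total; the p-value is a
two-tailed Student *t* on `h²/SE` at `df = n − rank(X)`.  For a variance
ratio this test is an approximation (the null distribution of a
non-negative h-squared is a boundary mixture); it reproduces the
convention of pedigree-software pipelines and its type-I behaviour is
checked by permutation in the acceptance tests.  Note that a true-zero
variance component is estimated at the boundary in only roughly half to
two-thirds of replicates — the constrained-REML half-mass-at-zero
asymptotics — which is what the boundary test asserts.

## Synthetic populations (`synthio`)

The generator emulates the study design the analysis targets: ~128 ewes,
each with one litter of 1–4 lambs (default litter-size probabilities
0.65/0.30/0.04/0.01, mean 1.41 ≈ 179/128 lambs per ewe), a finite ram pool
(12 sires) so littermates are full sibs and some lambs across litters are
paternal half sibs, and one rumen sample per dam and per lamb (sires are
unsampled).  Defaults for ages (dams 1033 ± 425 d, lambs 60 ± 1.5 d) and
library sizes (negative binomial, mean 35,000, shape 13.5 → SD ≈ 9,500)
mirror typical published flock and amplicon-depth figures.

Latent per-ASV log abundances follow the animal model above exactly (the
additive vector is drawn jointly as `L u` with `L` the Cholesky factor of
`A`).  Latent values map to a composition by a per-sample softmax — this
guarantees valid proportions and is approximately inverted by the
log-relative-abundance transform — and counts are multinomial at the
sample's library size.  Traits: WW is linear in the centered latent values
of the designated causal ASVs plus a litter-size effect and Gaussian
noise; BW gets a tenth of the causal effect; PWG = WW − BW identically.
Fermentation parameters (NH₃-N and six VFAs) are weakly coupled to the
causal ASVs.

What the generator does **not** emulate: sequencing error and chimeras,
taxonomy-assignment noise, overdispersion beyond multinomial counting,
diet/pen covariance between littermates, and seasonal compositional
shifts.  Passing the planted-recovery tests therefore demonstrates the
statistical machinery is correct under the model's own assumptions, not
that real rumen data meet those assumptions.

### Planted-truth calibration

Because softmax + multinomial counting adds shared per-sample variation
(the log-sum-exp term) and count noise, h² estimated from log relative
abundance is mildly attenuated relative to the latent truth.  With the
default spread of baseline abundances (`base_log_mean_sd = 1.0` in the
benchmark configurations) the attenuation stays well inside the ±0.1
recovery band at planted h² ∈ {0, 0.2, 0.4, 0.6}, which the test suite
verifies over 30 replicate populations of ≥300 animals.

## Tables, networks, associations, prediction

* **Prevalence filter**: ASVs detected in ≥ the threshold fraction of all
  samples are kept — an ASV at exactly 5% is retained (only strictly rarer
  ASVs are removed).  Rarefaction subsamples without replacement
  (multivariate hypergeometric), one seeded draw per sample; samples below
  depth are dropped with a warning.  The log transform uses a configurable
  pseudocount, default 1e-6.
* **Diversity**: Chao1 is the bias-corrected form
  `S_obs + f₁(f₁−1)/(2(f₂+1))`; Shannon uses natural logs; evenness is
  Pielou's `H/ln S_obs`, undefined (NaN) for single-taxon samples.
  Weighted UniFrac is the normalized form (values in [0, 1]); PCoA drops
  axes with non-positive eigenvalues and reports proportions over the
  positive spectrum.  PERMANOVA uses Anderson's pseudo-F with seeded label
  permutations and the add-one p-value, so 999 permutations bound p below
  at 0.001.
* **SparCC**: fractions from counts + 1 (deterministic; Dirichlet
  resampling with a median over iterations is available), variation matrix
  `T_ij = var log(x_i/x_j)`, basis variances solved from the sparsity
  approximation `T_ij ≈ ω_i + ω_j`, with up to 10 rounds of excluding the
  strongest correlated pair from the basis system; correlations clipped to
  [−1, 1].  Pseudo-p-values permute each ASV's counts independently across
  samples (destroys correlation, preserves marginals), add-one two-sided.
  Networks are built per cohort; edges need |r| > 0.5 strictly and
  p < 0.01; nodes need prevalence > 20% strictly; hub/keystone ties are
  broken lexicographically and all ties reported.
* **MCODE**: node weight = density of the highest k-core of the closed
  neighborhood × that core's k; seeds expand breadth-first including
  neighbors within `node_score_cutoff` (0.2) of the seed weight; clusters
  without a 2-core are discarded; score = density × size; haircut/fluff
  off.
* **Associations**: candidate ASVs present in ≥50% of dams **or** of lambs
  (boundary inclusive).  A dam's abundances are paired with each of her
  lambs (duplication across littermates is deliberate and noted in the
  output).  Spearman uses midranks; p is exact (full enumeration) for
  n ≤ 9, t-approximate otherwise.  BH is applied jointly across the whole
  ASV × variable matrix, threshold 0.05.
* **Prediction**: within each litter-size stratum lambs are ranked on the
  trait; the top and bottom `floor(0.25 n)` become high/low, the middle is
  excluded.  Features are log relative abundances with `lamb:`/`dam:`
  prefixes; maternal rows repeat across littermates.  Tree count is chosen
  by a 7-fold CV learning curve over {100, …, 1000}, depth and feature
  fraction by grid search ({3, 5, 8, None} × {sqrt, log2, 0.3}); features
  with importance < 1e-3 are dropped and the model refitted.  Accuracy is
  the 7-fold stratified CV mean; AUC comes from one stratified 70/30 split
  using mean tree-vote probabilities.  Folds are stratified because class
  counts are small.  No nested cross-validation is attempted, so the
  reported CV accuracy is mildly optimistic after tuning — a known caveat.

## Problem sizes in the bundled benchmarks

The test suite and `scripts/acceptance.py` use populations of 48–128 ewes
(up to ~310 pedigree animals, ~300 samples), 40–230 ASVs, 100–200
permutation/bootstrap draws and 30 replicate populations where replication
is asserted — sizes chosen so the full validation completes on a single
CPU in minutes while keeping every Monte-Carlo tolerance meaningful.  The
random-forest benchmarks default to a reduced hyperparameter grid
(`small_rfc_config`); the full grid above is available via `RfcConfig`.

## Known limitations

* The maternal effect is i.i.d. per dam; no additive-maternal covariance,
  dominance, or permanent-environment terms.
* Marker-based (genomic) relationship matrices are out of scope; `A` is
  pedigree-only.
* The Student-t p-value for h² is approximate near the boundary (see
  above).
* SparCC assumes sparse true correlation; dense correlation structures
  bias the basis variances.
* PERMANOVA assumes exchangeability under the null; litter structure is
  not blocked in permutations.
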