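# Methods

This note documents the statistical model behind `dmusage`, the estimation
and testing procedures, the numerical choices, what the simulator does and
does not emulate, and the package's known limitations.

## Model

For one gene with `q` features observed in sample `i`, the count vector
`y_i` with total `m_i` is modelled as Dirichlet-multinomial (DM):
conditionally multinomial, `y_i | Π_i ~ Mult(m_i, Π_i)`, with random
proportions `Π_i ~ Dirichlet(γ₊ π)`.  Integrating out `Π_i` gives

    f(y; γ) = C(m; y) · Γ(γ₊)/Γ(m+γ₊) · ∏_j Γ(y_j + γ_j)/Γ(γ_j),
    γ = γ₊ π,  γ₊ = Σ_j γ_j.

Moments: `E[y] = m π` and `Cov[y] = c·m·(diag(π) − ππᵀ)` with inflation
factor `c = (m+γ₊)/(1+γ₊) ≥ 1`.  The equivalent dispersion parameterization
is `θ = 1/(1+γ₊) ∈ (0,1)`; at `θ = 0` the DM is exactly multinomial.

Assumptions worth making explicit:

* **`m` is ancillary.**  The per-sample total carries information about
  depth and overall expression, not about `π`, so samples with `m_i = 0`
  are dropped from a gene's likelihood and no library-size normalisation is
  performed anywhere.
* **One concentration per gene**, shared across condition groups.
* **Samples are independent** given the parameters; no covariates or
  pairing structure can be encoded (a regression extension is out of scope).

## Estimation

**Proportions at fixed concentration.**  Per group, `π` maximises the DM
log-likelihood over the open simplex.  The optimiser works on `q−1` free
coordinates via the additive log-ratio transform (last feature as
reference), which is unconstrained and smooth; the analytic score in `π` is
mapped through the chain rule.  The returned point is floored at 1e−10 per
coordinate and renormalised, the initial value is the group's pooled
observed proportions, and the fit never returns a point with lower
likelihood than its initialisation (it falls back to the start value and
flags non-convergence).  L-BFGS-B runs with `ftol = 1e−8`, at most 1000
iterations.

**Concentration by adjusted profile likelihood.**  The profile likelihood
`PL(γ₊)` maximises out the per-group proportions at each fixed `γ₊`.  Raw
profile likelihoods are biased when many nuisance parameters are profiled
out, so the Cox–Reid adjustment is applied:

    APL(γ₊) = PL(γ₊) − ½ log det I_obs(π̂),

where `I_obs` is the observed information (negative analytic Hessian) of the
log-likelihood with respect to the stacked free proportion coordinates,
`q−1` per group, block-diagonal across groups.  The Hessian has the closed
form `H = γ₊²(diag(S_1..S_{q−1}) + S_q 1 1ᵀ)` with
`S_j = Σ_i ψ′(y_ji+γ_j) − n ψ′(γ_j)`, verified in the tests against central
finite differences.  The information already scales with the data, so no
additional multiplication by `m` is applied; the alternative reading differs
only by a `γ₊`-independent constant when `m` is constant across genes and
samples, leaving grid argmaxes unchanged in the simulated designs.  If the
information matrix is not positive definite (degenerate data) the code falls
back to the raw profile likelihood with a warning.

**Grid search.**  `γ₊` is estimated on a grid of 21 points equally spaced in
`log10 γ₊` over `[0, 6]` (i.e. `γ₊ ∈ [1, 10⁶]`), not by continuous
optimisation.  Per-gene APL curves are cached, so every estimation flavour
is an argmax over (weighted sums of) cached curves:

* *common*: argmax of the mean curve across genes;
* *genewise-none*: per-gene argmax;
* *genewise-moderate-common*: argmax of `APL_g + W · mean(APL)`;
* *genewise-moderate-trend*: as above with the mean taken over the gene's
  expression neighborhood — genes ranked by mean per-sample total, windows
  of `max(⌈0.1·G⌉, 50)` consecutive ranks shifted (not shrunk) at the
  extremes; datasets below the minimum fall back to the common target.

Grid ties break toward the smaller `γ₊` (more dispersion), the conservative
direction.  Estimates at the first or last grid point are flagged
`at_boundary`.

**Moderation weight.**  `W` is denominated in "genes of data": the shared
curve has the same curvature scale as a single gene's likelihood, so `W = 1`
weights the prior like one extra gene.  The default is `W = 0.05`,
deliberately weak.  Validation on concentration-recovery simulations
(gene-wise truths spread over `log10 γ₊ ∈ [1, 3]`, `m = 1000`, 3 vs 3)
showed that strong weights (`W ≥ 0.25`) drag well-identified per-gene maxima
toward the common argmax and *increase* the median log-scale error, while
`W = 0.05` removes boundary blow-ups entirely (flat likelihood tails are
displaced by even a weak prior) and slightly improves the median error.
Larger weights remain appropriate, and configurable, when true dispersions
are believed nearly constant across genes.

## Testing

**DTU.**  Per gene, the full model fits one proportion vector per group and
the null model one pooled vector, both at the same fixed `γ₊` (by default
the moderated genewise estimate; a known scalar or per-gene mapping can be
supplied instead).  `D = 2(l_full − l_null)` is referred to χ² with
`(c−1)(q−1)` degrees of freedom.  Equality of proportions is the *null*
hypothesis.  Tiny negative `D` from finite optimisation is clipped to zero;
`D < −10⁻⁶` marks an optimiser failure and the p-value is reported missing
rather than wrong.  BH correction (via statsmodels) is applied across genes,
with missing p-values passed through.

**tuQTL.**  Per gene, SNPs within ±5 kb of the gene body (1-based inclusive
coordinates, window clipped at position 1) are retained if they show at
least two distinct observed dosages and the minor allele is carried (dosage
1 or 2) by at least five non-missing samples.  SNPs with identical genotype
vectors — including the missing-data pattern — form one block, tested once;
blocking is exactly lossless.  Dosage levels are treated as unordered
categories in the `c`-group LRT (`c` = observed levels, 2 or 3); samples
with missing dosage are excluded per block.  The gene's `γ₊` is estimated
once from the whole cohort (single pooled group) and reused for all blocks.

**Permutation adjustment.**  Nominal per-block p-values within a gene are
correlated and numerous, so gene-level significance uses a permutation
scheme standard in the sQTL literature: expression sample labels are
permuted (genotypes fixed; 100 permutations by default), the per-gene
minimum nominal p is recorded per permutation, and the adjusted p is
`(1 + #{perm minima ≤ observed min}) / (1 + B)`.  BH is then applied across
genes on the adjusted values; per-block empirical p-values against the
pooled permutation null are also reported.  Per-gene RNG substreams are
spawned from the master seed, and genes are processed with samples in a
canonical sorted order, so results are invariant to SNP and sample input
order and fully reproducible from the seed.

## Filtering

Two flavours, both computing per-sample proportions against the gene totals
of the raw matrix and recomputing totals after subsetting:

* cohort-scale (QTL) rules: a feature needs count ≥ 10 **and** proportion
  ≥ 5% jointly in ≥ 5 samples; a gene needs total ≥ 10 in ≥ 70 samples and
  ≥ 2 surviving features (all thresholds configurable — the 70-sample rule
  is a large-cohort default and should be lowered for small designs);
* the lighter differential-usage pre-filter: drop features whose proportion
  is below 5% in *every* sample.

Filtering is idempotent and genes reduced below two features are removed —
single-feature genes have no usage signal to test.

## Simulator

`simulate_null` / `simulate_dtu` draw, per gene and sample,
`Π ~ Dirichlet(γ₊ π₀)` then `y ~ Mult(m, Π)`.  Defaults: 1000 genes,
`m = 1000`, `q = 3`, two groups of 3, common `γ₊ = 100`; proportions uniform
(`1/q`) or geometrically decaying (`π_j ∝ 0.5^{j−1}` — the decay rate is a
package choice, exposed as a parameter).  Differential genes swap the two
most abundant features' proportions in group B; a tied top pair makes the
swap a no-op and the gene is relabelled null.  The gene-wise dispersion
architecture draws `log10 γ₊ ~ Uniform[1, 3]` per gene — a synthetic
stand-in for dispersion spreads estimated from real data.  Per-gene RNG
substreams are spawned from the master seed, so gene `g`'s draws do not
depend on how many genes are simulated.  `simulate_tuqtl` adds genes tiled
every 100 kb, SNPs uniform in each ±5 kb window with Hardy–Weinberg dosages,
and optional causal SNPs under which carriers switch proportions.

What the generator does **not** emulate: variable per-sample totals and
differential overall expression, dispersion–mean trends, realistic linkage
disequilibrium between SNPs, quantification uncertainty in the counts, and
transcriptome-scale proportion distributions.  Passing the calibration
tests therefore demonstrates correctness of the inferential machinery under
the model, not performance on any particular real dataset.

## Calibration behaviour, by design

Two deliberate properties show up in the tests:

* With many features and decaying proportions (`q = 10`), the χ² reference
  distribution is anti-conservative even when the *true* concentration is
  supplied: the null FP rate at p ≤ 0.05 sits near 0.06 rather than 0.05.
  This is a documented finite-sample property of the LRT in this regime,
  asserted (not excused) by the acceptance suite.
* The 21-point grid quantises concentration estimates (spacing 0.3 in
  log10); a truth of 100 snaps to 10^2.1 ≈ 126, making plug-in tests mildly
  liberal at very small n.  A finer grid reduces this at proportional cost.

## Problem sizes used by the test suite

Chosen as scaled-down versions of the reference designs: null calibration
uses 1000 genes × 10 repetitions (known `γ₊`); the many-feature
miscalibration check the same at `q = 10`; estimator-ordering comparisons
100 genes × 10 repetitions per design; the tuQTL global-null run 100 genes
× 100 permutations with 30 samples.  All seeds are fixed in the tests.

## Limitations

* No regression framework: covariates, pairing and population structure
  cannot be adjusted for; tuQTL analyses should be run within populations.
* Transcript count estimates are treated as fixed; quantification
  uncertainty is not propagated.
* The χ² asymptotics degrade for many features with skewed proportions (see
  above); permutation-based gene-level inference in the tuQTL path is the
  more robust alternative there.
* Dispersion estimation is grid-based; extreme true concentrations outside
  `[1, 10⁶]` are reported at the boundary and flagged.
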