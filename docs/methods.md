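# Methods

This note documents the statistical models implemented in `mirnet`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter.

## Count-based differential expression (`mirnet.rnaseq`)

**Model.** Counts for gene g in sample j are negative binomial with mean
μ_gj = s_j · q_gj and dispersion α_g (Var = μ + α μ²). The two-group
structure enters through a log-link GLM, q_gj = exp(b0_g + b1_g x_j)
with x_j ∈ {0, 1}; b1_g / ln 2 is the reported log2 fold change (case
group in the numerator).

**Size factors** are the classical median-of-ratios estimator: the
reference for each gene is its geometric mean across samples (restricted
to genes positive in every sample), each sample's factor is the median
of its count/reference ratios, and the factors are rescaled to geometric
mean 1. The median is taken on the linear-scale ratios (medians do not
commute with the log for even gene counts). If no gene is positive
everywhere, an explicit `pseudo_reference=True` switches to a reference
over each gene's positive entries.

**Dispersions.** A method-of-moments estimate per gene on size-factor
normalized counts q = y/s, pooled within groups:
α̂_g = max(0, (pooled within-group var(q) − mean(1/s)·mean(q)) / mean(q)²).
The mean(1/s) term makes the estimator unbiased under non-unit size
factors and reduces to the plain (s² − μ)/μ² form when all s_j = 1.
Gene estimates are shrunk halfway (weight configurable via
`shrink_weight`, default 0.5) toward a robust (Huber) regression trend
α(μ) = a₀ + a₁/μ fitted over genes with positive α̂. This is a
deliberately simple, fully specified estimator — not a reimplementation
of any particular package's empirical-Bayes dispersion machinery — and
it recovers planted dispersions well at moderate replication (median
α̂ within [0.15, 0.25] for a true 0.2 at n = 50/group; median < 0.02
under Poisson data).

**Wald test.** With α_g fixed at its estimate, the two-group log-link NB
model is separable by group, so each group's mean solves the scalar
score equation Σ_j (y_j − s_j m)/(1 + α s_j m) = 0 — a vectorized Newton
iteration over genes (closed form Σy/Σs at α = 0). The Wald statistic is
z = b1/SE with SE from the **observed** information at the MLE,
Var(b1) = 1/I₀ + 1/I₁, I_g = Σ_j μ_j(1 + α y_j)/(1 + α μ_j)². Observed
information is used because it is what a brute-force likelihood Hessian
produces; for this non-canonical link it differs slightly from the
expected (Fisher) information. Two-sided normal p-values, BH adjustment,
significance at adjusted p < 0.1. Genes with all-zero counts are removed
before testing (logged in the filter report) and genes with an all-zero
group get missing statistics, excluded from the BH denominator.

Exact invariance of z under rescaling one sample's column is not
attainable: scaling counts changes the likelihood information. The size
factor absorbs the scale exactly; z moves by O(10⁻³) per three-fold
scaling on small matrices.

## Two-color dye-swap arrays (`mirnet.arrays`)

**Background and M/A.** net = foreground − local background per channel;
M = log2(netR/netG), A = (log2 netR + log2 netG)/2. Spots with a
non-positive net intensity in either channel are missing — no
offset-based rescue, because plain subtraction is the documented
preprocessing of the upstream quantification.

**Within-array normalization.** Per print-tip group, a robust local
linear (lowess) fit of M on A — span 0.4, degree 1, 4 robustifying
iterations — is subtracted. These are conventional print-tip defaults,
exposed as parameters. Groups with fewer than 20 usable spots fall back
to the array-wide fit; all-missing groups are left unchanged with a
warning. A second application is a near no-op for trends within the
smoother's capacity; curved trends leave a small lack-of-fit that a
second pass would re-smooth.

**Between-array normalization** is quantile normalization of the
A-values only (the two-color "Aquantile" convention: M is the inference
target and is already centered within arrays). Each array's sorted
A-values are replaced by the cross-array mean of the order statistics,
interpolated onto a common quantile grid when arrays differ in usable
spot counts; ties receive the mean of the order statistics they span
(average ranks).

**Nonspecific filtering.** Probes without the required species
annotation are dropped first; then per-probe SDs across arrays are
compared against the shorth — the mean of the shortest interval
containing ⌈n/2⌉ of the SD values — keeping probes with SD strictly
greater. If that would remove every probe (degenerate SD distribution)
all are kept, with a warning. Filter stages are recorded in a
`FilterChain` whose counts telescope from input to final matrix.

**Dye-swap linear model.** Duplicate spots of a probe are averaged
within each array before fitting (an intra-duplicate correlation model
would be the refinement; averaging is the simple documented choice).
Per probe, M is regressed on the orientation design x_a ∈ {+1, −1} with
no intercept; the coefficient is the case−control log2 fold change, the
residual variance has df = (#arrays with data) − 1, and a constant dye
bias cancels exactly in a balanced design. Probes on fewer than two
arrays are excluded.

**Moderated t.** Residual variances are modelled as scaled-F draws
around a prior (d₀, s₀²); the hyperparameters come from moment matching
on log s² using the digamma/trigamma equations, with the trigamma
inversion done by Newton iteration. Shrunk variances
s̃² = (d₀s₀² + d s²)/(d₀ + d) give t̃ = coef/(s̃·u) on d₀ + d degrees of
freedom. d₀ = 0 reproduces the ordinary t exactly; d₀ = ∞ pools
completely (and is the fallback when the trigamma inversion fails or the
excess variance of log s² is non-positive). Single-channel matrices use
the same moderation after an IQR > 0.35 row filter and a two-group
least-squares fit.

## Enrichment (`mirnet.enrich`)

Category enrichment is the unconditional one-sided hypergeometric test
P(X ≥ k), computed by exact tail summation, run separately for up- and
down-regulated lists against an explicit, caller-supplied background
(the background definition is a scientific choice, so it is an input).
A term is significant at raw p < 0.05 only if it contains ≥ 2 DE genes
of that direction; no multiple-testing correction is applied to the
category p-values by default, matching the documented screening rule,
but a BH q-value mode (`adjust=True, q_cut=...`) is available for
pathway-style runs. No ontology-graph conditioning or semantic
clustering is performed; results are exported for external tools.

miRNA-family enrichment tests whether a family's log2 fold changes are
shifted against all other scored miRNAs: a Welch two-sample t with
one-sided p-values for each direction, reporting the smaller with its
direction. This is a documented interpretation of a gene-set shift test
on fold-change profiles; paired variants are out of scope. Families with
fewer than two scored members, or an empty complement, are skipped.

## Integration and network (`mirnet.integrate`)

**Platform combination** takes the union of per-platform significant
features, keeps both platforms' fold changes and adjusted p-values,
reports the mean of the available fold changes for display, and flags
direction conflicts rather than averaging them away.

**Correlation** is Pearson's r across matched samples; matrices are
column-matched by pool identifier through an explicit sample map, and
unmatched columns are dropped with a warning. Fewer than 3 matched
samples is an error unless explicitly allowed (`allow_low_n`), because
correlations over 2 points are ±1 by construction. Zero-variance
vectors yield missing r, which never passes the filter. RNA-seq
expression enters on the log2(normalized count + 1) scale; array
expression on the log2 net-intensity scale.

**Evidence filter.** A candidate pair is kept iff at least one clause
holds — target-prediction p < 0.1, or prediction by ≥ 2 of the four
programs (the primary-source prediction counts toward the two by
default; switchable), or a validated interaction — AND r ≤ −0.3. The
floor is boundary-inclusive and means "negative correlation of magnitude
at least 0.3"; a positive floor is rejected. An optional
enriched-gene-set membership filter restricts kept pairs to genes in
significantly enriched functional categories. Relaxing the floor toward
0 or raising the p cutoff can only grow the kept set.

**Network.** Kept pairs form a directed bipartite graph miRNA → mRNA
with node attributes (kind, mean log2 fold change, degree) and edge
attributes (r, number of predicting programs), exported as GraphML and
SIF for external visualization.

## Summary t-tests (`mirnet.compare`)

From (n, mean, SEM) per group: SD = SEM·√n, pooled variance
s²_p = ((n_a−1)SD_a² + (n_b−1)SD_b²)/(n_a+n_b−2),
t = |mean_a − mean_b| / (s_p √(1/n_a + 1/n_b)), df = n_a+n_b−2,
two-sided p. The statistic is reported as an absolute value (group order
does not matter). The pooled variant is the default because it
reproduces published motor-behavior t values from their printed
summaries; a Welch variant is provided. Two zero-variance groups with
equal means give t = 0, p = 1; with unequal means the test is undefined
and rejected.

## Synthetic studies (`mirnet.simulate`)

The generator emulates a two-group pre-symptomatic profiling design:
a small number of pooled biological replicates per group (default 3,
mirroring pools of several animals), measured by RNA-seq (counts),
single-channel arrays (log2 matrix) and dye-swap two-color arrays, with
the same pools shared across platforms so the matrices are
column-matchable.

- **Counts**: NB(mean = s_j · 2^(b_g + β_g x_j + e_gj), dispersion α)
  via gamma-Poisson mixing; baselines uniform on a log2 interval
  (default 3–10), size factors uniform 0.7–1.4 (geometric mean 1),
  exactly round(frac_de · n_genes) genes at β = ±log2fc (balanced
  signs). e_gj is a pool-level biological effect (default SD 0.25 log2
  units) shared conceptually with the array measurement of the same
  pool; setting it to 0 gives the textbook NB model used by the
  estimator-calibration tests.
- **Arrays**: one dye-swap pair (two arrays, opposite orientations) per
  pool. Channel log2 signal = latent(sample) ± dye_bias/2 ± trend(A)/2 +
  spot noise; the trend is a per-print-tip quadratic in A (amplitude
  default 0.3 log2); foreground = 2^signal + recorded local background
  (constant 50 with ±10% jitter), so net-intensity correction recovers
  the signal up to float rounding. Two duplicate spots per probe by
  default (the true per-probe duplication of the emulated platform is
  not documented; this is a parameter, not a fidelity claim). A fraction
  of probes (default 5%) lack the species annotation, exercising the
  annotation filter.
- **Coupling**: each true interaction's target gene has latent
  expression baseline − coupling_strength · (regulator's latent
  deviation), planting both the negative correlation and an
  opposite-sign fold change of magnitude coupling·log2fc. This is the
  simplest mechanism that makes the r ≤ −0.3 screen recoverable.
- **Annotations**: every true pair carries at least one qualifying
  evidence clause; each non-true DE×DE pair gets qualifying (decoy)
  evidence with probability decoy_annotation_rate (default 0.02 — a
  plausible rate for a random candidate pair to carry database
  evidence) and a non-qualifying noise row at the same rate.
- **Gene sets**: random GMT sets plus one set seeded with planted DE
  genes, so category enrichment has a recoverable signal.

All generators are deterministic given (config, seed); distinct
generator stages use distinct seed streams.

**What the generator does not emulate** — and hence what passing tests
do not demonstrate about real data: spatial array artifacts beyond
print-tip trends, probe sequence effects and cross-hybridization, count
overdispersion heterogeneity beyond a single α per study, GC/length
biases, batch effects, and any realistic structure of target-prediction
databases beyond a flat decoy rate.

## Known limitations and numerical notes

- The simple dye-swap model treats the two arrays of a swap pair as
  independent observations; with strong pool-level biological noise the
  pair shares its biological contrast, so miRNA DE p-values are
  anti-conservative (false-positive miRNAs carry no target evidence, so
  the network stage is largely insulated from this). A technical-
  replicate correlation model would be the refinement.
- Dispersion estimation is moment-based with fixed-weight trend
  shrinkage, not a full empirical-Bayes treatment; no independent
  filtering, outlier replacement or fold-change shrinkage is performed.
- The NB Newton solver starts at Σy/Σs and is guarded against negative
  steps; non-positive group means produce missing statistics.
- BH adjustment propagates missing p-values and excludes them from the
  number of tests.
- Quantile-normalization ties receive the mean of the spanned order
  statistics (average ranks); the shorth uses the first shortest window
  on ties.
- Problem sizes in the test suite and the acceptance script (2000
  genes, 300 probes, 3–10 samples/group, 10 replicate seeds) were
  chosen as the package's standard benchmark conditions; they match the
  emulated study's scale.
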