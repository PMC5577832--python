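# Methods

## Study design and model assumptions

The package targets the smallest viable two-group methylation design: a few
cases against matched controls, normalized Infinium beta values in [0, 1].
All tests run on the beta scale, not M-values, because every decision
threshold the pipeline applies (|Δβ| > 0.15 for large single-probe effects,
|Δβ| ≥ 0.3 for regional effects) is a beta-scale quantity; mixing scales
would make the cutoffs uninterpretable. Per-probe noise is treated as
approximately Gaussian within groups — defensible mid-range, optimistic near
the boundaries (see Limitations).

### Single-probe testing

A two-group one-way ANOVA per probe: F = MS_between/MS_within with df
(1, n₁+n₂−2). For two groups this is exactly the pooled-variance t test
(F = t²), and the suite asserts that identity at machine precision. p-values
are deliberately unadjusted: at n = 3 + 3 with ~10⁵–10⁶ probes, FDR control
would leave nothing, so the design instead relies on a strict α (0.001) and,
downstream, on effect-size filters. A Benjamini–Hochberg q-value column is
emitted for users but never drives any call. Threshold comparisons are
strict (p < 0.001, |Δβ| > 0.15) matching the stated decision rules;
degenerate probes with zero total variance return (F, p) = (0, 1).

"Genic regions" are counted as distinct gene symbols after splitting
multi-gene annotation strings; an alternative counting by unsplit annotation
string is exposed (`genic_count="strings"`) since either reading is
defensible.

### Region testing

Eligible probes are those in a CpG island, shore or shelf *and* associated
with at least one gene. Adjacency is defined within an island unit: probes
sharing the same manifest island name, ordered by position (probe id breaks
exact ties deterministically). Windows of three consecutive eligible probes
slide with step 1 and never span island units — one island per region, which
also keeps windows from bridging unrelated loci across large gaps. The
grouping rule is a documented choice; grouping by gene or by base-pair
distance would be alternatives, and the island-unit rule is the most
conservative of them.

Each window is tested with the two-group MANOVA. All four classical MANOVA
statistics (Wilks, Pillai, Hotelling–Lawley, Roy) coincide for two groups,
so the implementation uses Hotelling's T² with its exact F transform,
df (p, n₁+n₂−p−1); the test suite cross-checks F and p against an
independent MANOVA implementation (statsmodels, Wilks' Λ path) and against
an exact balanced-relabeling permutation distribution on 3v3 toys. A
singular pooled covariance (e.g. perfectly collinear probes) falls back to a
pseudoinverse at relative tolerance 1e-10 and flags the window. With 3v3
samples the error df is n₁+n₂−p−1 = 2, so the null tail is heavy — a fact
with major power consequences (below).

A window is significant iff p < 0.001 (strict) AND some run of ≥ 2
*mutually adjacent* probes all have |Δβ| ≥ 0.3 (inclusive — "a minimum
difference of 0.3"). Two exceeding probes merely co-present in the window do
not qualify; adjacency is what makes the criterion stronger than the window
itself. Overlapping or abutting significant windows within an island merge
into one DMR; the DMR p is the minimum member-window p (a single summary p
per region is needed and the minimum is the value that triggered the call),
its direction is HYPER/HYPO when all threshold-exceeding deltas agree in
sign, MIXED otherwise. The Δβ criterion is applied per window, not to the
merged extent. BED export converts 1-based manifest positions to 0-based
half-open intervals.

### Enrichment

One-sided Fisher exact p (hypergeometric upper tail) per term against a
background that defaults to the union of all library genes — the analysis
never states a universe otherwise, and this default is overridable. The
rank component asks how a term's p-rank for the observed list compares with
its rank distribution over random input sets of the same size: z =
(observed − μ_null)/σ_null, negative meaning better than expected. The null
is enumerated exhaustively whenever C(|background|, input size) ≤ 10⁵,
otherwise sampled with a seeded generator (n ≥ 100 draws), making the whole
ranking bit-reproducible for a fixed seed. The combined score is c =
ln(p)·z with the natural log — the base only rescales the ranking — and
results at p < 0.05 sort by |c| descending, ties by ascending p then term
id. Published combined scores from hosted enrichment services are not
comparable: they depend on proprietary precomputed null tables and library
versions, so only the identity c = ln(p)·z and the ranking contract are
asserted.

### Expression and concordance

Two-sided pooled t tests; fold change on the linear scale, FC =
2^(Δ mean) for log2 data. Scale auto-detection treats a non-negative matrix
with ≥ 99% of values ≤ 20 as log2. When one symbol maps to several array
rows, the row with the widest inter-quartile range is used (most informative
probe; mean-collapse is available). The concordance flag records the
canonical inverse methylation–expression relation (hyper→down, hypo→up);
discordant pairs — which genuinely occur, e.g. hypermethylated yet
up-regulated genes — are reported as-is with no causal claim.

### Replication

Order-preserving intersection with the second design's probe universe, then
per-probe ANOVA in the second dataset with tiered counts (strict p < 0.001,
loose p < 0.05) and sign concordance against the discovery deltas. A
case/control variance-ratio column surfaces the common failure mode of
cross-tissue or cross-immortalization comparisons (inflated within-group
variance in one dataset) without acting on it.

## Synthetic generator

What it emulates: island-clustered probe layout (shelf–shore–island–shore–
shelf relation pattern), bimodal beta baselines (Beta(2,10)/Beta(10,2)
mixture, 55% low mode), two groups of 3, Gaussian within-group noise on the
beta scale with clipping to [0, 1], spiked single-probe effects (|Δβ|
uniform in 0.15–0.45) and regional effects (|Δβ| = 0.35 over 3 adjacent
eligible probes), and a matched 10v10 log2 expression matrix whose spiked
genes can be tied (inversely) to the spiked methylation directions.
Spiked probes get baselines re-drawn so the shifted mean stays inside
[0, 1]; at most one single-probe spike lands per island so spikes cannot
accidentally assemble a region. Every injected effect is registered in the
truth object. Noise is Gaussian-with-clipping rather than logit-normal
because the pipeline's thresholds live on the beta scale.

**Within-group noise default (sd = 0.008).** The default was chosen from
the power analysis, once, as the noise level at which the 3v3 regional
design actually works: with window size 3 and 3v3 groups the F transform
has only 2 error df, and the exact noncentral-F power of the window test at
α = 0.001 for Δβ = 0.35 is 0.19 at sd = 0.03, 0.37 at sd = 0.02, 0.84 at
sd = 0.01 — i.e. the regional design is only well-powered at
technical-replicate-scale noise (≲ 1% sd on betas, which Infinium arrays
achieve for well-behaved probes). At sd = 0.008 the island-level
sensitivity is ≈ 0.97, and the published use of this window test on real
3v3 data — which did find regions at p < 0.001 — is itself only consistent
with within-group noise of this order. Larger noise levels remain available
as a parameter.

What the generator does **not** emulate: type I/II probe chemistry and its
variance differences, batch/position effects, cell-composition variation in
whole blood, age drift, spatial correlation of noise along islands, and
heavy-tailed outlier samples. Passing recovery tests therefore demonstrate
the algorithmic machinery (calibration, adjacency logic, merging, ranking),
not robustness to those real-data pathologies.

## Numerical and design choices

- Strict inequalities at p thresholds, inclusive at the Δβ ≥ 0.3 regional
  criterion; |Δβ| > 0.15 strict for the large-effect summary.
- Probes with any missing beta are excluded from testing (counted in the
  log): with 3 samples per group there is no room for imputation.
- Probes at identical positions order by probe id; term-rank ties order by
  term id; both make every output deterministic.
- PCA centres per probe and reports plain fractions of total variance;
  components are only defined up to sign.
- `probe_anova` on zero within-group variance with distinct means returns
  (inf, 0) rather than an error — the data are genuinely maximally
  discriminative at this df.
- Every randomized operation takes an explicit seed; there is no module
  state.

## Problem sizes

The test suite and `scripts/acceptance.py` use 10⁵ null probes and 10⁴
disjoint null windows for calibration (99% binomial CIs around α = 0.001),
200 spiked regions / 200 spiked probes for sensitivity and power, and the
default 350-probe scene for end-to-end runs — sizes at which the binomial
error of the measured rates is small relative to the margins being asserted,
while the whole suite runs in well under a minute.

## Known limitations

- With 2 error df, the window test's parametric p is exact under normality
  but fragile to heavy tails; clipping-induced non-normality near beta 0/1
  slightly perturbs extreme-tail calibration (measured: within the 99% CI
  at α = 0.001 under the default generator).
- No covariate adjustment, batch correction or cell-composition
  deconvolution; the pipeline assumes those were handled upstream or are
  absorbed by matching.
- The enrichment z is estimated from a finite null (exact only in the
  enumerable regime), so z values across different background sizes are not
  comparable.
- Replication across tissues (e.g. whole blood vs immortalized lines) is
  reported mechanically; the variance-ratio column is diagnostic, not a
  correction.
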