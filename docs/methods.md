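# Methods

This note documents the models, algorithms, numerical choices and
assumptions behind `barseqtools`, and what the bundled simulator does and
does not emulate.

## Data model

A Bar-seq experiment measures the relative abundance of thousands of
barcoded mutants competing in a pool. Each mutant carries two independent
20-bp barcodes (UPTAG and DNTAG) that are two semi-redundant measurements
of one genotype; each sequencing library is identified by a 5-bp sample
index. A *biological replicate* is an independently grown culture; a
*technical replicate* is an independent library preparation of the same
DNA. Counts therefore carry three nested noise layers: treatment effects,
culture-to-culture (biological) variation, and counting/library
(technical) variation.

## Demultiplexing

Reads have a fixed layout (index 0–4, constant priming region 5–19,
barcode 20–39), a consequence of the two-step PCR protocol; the layout is a
configuration object, not a search. Sample indices are matched at
Levenshtein distance ≤ 1, barcodes at ≤ 2, and the constant region decides
UPTAG vs DNTAG at ≤ 2. Matching is **nearest-unique**: the unique
minimum-distance reference wins even if other references sit within the
cutoff; a tie at the minimum distance discards the read as ambiguous; the
outcome is independent of read order and of catalog order. Reads shorter
than the barcode end are counted separately. Candidate generation uses an
exact-seed pigeonhole filter (split the query into d+1 pieces; one piece of
anything within d edits survives verbatim, displaced ≤ d), with edlib
verifying true distances, so the filter can change speed but never
semantics. Distances are cheap to audit: the mapping statistics record how
many reads mapped at distance 0, 1 and 2, which is monotone by
construction.

## Count processing

Rows (mutant, tag) with a total below 100 reads across all samples are
removed — "fewer than 100" is strict, a row totalling exactly 100 stays.
Control strains spiked into every plate (e.g. the HO deletion) are removed
by id. UPTAG + DNTAG and technical replicates are **summed** (not
averaged): sums keep counts on their natural sampling scale, and are robust
to the loss of one barcode, which is common — the per-mutant UPTAG/DNTAG
ratio report quantifies this, using a pseudocount of 1 only when a tag
total is zero and only for reporting. Whether the low-count filter runs
before or after control removal is configurable (default: filter first);
on realistic data the two orders differ only when a control sits below the
count threshold. Time-zero samples travel through the count stages and are
excluded from testing by a metadata filter.

## Differential abundance

Counts are modelled as negative binomial, Var = μ + φμ² (φ = 0 is
Poisson). The stack is:

1. **TMM normalization.** Per-column scaling factors from the doubly
   trimmed (30% of M-values and 5% of A-values in each tail), inverse-
   variance-weighted mean of log2 count ratios against a reference column
   (the one with the most typical upper quartile); factors are rescaled to
   geometric mean 1 and multiply the raw library sizes into effective
   sizes.
2. **Library-size equalization.** Every count is quantile-matched from
   NB(λN_j, φ) to NB(λN*, φ), N* the geometric mean of effective sizes and
   λ the mutant's within-group relative abundance. The mapping interpolates
   the normal and gamma approximations of the NB; it is continuous,
   monotone, fast, and exactly the identity when N_j = N*, so equal-library
   analyses operate on the raw counts. Pseudo-counts and dispersion depend
   on each other; two alternating rounds (starting at φ = 0.01) suffice.
3. **Dispersion.** The common φ maximizes the conditional log-likelihood
   given per-mutant group totals (for a group of n replicates with total z:
   Σ_j lnΓ(y_j + 1/φ) − n lnΓ(1/φ) + lnΓ(n/φ) − lnΓ(z + n/φ)), summed over
   mutants, optimized in log φ over [1e-8, 10] to relative tolerance 1e-6.
   Requires at least one group with two replicates; without biological
   replication the within-treatment variance is not estimable and fitting
   refuses. Per-mutant (tagwise) dispersions maximize the mutant's own
   conditional likelihood plus prior_n × the average likelihood across
   mutants, prior_n = prior_df / residual df with prior_df = 10; the
   maximizer is found on an 81-point log grid with quadratic interpolation.
   prior_df → ∞ collapses to the common value; prior_df = 0 is the
   unshrunken per-mutant estimate.
4. **Exact test.** Group sums of equalized counts (rounded to integers for
   enumeration) are compared conditionally on their total t: under the null
   of equal relative abundance the first group's sum is beta-binomial
   (t, n1/φ, n2/φ), binomial in the Poisson limit (φ < 1e-7). The
   two-sided p sums the probabilities of all outcomes with probability ≤
   the observed outcome's ("doubletail"), ties included with multiplicative
   slack 1e-12. log2FC is the log-ratio of per-replicate group means with a
   prior count of 0.125 added to each to avoid infinities. Scaling a truly
   different mutant's counts up (equal libraries) strictly decreases its
   p-value — the property that separates count models from location tests.
5. **q-values.** π₀ is estimated from π₀(λ) = #{p>λ}/(m(1−λ)) on
   λ = 0.05…0.95, smoothed by a cubic least-squares fit evaluated at
   λ = 0.95 and clipped to (0, 1]; q_i = min over thresholds t ≥ p_i of
   π₀·m·t/#{p ≤ t}. Forcing π₀ = 1 reproduces Benjamini–Hochberg exactly.

The `NBExactModel.fit()` → `NBExactResults` pair carries the estimates,
dispersions, per-mutant table (logFC, logCPM, p, q) and a `summary()`.
Exact numerical agreement with any external package is not a goal;
agreement with brute-force enumeration of the conditional distribution is,
and is tested to 1e-10 on all instances with totals ≤ 200.

## Variance partitioning (eigen-R²)

Counts + 1 are scaled by TMM effective sizes, log-transformed, and the
bottom 10% of mutants by total count dropped (low counts otherwise inflate
the technical share; the decomposition is insensitive to the exact
percentile, which is a tested property). The row-centered matrix is
decomposed by SVD; each right singular vector is regressed on the factor's
centered indicator span and the R² values are averaged with eigenvalue
weights, retaining every component above an eigenvalue share of 1e-12.
Retaining all components makes eigen-R² identical to the row-SS-weighted
average of per-row ANOVA R² values, which is the oracle used in tests. The
biological factor is encoded replicate-within-treatment, so its span
contains the treatment span and R²_B ≥ R²_T always; reported components
are treatment = R²_T, biological = R²_B − R²_T, technical = 1 − R²_B,
which are non-negative and sum to one by construction. (The alternative
reading "technical = 1 − R²_B − R²_T" is arithmetically inconsistent with
components that sum to 100%; this package uses the additive convention.)
Fixed-effect R² of a random factor absorbs about (levels−1)/(columns−1) of
pure noise; recovery tests budget for that bias explicitly.

## Gene-set enrichment

Each set's log-fold changes are compared with all others' by a two-sided
Wilcoxon rank-sum test — exact enumeration when the in-set size is ≤ 10,
otherwise the normal approximation with tie and continuity corrections.
Sets are first intersected with the detected universe; fewer than 4
detected members drops the set (exactly 4 is kept). Overlapping sets are
tested independently; the only multiplicity treatment is the q-value step
at 5% FDR, and sidedness is a flag.

## Design evaluation by subsampling

The full 2×4×2 experiment defines the **gold standard**: its test results,
its significant set at q ≤ 0.05, and fold-change strata (all / ≥1.5-fold /
≥2-fold, nested). Reduced designs keep a subset of replicate columns; every
combination is enumerated — C(4,b) biological choices shared across both
treatments × a globally shared technical-replicate choice (2 options when
k=1), giving 1, 2, 4, 8, 6, 12 combinations for 2×4×2 … 2×2×1. Depth is
reduced by binomial thinning S_ij ~ Binom(X_ij, p), which is
distributionally identical to sampling a fraction p of reads before
mapping; thinning composes (p then q equals pq), also a tested property.
Fractions default to the 400-point grid 0.25%, …, 100% and are applied to
the collapsed mutant × replicate matrix (a read-level mode exists through
the simulator for end-to-end checks). Each subsample is pushed through the
identical pipeline and scored on: number significant, power (fraction of
the gold significant set recovered), MSE of logFC against gold, number of
significant gene sets, and empirical FDR (called mutants absent from gold;
reported as missing when nothing is called). Per-design curves pool all
combinations and are smoothed with least-squares natural cubic splines —
df 20, and 15 for the noisier gene-set counts, the convention being about
one basis function per 7 grid points at the 400-point grid. Every
(design, combination, fraction) point draws from its own named RNG stream,
so any point is reproducible in isolation.

Two measurement caveats are built into the shape analyses. First, the
fraction-1.0 point of the full design compares the gold standard with
itself (power ≡ 1, FDR ≡ 0); it is excluded from saturation measurements
as circular. Second, when the grid is scaled down (e.g. 40 points), the
smoothing df is scaled with it to keep the same basis-per-point density;
df 20 on 40 points would chase per-point noise.

## The simulator

`SimParams` defaults are the study conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| `n_mutants` | 4295 | deletion-collection scale |
| `baseline_sdlog` | 0.8 | log-normal abundances; totals centred at 1e4 then span ~1e3–1e5 at the 1st–99th percentiles (σ must be ≤ ~0.99 for that span to fit) |
| `dispersion` | 0.1 | biological NB dispersion; no published value exists for this layer, so it is an explicit assumption, exposed and used consistently by the calibration tests |
| `frac_affected` | 0.1 | fraction of mutants with a true effect in calibration studies |
| `effect_sdlog2` / `effect_magnitude` | 1.0 / off | Normal(0,1) log2 effects, or fixed ±1 when a single effect size is wanted |
| `tag_dropout_prob` | 0.13 | per-tag loss (suppression ×10⁻²–10⁻³, not hard zero); with two tags per mutant ≈ 24% of mutants end ≥100-fold divergent |

Counts are generated as: per-culture relative abundances = baseline ×
2^(log2FC · treatment) normalized to 1; one gamma(1/φ, φ) draw per
(mutant, culture) shared by both tags and all technical replicates;
Poisson sampling per library at the requested depth. Biological replicates
are therefore exactly NB(φ) while technical replicates of one culture are
Poisson resamplings — reproducing the variance ordering technical <
biological that motivates summing technical replicates. Reads are emitted
as index + constant + barcode with i.i.d. substitutions; simulated
barcodes are rejection-sampled to pairwise Levenshtein distance ≥ 5, so
error injection cannot create ambiguity at the distance-2 cutoff (the
ambiguity code path is exercised by dedicated fixtures instead, since real
catalogs do violate this).

**What the simulator does not emulate:** PCR amplification bias and
cycle-level jitter, indel sequencing errors, quality-score structure,
composition bias between libraries (TMM factors are exercised on counts,
not caused by a biological mechanism), index hopping, and strain-specific
growth interactions. Passing tests therefore demonstrate correctness and
calibration of the statistics under the stated noise model, not robustness
to every artefact of real sequencing.

## Problem sizes used in the checks

The bundled statistical checks run at desk scale, as the package's own
choice of study size: calibration uses 2000 mutants × (4 vs 4) at ~349
reads/mutant/library (the recommended knee depth) over 20 seeds; the
design-evaluation study uses 2000 mutants at 875 reads/mutant/library —
ten times the knee, mirroring a deliberately oversampled full experiment —
a 40-point fraction grid and two replicate combinations per design. At
those conditions the measured type-I error at p ≤ 0.05 is ~0.05, mean FDP
at q ≤ 0.05 is ≤ 0.1, dispersion is recovered within a few percent, power
at matched per-condition depth orders 4 > 3 > 2 biological replicates, the
technical-replicate gain is near zero (technical replicates are pure
Poisson resampling here, so at matched total depth they add no
information), and smoothed power curves gain < 0.02 across the top decile
of depths.

## Known limitations

* The exact test enumerates the full conditional distribution; cost grows
  linearly with per-mutant totals (chunked to bound memory). Very deep
  experiments pay proportionally.
* Only two-group comparisons; no GLM/multi-factor testing.
* The q-value π₀ smoother is a cubic polynomial fit, adequate on thousands
  of p-values but noisy on very small families (it is clipped to (0, 1]).
* Demultiplexing assumes fixed read layout; no indel-tolerant layout
  search, no quality-aware matching.
* Variance partitioning is a fixed-effect decomposition, not a mixed
  model, and inherits fixed-effect noise absorption on small column counts.
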