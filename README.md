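# barseqtools

A toolkit for designing and analysing **Bar-seq** experiments — pooled
fitness screens in which thousands of barcoded mutants (such as the
*Saccharomyces cerevisiae* deletion collection) compete in a culture and
each mutant's abundance is read out by sequencing its molecular barcodes.
It is aimed at researchers running pooled screens who need to (i) turn raw
reads into per-mutant counts, (ii) test for differential abundance between
conditions with statistics appropriate for overdispersed count data, and
(iii) decide **how many replicates and how many reads** a future screen
actually needs.

## What it does

* **Demultiplexing** — reads are laid out as a 5-bp sample index, a 15-bp
  tag-specific constant priming region, and a 20-bp molecular barcode
  (UPTAG or DNTAG). Indices are matched at Levenshtein distance ≤ 1 and
  barcodes at distance ≤ 2; a read matching two references equally well is
  discarded as ambiguous.
* **Count processing** — rows with fewer than 100 reads across all samples
  are removed (they are mostly sequencing error), spiked-in control strains
  (e.g. the HO deletion) are dropped, and UPTAG + DNTAG counts and technical
  replicates are *summed* into a mutant × biological-replicate matrix.
* **Differential abundance** — library sizes are normalized by TMM (trimmed
  mean of M-values); counts follow a negative binomial, Var = μ + φμ², with
  the dispersion φ estimated by conditional maximum likelihood and shrunk
  per mutant toward the common value (empirical Bayes, prior df = 10). Each
  mutant is tested with an exact conditional test: given the mutant's total,
  the split between the two groups is beta-binomial under the null, and the
  two-sided p-value sums all outcomes no more likely than the one observed.
  Storey q-values provide FDR control. This is the right tool where a
  *t*-test is not: counts (8, 9) vs (13, 14) and (8000, 9000) vs
  (13000, 14000) give identical *t*-test p-values, but very different exact
  NB p-values, because the deeper counts genuinely carry more information.
* **Variance partitioning** — eigen-R²: SVD of the row-centered
  log-normalized matrix, each right singular vector regressed on a design
  factor, eigenvalue-weighted average of the R² values. Components reported
  as treatment = R²_T, biological = R²_B − R²_T, technical = 1 − R²_B.
* **Gene-set enrichment** — two-sided Wilcoxon rank-sum comparison of each
  set's log-fold changes against the rest, sets with fewer than 4 detected
  members discarded, 5% FDR by q-value.
* **Design evaluation** — the core contribution: a full 2 × 4 × 2
  experiment (treatments × biological × technical replicates) is the gold
  standard; reduced designs are emulated by dropping replicate columns
  (every combination enumerated: 1, 2, 4, 8, 6, 12 for the six standard
  designs) and reduced depth by binomial thinning S ~ Binom(X, p) over a
  grid of 400 fractions (0.25%, …, 100%). Each subsample is re-analysed
  end to end and scored on power, logFC accuracy (MSE), number of
  significant gene sets, and empirical FDR against the gold standard;
  curves are smoothed with natural cubic splines (df 20, or 15 for the
  noisier gene-set counts).
* **Simulator** — synthetic experiments with log-normal baselines,
  gamma-mixed Poisson (i.e. NB) biological replicates, Poisson technical
  resampling, per-tag dropout, and optional raw-read generation with
  per-base substitution errors, so the whole pipeline is testable
  end to end without any external data.

## Worked example

```python
import barseqtools as bt

params = bt.SimParams(n_mutants=2000, dispersion=0.1, frac_affected=0.1,
                      effect_magnitude=1.0, seed=42)
catalog, sheet, truth, matrix = bt.simulate_experiment(
    params, bt.DesignSpec(2, 4, 2), depth_per_sample=300_000)

collapsed = bt.collapse_tags_and_technical(matrix)
result = bt.NBExactModel(collapsed, groups="treatment").fit()
print(result.summary())
```

prints

```
Negative-binomial exact test (doubletail)
  mutants tested:        2000
  groups:                YPGal vs YPD (4 vs 4 replicates)
  common dispersion:     0.1005
  tagwise dispersion:    median 0.09761 (prior df 10)
  significant (q<=0.05): 91
```

The common dispersion recovers the simulated φ = 0.1; at this depth about
half of the 200 truly affected mutants (|log2FC| = 1 on a 2000-mutant pool
at ~150 reads/mutant/library) clear the 5% FDR threshold. A design
evaluation on the same matrix ranks designs by power at matched
per-condition depth:

```python
ev = bt.run_design_evaluation(matrix, ["2x4x2", "2x3x2", "2x2x2"],
                              grid=bt.make_fraction_grid(0.1), seed=7,
                              max_combinations=2)
print(ev.points.groupby("design")["power"].mean().round(2))
```

```
design
2x2x2    0.08
2x3x2    0.43
2x4x2    0.83
Name: power, dtype: float64
```

— four biological replicates dominate three, which dominate two, the
pattern that makes biological replication the first thing to budget for;
sequencing depth saturates near ~1400 reads per mutant per condition
(6 million reads per condition for the 4295-mutant deletion collection,
i.e. 30 conditions on a 200-million-read lane with 120 indexed adaptors).

A `barseq` command-line interface exposes each stage
(`simulate`, `demux`, `counts`, `test`, `variance`, `enrich`,
`design-eval`, `pipeline`); see `barseq --help`.

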