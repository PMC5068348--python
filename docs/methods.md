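# Methods

## The null-deviation model

For a group of samples (e.g. all samples from one chronosequence year and
one community fraction), observed β-diversity is the mean pairwise
Sørensen–Czekanowski binary dissimilarity

    d(x, y) = 1 − 2a / (2a + b + c),

with `a` the shared presences and `b`, `c` the presences unique to each
sample. The null model re-assembles each sample independently from the
regional species pool — the set of species observed anywhere in the input
matrix — under two hard constraints: the sample keeps exactly its observed
richness (α fixed) and draws only pool members (γ fixed). Species are
drawn without replacement with probability proportional to their regional
occurrence frequency (fraction of samples occupied); an equiprobable
variant is available. β_null is the mean group β over `n_randomizations`
such assemblages (default 10,000), and the null deviation is

    ND = (β_obs − β_null) / β_null.

Because randomization preserves α and γ exactly, ND isolates co-occurrence
structure: ND ≈ 0 means species identities within samples look like random
draws from the pool (stochastic assembly); β_obs below/above the null
expectation (|ND| toward 1) means samples are more similar/dissimilar than
chance allows (deterministic assembly). ND for the Sørensen metric is
bounded in (−1, (1−β_null)/β_null]; in practice environmental filtering at
a shared environment drives ND negative.

Replicate simulations: `replicate_null_deviation` repeats the whole
computation `n_replicates` times (default 5) with seeds `base_seed + r`,
giving per-group ND distributions whose fraction-vs-fraction differences
are tested by label permutation.

### Sampling without replacement

Weighted sampling without replacement is implemented with exponential sort
keys: each species gets key `E_i / w_i` with `E_i ~ Exp(1)`, and the k
smallest keys are the sample. This is distribution-identical to drawing
species one at a time with weight renormalization after each draw
(Efraimidis–Spirakis), and it vectorizes across all randomizations; the
test suite checks the realized pair probabilities against the closed-form
sequential-draw expression. β over a batch of randomized assemblages is
computed from the shared-species counts `P P^T`, using
`d_ij = 1 − 2 a_ij / (k_i + k_j)` with fixed richness `k`.

### Degenerate cases

If every sample's richness equals the pool size, every randomized
assemblage is the full pool and β_null = 0; this raises
`DegenerateNullError` rather than returning ±inf. Empty samples are
rejected by all dissimilarity operations (treating two empty samples as
identical would silently bias β_null); callers drop them explicitly, and
the pipeline does so after binning.

## Permutation inference

All tests use the add-one Monte-Carlo convention
`p = (1 + #extreme) / (1 + n_permutations)`, so p ≥ 1/(n+1) and p = 0 is
impossible. Whenever the number of distinct relabelings is at most the
requested permutation count, the test switches to exhaustive enumeration
and reports the exact fraction of relabelings (identity included) at least
as extreme as the observed statistic.

- **Two-group ND test** — statistic mean(a) − mean(b), two-sided on the
  absolute difference (the hypothesis is equality of mean ND between
  fractions). Degenerate all-equal input returns p = 1 with a warning.
- **PERMANOVA** — `SS_total = (1/N) Σ_{i<j} d_ij²`,
  `SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d_ij²`, `SS_among` by difference;
  pseudo-F = (SS_among/df_among)/(SS_within/df_within); labels permuted,
  one-sided upper. Because F is strictly decreasing in SS_within at fixed
  SS_total, permutations are ranked on SS_within directly. On Euclidean
  distances of univariate data the statistic reduces exactly to the
  classical one-way ANOVA F (verified in tests). Pairwise PERMANOVA runs
  the one-way test on each pair's submatrix; p-values are reported raw by
  default with optional Holm adjustment.
- **Mantel / partial Mantel** — Pearson r of the strict lower triangles;
  the second matrix's rows and columns are permuted jointly (one-sided
  upper, since positive association is the hypothesis). The partial test
  residualizes both triangles on the control matrix by simple linear
  regression and permutes the re-symmetrized residual matrix of dy (method
  of residuals; variants exist, this one is stated explicitly). If the
  control matrix explains dy exactly, the partial r is reported as 0 with
  p = 1 — the formal correlation is undefined but nothing remains to
  explain.

A note on discreteness: an exhaustive permutation p takes values k/K over
the K distinct relabelings, so the achievable significance levels are a
finite grid. With two equal-size groups the label-swap symmetry halves K
(every partition appears twice), which can push the smallest achievable
level past a nominal α; calibration experiments therefore use unequal
group sizes.

## Data transformations

- `bin_temporal_replicates` sums counts across sampling events within a
  unit (grand sample per focal unit); non-event metadata must agree within
  the unit, and the grand total count is conserved.
- `log_relativize` applies log10(x+1) then divides each species column by
  its maximum transformed value, so every non-empty column peaks at 1.
  Log-then-relativize order and the per-column (rather than global)
  maximum follow the usual general-relativization convention for
  abundance data before Bray–Curtis PERMANOVA; base and a global-maximum
  variant are exposed as options.
- Environmental Euclidean distances z-standardize each variable first
  (units are heterogeneous: %, mg kg⁻¹, counts); constant variables are
  dropped; a raw-scale option exists.
- Shannon H′ uses natural log (nats) by default, configurable.
- Species accumulation uses the randomized-sample-order estimator
  (default 1,000 orderings) rather than the analytic Mao Tau form; the
  mean curve is monotone and ends at total observed richness.

## The synthetic chronosequence generator

The generator exists so every pipeline stage can be validated against a
known truth without field data. A regional pool of γ species receives
lognormal relative abundances (shape σ = 1 by default — a typical
dominance structure for arthropod assemblages) and niche optima uniform on
a [0, 1] environment axis. Each sample draws a Poisson richness (mean
`richness_mean`, truncated to [1, γ]) and selects members without
replacement with weight

    w_i ∝ abundance_i · exp(−F (opt_i − env)² / (2 b²)),

where `F` is `filtering_strength` and `b` is `niche_breadth` (default 0.3
on the unit axis, wide enough that moderate F leaves realistic richness
attainable, narrow enough that strong F forces convergence on the locally
matched species set). `F = 0` reduces exactly to neutral assembly — the
random stream is identical, so the neutral and filtered functions agree
bit-for-bit at the same seed. Abundances of selected species are
1 + Poisson around the pool's relative-abundance profile (~150 individuals
per sample).

The default scenario mirrors a five-year tree-mortality chronosequence
design: two fractions with pools of 23 and 20 species sharing 4; 8
aboveground samples per year (7 in the final year) with mean richness ~11;
6 belowground samples per year with mean richness ~5; a monotone
environment gradient across years plus two gradient-correlated covariates
and two pure-noise covariates in the environment table. Filtering is
applied to the aboveground fraction by default (strength 4) and the
belowground fraction is neutral.

What the generator does *not* emulate: spatial dispersal kernels, temporal
autocorrelation beyond the year-level gradient, detection error, or
abundance-dependent sampling effort. Passing the recovery experiments
therefore shows that the pipeline detects filtering when α, γ and the
abundance distribution are well behaved — not that it is robust to every
failure mode of real survey data.

## Problem sizes and numerical choices

The validation experiments run at sizes chosen to keep the whole suite
fast while leaving Monte-Carlo error far below the effects being measured:
null-centering uses 200 simulated datasets at 500 randomizations each
(mean ND within 3 standard errors of 0); parameter recovery uses 50
scenario replicates at 200 randomizations (filtered |ND| ≈ 0.52 vs.
neutral ≈ 0.12, so reduced randomization noise of ~0.02 is immaterial);
calibration uses 1,000 null datasets at 99 permutations. Enumeration
oracles (216 assemblage triples; all label arrangements for instances of
≤ 10 samples; all 24 relabelings of 4×4 Mantel matrices) anchor the
Monte-Carlo paths exactly. Floating-point ties in permutation counting are
broken with a relative tolerance of 1e−12 toward counting the tie as
extreme (conservative). All randomness flows through
`numpy.random.default_rng` seeds recorded in results and manifests;
replicate r of a null-deviation run uses seed `base + r`.

## Known limitations

- The null model is binary (Sørensen); abundance-weighted null models
  (individual-based Raup–Crick variants) are out of scope.
- ND of a neutral community is centered near 0 only when the analysis
  weights match the generating process; occurrence-frequency weighting on
  abundance-assembled neutral data leaves a small residual |ND| (~0.1 at
  the default scenario's sample sizes), which is why inference rests on
  the fraction contrast and permutation tests rather than on |ND| alone.
- Mantel tests permute the second matrix only; with strongly structured
  control matrices the method-of-residuals partial test is approximate,
  as all partial Mantel variants are.
- PERMANOVA is one-factor; dispersion effects (PERMDISP) are not
  separated from location effects.
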