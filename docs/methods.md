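# Methods

This document defines the models and procedures implemented in
`growthcub`, the parameter defaults and their rationale, the semantics of
the synthetic data generator, and known limitations.

## 1. Codon usage bias scores (`seq_cub`)

A CUB score for a coding sequence with scored codons \(c_1 \dots c_L\) and
weight table \(w : \text{codon} \to (0, 1]\) is the geometric mean
\(\big(\prod_i w_{c_i}\big)^{1/L}\), computed as
\(\exp\!\big(\tfrac{1}{L}\sum_i \ln w_{c_i}\big)\) to avoid underflow on
long genes. The same formula serves CAI and tAI; only the weight table
differs, so both are handled by `CodonWeightTable` (weights are validated
to lie in \((0, 1]\); missing sense codons produce a warning at load and a
`MissingWeightError` if actually encountered).

Conventions:

- the terminal stop codon is dropped by default (`drop_stop=True`);
  optionally the initiator codon can be dropped too;
- codons containing `N` (or any non-ACGT character) are counted under an
  `ambiguous` key and excluded from the score;
- a sequence with zero scorable codons raises `UndefinedScoreError` —
  never a silent 0 or NaN.

CDS input is read with Biopython (`fasta` or `genbank`; for GenBank only
CDS features are extracted, strand-aware). `filter_cds` removes records
whose length is not a multiple of 3, whose length disagrees with a
declared length, or which exceed a maximum; the median length is reported
before removal so filtering is auditable.

`CodonWeightTable.example()` provides a deterministic synthetic table:
within each synonymous family the codons are ranked alphabetically and
weighted \(1, 0.5, 0.25, \dots\) (decay 0.5). It is a stand-in for
organism-derived weights, used by the generator and the examples.

## 2. Expression preprocessing (`expr_prep`)

Raw abundances \(a_{gc}\) are normalized per condition to
\(6 + \ln(a_{gc} / \sum_g a_{gc})\) (tag `six_plus_ln_frac`) or
\(6 + \log_{10}(a_{gc} / \sum_g a_{gc})\) (`six_plus_log10_frac`). Zeros
are replaced by the **global** matrix minimum nonzero value *before* the
transform, and the column totals are recomputed after replacement, so the
fractions still sum to 1. A `zero_policy="error"` mode refuses zeros
instead. The number of replaced zeros is reported.

Condition-quality filters (applied before any statistics): growth rate
must be present and strictly positive; alignment score, when present, must
be ≥ 80 (configurable). The filter report counts `missing_growth`,
`zero_growth`, and `low_alignment` separately; removing every condition is
an error.

Replicates (experiment columns sharing a `condition_id`) are averaged
arithmetically — values and growth rates alike — and boolean metadata
flags are merged by OR.

Duplicate experiment profiles are detected as column pairs with Spearman
ρ = 1 exactly (rank-identical profiles, which also catches monotone
re-scalings); constant columns, for which ρ is undefined, are reported
separately rather than matched. The drop policy removes **both** members
of each duplicate pair, since neither can be identified as the original.

`prune_to_sparse(matrix, target_n, seed)` iteratively removes one member
of the currently most-correlated column pair (Spearman) until `target_n`
columns remain. Ties are broken lexicographically by the column-name pair,
and the member to remove is chosen by a seeded coin flip; every iteration
is logged (pair, ρ, removed column), so runs are reproducible and
auditable.

## 3. GCI statistics (`gci_stats`)

\(\mathrm{GCI}_g\) is the Pearson correlation between gene \(g\)'s
expression profile and the growth-rate vector. It is NaN when fewer than
3 paired observations exist or either vector is constant — undefined is
never coerced to 0. The vectorized implementation uses centered dot
products over the whole matrix.

The permutation null draws **one** permuted GCI per gene: each gene's
expression vector is independently re-paired with a shuffled growth
vector. `null_summary` reports the null mean and sd and the fraction of
observed GCI outside mean ± 2 sd; this is descriptive, not a hypothesis
test.

`per_condition_cub_fit` regresses the CUB metric on each condition's
expression column; for simple OLS the fit R² equals the squared Pearson
correlation, which is what is computed. `growth_vs_fit_correlation` then
takes the Spearman correlation of that R² with growth rate. For n ≤ 9
conditions the two-sided p-value is **exact**, by vectorized enumeration
of all n! rank pairings; above that it falls back to the asymptotic
`scipy.stats.spearmanr` p-value.

`doubling_time(rate) = ln 2 / rate`. At the default growth-rate range
endpoints 0.07 and 1.42 h⁻¹ this gives 9.90 h and 0.488 h; note that a
display that truncates rather than rounds to two decimals would show the
latter as 0.48.

## 4. Model battery (`model_suite`)

Four OLS models of per-gene CUB \(y_g\), fit with statsmodels:

| model id      | design                                                       |
|---------------|--------------------------------------------------------------|
| `expr_only`   | \(1 + \bar e_g\)                                             |
| `gci_only`    | \(1 + \mathrm{GCI}_g\)                                       |
| `additive`    | \(1 + \bar e_g + \mathrm{GCI}_g\)                            |
| `interaction` | \(1 + \bar e_g + \mathrm{GCI}_g + \bar e_g \cdot \mathrm{GCI}_g\) |

Rows with any NaN are excluded listwise before fitting (the common-sample
n is reported per fit). A rank-deficient design raises
`SingularDesignError` rather than returning pseudo-inverse coefficients.
Each fit reports coefficients, standard errors, R², adjusted R², and the
overall F-test p-value. For the additive model, variance inflation
factors \( \mathrm{VIF}_j = 1/(1 - R_j^2) \) are computed (infinite when
\(R_j^2\) reaches 1 within 1e-14). `linear_vs_quadratic_aic` compares a
linear to a quadratic fit by AIC for curvature checks.

## 5. Group statistics (`group_stats`)

- **Two-sample t-test**: pooled-variance Student's t by default
  (df = nₐ + n_b − 2), Welch as an option; implemented via
  `scipy.stats.ttest_ind`.
- **GCI-sign split**: genes with GCI < 0 vs > 0; exact zeros and NaN are
  excluded and their count reported.
- **Over-representation analysis**: for a query set of size n drawn from a
  universe of N genes with K annotated to a term and k in the overlap,
  the upper-tail hypergeometric p-value is `hypergeom.sf(k-1, N, K, n)`.
  The odds ratio is the 2×2 cross-product \((ad)/(bc)\), reported as
  `inf` when only the denominator is zero and NaN when both are.
- **Multiple testing**: Benjamini–Hochberg via
  `statsmodels.stats.multitest.multipletests` (`fdr_bh`).
- **Reporting thresholds** (defaults): raw p ≤ 0.04 **and** BH q ≤ 0.05;
  surviving terms are ranked by descending odds ratio (term id as a
  deterministic tie-break) and truncated to the top 15 (`top_k=None`
  disables truncation).

## 6. Synthetic data generator (`simulate`)

The generator is the study condition: its defaults define the dataset the
acceptance checks run on, and every planted parameter is recorded in a
`SyntheticTruth` (JSON-serializable) for recovery testing.

**Conditions.** `n_cond = 50` growth rates drawn Uniform(0.07, 1.42) h⁻¹;
condition ids `cond000…`; optional replicate expansion (experiment columns
`{cond}_r{k}`, with small growth-rate jitter only when replicates > 1) and
optional ALE / mutant-or-KO flag assignment.

**Expression.** For gene g in condition c,

\[ e_{gc} = b_g + s_g\,\mu_c + \varepsilon_{gc}, \qquad
   \varepsilon \sim \mathcal N(0, 0.5^2), \]

with baselines \(b_g \sim \mathcal N(5, 1.5)\) (log-ish scale) and a slope
mixture: 65 % of genes \(s_g \sim \mathcal N(-1, 0.5)\), 35 %
\(s_g \sim \mathcal N(1.5, 0.5)\). The negative-majority mixture plants
the left-skewed GCI distribution; the positive component is stronger so
growth-coupled genes are clearly separable. Defaults: 3,000 genes.
Duplicate experiments are optionally injected by copying **all** replicate
columns of a source condition into a new condition (`{src}_dup{k}`); the
condition-id pairs are recorded in the truth.

**Sequences.** Each gene gets a bias strength

\[ \beta_g = \mathrm{softplus}\big(\alpha\, z(b_g) + \gamma\, z(s_g)
   + \mathcal N(0, \sigma_\beta^2)\big), \]

with defaults \(\alpha = 1.0\) (expression coupling), \(\gamma = 1.2\)
(growth-slope coupling), \(\sigma_\beta = 1.5\); softplus keeps β
positive. Codons are sampled within each synonymous family with
probability \(\propto w^{\beta_g}\), so high-β genes concentrate on
preferred codons and CUB increases monotonically with β. Sequences start
with ATG, end with a stop, default mean length 300 codons. The default
(\(\alpha, \gamma, \sigma_\beta\)) was chosen at design time, before
freezing the acceptance checks, so that mean expression and GCI each carry
independent signal (additive adjusted R² ≈ 0.50 vs 0.44/0.32 for the
single-predictor models, VIF ≈ 1.45); an earlier \(\gamma = 0.6\) draft
made the two predictors nearly collinear directions of the same latent
(b, s) pair, which is unrealistic and uninformative.

**Annotations and labels.** 20 terms of ~60 genes; 2 planted terms draw
their members preferentially from positive-slope genes with enrichment
strength 4 (at strength 0 the draw is uniform — a null check). Labels mark
`essential = slope > 0` for the t-test stage. Sub-generators use fixed
large-prime offsets of the dataset seed so stages are independently
reproducible.

**What the generator does not emulate:** read-count noise models
(expression noise is Gaussian on the transformed scale, not
negative-binomial counts), gene–gene correlation structure (co-regulation,
operons), amino-acid composition differences between genes (all genes
share one sampling recipe), GC-content or mutational bias gradients,
condition-specific regulation beyond the single linear growth response,
and batch effects other than literal duplicate columns.

## 7. Pipeline (`pipeline`, `cli`)

`RunConfig` (YAML-loadable) validates paths and parameters before any
stage runs; errors carry a stage and machine-readable code
(`missing_input`, `sparse_n`, …) and leave a `FAILED` marker in the output
directory. Stage order: prep → score → gci → condition_fits → models →
group_stats, each appending a record to `manifest.json` with its counts
(columns in/out, filter report, duplicates dropped, zeros replaced), so
input/output accounting can be audited after the fact.

## 8. Numerical choices, in one place

- geometric means in log space (exact for these magnitudes, no underflow);
- undefined statistics are NaN, never 0 (GCI below 3 conditions, constant
  columns in pairwise R², ρ for constant profiles);
- exact Spearman p by enumeration at n ≤ 9, asymptotic above;
- deterministic tie-breaks everywhere a choice is arbitrary (lexicographic
  pair order + seeded coin in pruning; term id in enrichment ranking);
- all randomness flows through `numpy.random.default_rng` seeds held in
  configs or the truth object; reruns are bit-identical.

## 9. Limitations

- The permutation null is one-shot (one permutation per gene): cheap and
  unbiased for distributional comparison, but not a per-gene significance
  test; use more permutations for that.
- Exact Spearman p-values are limited to n ≤ 9 (10! pairings is already
  3.6 M × vector ops); the asymptotic fallback is approximate at
  moderate n.
- The OLS battery assumes homoscedastic Gaussian errors; CUB scores are
  bounded in (0, 1], so fits near the boundary are approximations (a
  logit transform is left to the caller).
- ORA treats genes as exchangeable; it does not correct for gene length
  or expression-level sampling bias.
- Duplicate detection requires *exact* rank equality; near-duplicates are
  handled by `prune_to_sparse`, not by the duplicate filter.
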