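# Methods

## Model

For one trio (stratifier, gene, biomarker) the package models expression
`y` as linear in the imaging biomarker `x` within each genotype subgroup
`g`:

```
y = a_g + b_g x + ε,   ε ~ N(0, σ²) i.i.d.
```

The null hypothesis of interest is that all subgroups share one line,
`(a_1, b_1) = … = (a_G, b_G)`, tested by the generalized Chow statistic
built from residual sums of squares: `S_C` from the pooled fit and `S_g`
from the subgroup fits,

```
F = [(S_C − Σ S_g) / ((G−1)k)] / [Σ S_g / (N − Gk)],
```

referred to the F distribution with `(G−1)k` and `N − Gk` degrees of
freedom. The model always includes an intercept, so `k = 2`. A line
through volume/expression data without an intercept would force the fit
through the origin for no biological reason, and the classic structural-
break formulation counts the intercept among the tested parameters, which
is what makes the three-group numerator degrees of freedom equal `2k`.

Assumptions worth keeping in mind: homoscedastic Gaussian errors with a
common variance across subgroups (the F denominator pools them), linearity
within subgroup, and independent samples. Under heteroscedasticity the
test over-rejects; the synthetic-data section below shows one concrete way
this matters.

### Numerical edge cases

- A subgroup with fewer than `k + 1 = 3` samples, or with a constant
  biomarker, cannot identify a line; it is dropped. If fewer than two
  eligible subgroups remain, the trio's p-value is *missing* (NA), not an
  error, so genome-scale scans keep going. Missing-p trios are excluded
  from FDR and from top-N selection.
- The numerator `S_C − Σ S_g` is mathematically non-negative but can come
  out slightly negative from floating-point or federated-solver residue:
  F is clamped at 0 (p = 1).
- If every subgroup fits perfectly (`Σ S_g = 0`), the statistic is 0 when
  the pooled fit is also perfect and +∞ (p = 0) otherwise.
- `N = Gk` leaves no denominator degrees of freedom and raises an
  insufficient-data signal.

## Federated protocol

The fits can be computed without pooling data. Institutions hold
`(X_i, y_i)`; minimizing `Σ_i ½‖X_i w − y_i‖²` by gradient descent needs
only the per-site gradients `∇S_i(w) = X_iᵀ(X_i w − y_i)`, which sum to
the global gradient. Each round, sites send gradients, the coordinator
broadcasts the sum, and *the sites* apply the update — the coordinator
never holds an updated `w`, so it cannot difference consecutive gradients
against a known coefficient vector to reconstruct `X_i`. After
convergence each site reports its scalar residual sum and count; the
coordinator assembles `S = Σ S_i`, `N = Σ N_i` per model (one per
subgroup plus the pooled model — four models when three subgroups are
eligible) and evaluates F and p from those scalars alone.

Design choices:

- **Conditioning.** Biomarker and expression are standardized before
  fitting, using globally aggregated first and second moments (counts and
  sums only, so nothing beyond aggregate statistics crosses a boundary).
  On standardized data the normal-equations matrix is essentially the
  identity scaled by `N`, so the applied step is `w ← w − (η/N)∇S` with
  `η = 0.1` by default, tolerance `1e-8` on the global gradient norm, and
  a 10,000-iteration cap (hitting the cap returns the fit with a
  convergence warning carrying the achieved norm). Final coefficients and
  residual sums are reported on the original scale; the residual scalars
  are computed by the sites from the back-transformed coefficients, which
  is what makes the aggregated `S` exactly a sum of per-site quantities.
- **Transport.** The protocol is pure message exchange (stats, gradient
  and residual messages), so it runs in-process, across processes or via
  files; there is no network code. An optional message log captures the
  full transcript as newline-delimited JSON for privacy audits.
- **Determinism.** Sites are iterated in list order and all randomness
  (partitioning) is seeded, so transcripts and results reproduce exactly.

The federated solution matches the centralized closed form to ~1e-9
relative in practice (tested at 1e-6), and is invariant to how samples
are partitioned across sites — the property the test suite checks across
partitions into 1, 3, 5 and 7 institutions. The published stability
experiment this mirrors states no simulation parameters, so its printed
residual value is not a reproduction target; only the invariance is.

**Privacy scope.** The guarantee enforced (and audited by test) is about
message *content*: only gradient vectors of length `k`, aggregate sums,
residual scalars and counts ever appear. No differential privacy or
secure aggregation is attempted. One inherent caveat: any sum over a
single sample equals that sample's raw value, so aggregate-sum messages
from a site holding exactly one sample of some subgroup are trivially
identifying — an unavoidable property of sum-based aggregation, relevant
to deployments with very small per-site subgroups.

## Enrichment probabilities

A selection of `N` genes from a universe of `M`, of which `k` fall in a
reference list of `n`, is scored with the hypergeometric distribution.
Three conventions are exposed, because published enrichment tables are
not always explicit about which quantity they print:

- `greater` — strictly-greater upper tail `P(X > k)` (default; the
  standard enrichment test);
- `geq` — `P(X ≥ k)`;
- `point` — the probability mass `P(X = k)` at the observed overlap.

The worked example the acceptance script reproduces (M = 20,211,
n = 632, N = 1,625, k = 73 → p = 0.00039) follows the **point**
convention: all seven printed values of the published table it comes
from match `P(X = k)` to printed precision, while the upper tail gives
0.00068 (same order of magnitude). The point mass is not a tail
probability and should not be read as significance; the four parameters
are carried in every result so any convention can be audited. Ranking
SNPs at fixed (M, n, N) is monotone in `k` under all three conventions,
so the choice does not affect SNP ranks, only the printed numbers.

Gene identifiers are matched case-insensitively; entries outside the
universe are dropped and logged. The default universe is the set of
scanned genes. P-value ties in any ranking are broken lexicographically
by identifier so reruns are byte-identical.

## Hardy–Weinberg QC

SNP filtering uses the exact conditional test: given the observed allele
counts, the probability of each attainable heterozygote count is computed
from the conditional distribution, and the p-value sums the probabilities
of all outcomes no more probable than the observed one. Monomorphic
sites admit a single outcome (p = 1). The filter runs on a designated
control-sample subset and removes SNPs with p below a configurable
threshold (default 1e-6, the conventional GWAS QC choice). The exact
p-value is discrete and conservative in small samples; its distribution
under the null approaches uniformity only for cohorts in the thousands,
which is why the calibration test uses cohorts of 10,000.

## Synthetic data

The generator produces exactly the structure the scan assumes: a Gaussian
biomarker (standard normal by default), biallelic genotypes drawn under
Hardy–Weinberg proportions `(p², 2pq, q²)` with configurable allele
frequency and missingness (or exactly balanced thirds with
`balanced_groups`, for calibration studies that fix per-group sizes), and
expression that is linear in the biomarker with per-genotype slopes for
planted causal (SNP, gene) pairs and a single shared slope elsewhere.
Group intercepts default to equal so that detected structure is
attributable to slopes alone. Causal genes are assigned to causal SNPs
round-robin and without replacement, so the truth table is unambiguous.

Default study conditions: 300 samples (~100 per genotype group at allele
frequency 0.5), planted slopes (0.5, 0.5, 3.0), noise sd 0.2 — a
strong-effect setting in which the planted gene essentially always tops
a 60-gene scan. Null calibration studies use equal slopes in all groups,
2,000 replicates, and check the rejection rate at α = 0.05 against a
3-standard-error binomial band.

**What the generator does not emulate:** linkage disequilibrium between
SNPs, correlated expression across genes, population structure,
covariates (age/sex), and non-Gaussian noise. Passing tests therefore
demonstrate correctness of the statistics and protocol under the model's
own assumptions, not robustness on real cohort data.

**The SNP-ranking experiment needs moderate effects.** A gene whose
slope varies with genotype carries extra variance `x²·Var(b)` when
viewed through *any other* stratifier. With the strong-effect slopes
(0.5, 0.5, 3.0) this slope-mixture heteroscedasticity inflates the Chow
F for causal genes under every SNP (the inflation is a constant factor,
so its p-value shrinks with n), every SNP's top-N selection saturates
with the causal genes, overlap counts tie, and the enrichment ranking
carries no information. The ranking study is therefore designed in the
regime where ranking is identifiable: slopes (0.5, 0.5, 1.0), noise sd
0.5, 300 samples, 150 genes with 16 causal across 4 of 12 SNPs, and
top-N equal to the per-SNP gene dosage (4), so a causal SNP fills its
selection with its own near-zero-p genes while a null SNP's top-4 rarely
reaches the reference list. In this design the four causal SNPs took the
top four ranks in 12 of 12 consecutive seeds, with the minimum causal
overlap strictly above the maximum null overlap — the ranking test also
asserts that separation, so a pass can never come from tie-breaking.

## Problem sizes used in the test suite

Simulation-heavy checks use: 2,000 replicates for null calibration
(three groups of 100); 100 seeds of 60-gene panels for planted-gene
recovery; three seeds of the 12-SNP ranking design for TPR; 1,000
samples for partition-invariance; 24 random datasets for federated-vs-
direct-formula agreement; full enumeration up to universe 50 (and 20
alleles for the Hardy–Weinberg test) for oracle equivalence. These sizes
make the binomial/enumeration bounds in the assertions meaningful while
keeping the default test run quick.

## Known limitations

- Bivariate models only; no covariate adjustment.
- At most three subgroups per stratifier (the genotype use case); the
  Chow machinery itself is general in G but the stratifiers are not.
- The federated solver is synchronous and dropout-free; sites are
  simulated in one process (or via serialized messages), not networked.
- Multi-allelic VCF records are skipped by default (or split on request);
  no phasing or imputation.
- Expression is assumed pre-normalized; no normalization is provided.
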