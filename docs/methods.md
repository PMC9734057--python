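# Methods

This note documents the statistical procedures `circpath` implements, the
generative model behind its synthetic cohorts, the defaults and why they
were chosen, and the limits of what the simulation-based tests can show.

## 1. The synthetic cohort generator

Every inference stage is validated against cohorts with *planted* causal
structure. A cohort is a set of (SNP, circRNA, gene, optionally miRNA)
triples, each assigned one of five scenarios, sharing one sample panel.

**Genotypes.** Dosages are drawn Binomial(2, maf) per SNP
(Hardy–Weinberg), maf uniform over a configurable range. Optional LD is
generated at the haplotype level through a Gaussian copula with
equicorrelation ρ inside blocks of configurable size, which creates
dosage correlation while preserving the Binomial margins — enough to
exercise the conditional independent-SNP selection, without pretending to
be a coalescent simulation.

**Geometry.** Each triple occupies its own chromosome region: back-splice
donor/acceptor 5 kb apart, cis SNPs spread within ±200 kb of the
back-splice sites (the planted causal SNP 1 kb from the donor), and the
trans gene 20 Mb downstream on the same chromosome. The cis window rule
(±200 kb, boundary inclusive) and the trans distance rule (gap strictly
greater than 5 Mb, or different chromosome) are therefore both exercised
by construction.

**Structural equations** (effects in residual-SD units; ε ~ N(0, σ²),
σ = `noise_sd`, default 1; k covariates ~ N(0,1) loaded with coefficient
0.5 on both circRNA and gene so covariate adjustment is consequential):

```
circ = beta_cis·g + 0.5·Σcov + ε                      (all non-NULL scenarios)
MEDIATION:    gene = beta_med·circ + beta_direct·g + 0.5·Σcov + ε
PLEIOTROPY:   gene = beta_pleio·g            + 0.5·Σcov + ε
INDEPENDENT:  gene = beta_pleio·g            + 0.5·Σcov + ε   (diagnosis independent)
REVERSE:      T ~ Bernoulli(expit(α + θ·g));  gene = beta_med·T + 0.5·Σcov + ε
NULL:         all genetic and causal effects zero
```

Diagnosis (except under REVERSE) is `logit P(T=1) = α + Σ θ_i·gene_i`,
with θ_i = `theta_trait` for MEDIATION triples and 0 otherwise; α is
solved numerically (Brent) so the expected prevalence is 0.5, matching a
near-balanced case/control cohort. INDEPENDENT deliberately keeps the
SNP→gene edge while severing any trait involvement — the "independent
model" in eQTL-trait causal taxonomy is a SNP that affects expression
while the trait varies for other reasons, and that is the structure the
causal-ordering test must reject.

**miRNA layer.** With `n_mirna > 0` and `mirna_bridge` (default), the
MEDIATION circ→gene edge is routed through a miRNA:
`mirna = √beta_med·circ + ε`, `gene = √beta_med·mirna + …`, so the
marginal SNP→gene slope is still `beta_cis·beta_med` while the miRNA
screen has a true mediator, and the target table records the miRNA's
sites on both the circRNA and the gene. `n_mirna_samples` restricts the
miRNA matrix to a sample subset, emulating a small-RNA library measured
on part of the cohort (the motivating study had 63 of 105 samples); the
pipeline aligns the miRNA stage separately so the main analyses keep the
full panel.

**Defaults** (`ScenarioConfig`): n_samples = 105 (the reference cohort
size), beta_cis = 0.8, beta_med = 0.6, beta_pleio = 0.48 (so the marginal
SNP→gene slope matches the mediation chain's 0.8·0.6), theta_trait per
experiment, maf ∈ (0.1, 0.5), 2 covariates. `gene_noise_sd` exists so a
pleiotropy cohort can be variance-matched to a mediation cohort
(σ·√(1+beta_med²)) when the two are compared head-to-head.

**What the generator does not emulate:** read counts and normalization
(expression is emitted already normalized — the real pipeline's
count-level normalization is upstream of everything tested here),
realistic LD/haplotype structure, imputation uncertainty, population
stratification, and non-linear or interaction effects. Passing tests
therefore demonstrate correctness of the *inference machinery* under the
declared linear-Gaussian/logistic generative model, not robustness to
every failure mode of real brain data.

## 2. QTL scans and permutation calibration

Expression is residualized once against [intercept | covariates]
(ordinary least squares); every (SNP, feature) test is then a simple OLS
slope on the residuals with a two-sided t p-value on n−2 df, which is the
additive linear model of standard matrix-eQTL practice. Internally the
scan works on z-scored variables so the whole SNP×feature grid is two
matrix products; `additive_test` is the audited scalar reference and the
grid path agrees with it to 1e-10.

**Empirical P.** `empP = (1 + #{P_i < P_obs}) / (n_perm + 1)` with a
strict inequality (ties count as "not smaller"). Each permutation applies
*one shared* sample-label permutation to the whole residualized
expression matrix and re-runs the scan — sharing the permutation across
features preserves feature–feature correlation, and residualizing before
permuting keeps the permuted statistic exchangeable. The permuted
statistic is the per-feature minimum nominal P for the cis scan and the
per-SNP minimum across genes for the trans scan. Whether a pair's empP
should be computed against its own unit's null minima (default,
`pooling="per_feature"`) or against all permuted minima pooled
(`pooling="pooled"`) is genuinely ambiguous in the underlying procedure;
both are implemented behind a switch. Default n_perm = 10,000,
reducible for test-scale runs (empP < 0.005 requires n_perm ≥ 200 to be
attainable at all).

**Gating.** Per circRNA, the minimal empP across its window; Storey
q-values over those minima with π₀ estimated on the λ grid
0.05–0.95 (cubic smoothing spline evaluated at λ = 0.95, clipped to
(0, 1]; with fewer than 10 features π₀ is fixed at 1, i.e.
Benjamini–Hochberg). circRNAs with q < 0.05 are circQTL-containing;
their associations with empP < 0.005 are retained.

**Independent signals.** Conditional-and-joint selection re-implemented
on individual-level data (the reference tool operates on summary
statistics with an LD panel; with genotypes in hand the individual-level
forward-stepwise is exact): seed with the minimum-p SNP, repeatedly add
the candidate with the smallest conditional p < 1e-3 given the selected
set, skipping candidates with R² > 0.9 against it, then a backward pass
drops any SNP that loses conditional significance in the joint model.

**Control SNPs.** For each max-circQTL, the matched control is the
scanned SNP with minimal nominal p across circRNAs > 0.05 whose MAF is
within 0.05, minimizing the difference in distance-to-back-splice-site,
chosen without replacement.

## 3. Mediation and partial correlation (MPT)

The mediator model `m ~ 1 + g` and outcome model `y ~ 1 + g + m` are fit
by OLS on covariate-residualized expression, dosage treated as a
continuous treatment. Inference is quasi-Bayesian: `n_draws` (default
1000) coefficient vectors are drawn from each model's asymptotic normal;
per draw ACME = a·b, ADE = c′, total = ACME + ADE (an exact identity
under the linear model), proportion mediated = ACME/total, clipped to
[−2, 2] for reporting because the ratio is heavy-tailed when the total
effect is near zero. Point estimates are medians, p-values two-sided
zero-crossing tail proportions floored at 1/n_draws, the ACME CI the
2.5–97.5 percentile band. A nonparametric bootstrap is intentionally not
the default — the quasi-Bayesian approximation is the standard default of
the R mediation ecosystem and is an order of magnitude cheaper at equal
draws.

The partial correlation is Spearman: rank-transform x, y and the
controls (average ranks on ties), regress the x- and y-ranks on
[intercept | control ranks], correlate the residuals, p from t on
n−2−k df. Zero-rank-variance controls are dropped with a warning; a
zero-variance residual yields (ρ = 0, p = 1, degenerate flag) instead of
an error so batch runs survive pathological axes.

An axis passes **MPT** iff p(ACME) < α and post-adjustment p < α
(α = 0.05). For comparing correlation strengths across groups the
two-sided Fisher-z test `Z = (z₁−z₂)/√(1/(n₁−3)+1/(n₂−3))` is provided,
as is the binned summary "fraction of axes passing mediation per
correlation-significance bin" (bins from decreasing thresholds, empty
bins reported missing rather than zero).

## 4. Causal inference test

The CIT is an intersection–union test: the ordering L → G → T holds only
if four conditions hold simultaneously, so the omnibus p is the maximum
of four component p-values — (1) L–T association (logistic LRT), (2) L–G
association given T (linear F), (3) G–T association given L (logistic
LRT), and (4) *conditional independence* of L and T given G. Binary
outcome models are logistic with likelihood-ratio p-values (own
Newton–Raphson; on separation/non-convergence both models are refit with
a ridge of 1e-4 and the result flagged).

Condition (4) is an equivalence test — a non-significant conditional
association is not evidence of independence — and is the one place where
a permutation scheme must be chosen. The implemented scheme rebuilds the
mediator under the no-mediation null while retaining the L→G link:
`G* = fitted(G~L) + permuted residuals(G~L)`; the statistic is the
partial F for L in the linear model T ~ L + G, and
`p4 = (1 + #{F*(G*) ≤ F_obs}) / (n_perm + 1)`. Under true mediation the
real G absorbs the L–T association and G* cannot, so F_obs falls far
below the permuted F's and p4 is small; under a direct L→T effect F_obs
is large and p4 → 1. (The alternative construction — permuting a
G-preserving surrogate of *L* and counting permuted F's above the
observed — makes p4 uniform under true mediation and destroys the power
of the omnibus test; it was evaluated and rejected.) The scheme is
seeded, vectorized over permutations, and isolated in one function for
auditability. Defaults: n_perm = 1000 for p4, 50 rounds for the
permutation FDR, both reducible.

FDR: each round permutes the genotype vector (severing all L links) and
recomputes every triple's omnibus p; `q(t) = mean permuted #{p ≤ t} /
observed #{p ≤ t}`, clipped to [0, 1] and monotonized from the largest
threshold downward; a pair "passes CIT" at p < 0.05 and q < 0.05.

## 5. Paths, miRNA screen, enrichment

Axes are the SNP-keyed join of cis and trans calls; propagation paths
the (snp, gene)-keyed join of MPT-passing axes with CIT-passing pairs.
The miRNA screen takes each (circ, gene) pair and each miRNA with target
sites on both, requires the circ–gene Spearman p < 0.05, and passes the
candidate iff the partial-correlation p after controlling the miRNA is
≥ 0.05 — the opposite direction of the SNP-adjustment rule, because here
the *disappearance* of the correlation is the mediation evidence. The
"unrelated" threshold (0.05) is configurable; note it is a
non-significance rule and therefore sample-size dependent — at large n
even the small residual left by rank-based partialling of a linear chain
becomes significant, which is why the screen runs on the (smaller) miRNA
sample overlap. Gene-set enrichment is a one-tailed Fisher exact test
per target list against a configurable background (default: all genes
tested in the trans scan), odds ratio ad/bc with a 0.5 continuity
correction only when a cell is zero (flagged), BH-adjusted across the
provided lists.

## 6. Pipeline, seeds, determinism

`RunConfig` carries every threshold with its canonical default (window
200 kb, n_perm 10,000, empP < 0.005, q < 0.05, trans P < 1e-4, trans
distance 5 Mb, α 0.05, MAF filter 0.05) plus one master seed; each stage
derives a named substream via `SeedSequence(master, spawn_key=crc32(stage))`,
so identical config + seed reproduces every output byte for byte and
changing one stage's workload does not perturb another's draws. The
manifest records thresholds, seeds and the tally at every filter, and the
tallies are non-increasing along each chain by construction.

## 7. Problem sizes used by the tests and the acceptance script

Simulation scales were fixed up front from power analysis under the
default effect sizes, and the suite runs them as stated:

* **Calibration** (NULL): 200 circRNAs, n = 105, n_perm = 1000.
* **Mediation recovery**: one cohort at n = 10⁴ (ACME standard error
  ≈ 0.012, so the planted 0.48 is pinned to ~2%).
* **MPT discrimination**: 200 mediation vs 200 variance-matched
  pleiotropy cohorts at the reference n = 105.
* **CIT discrimination**: 100/200/200 cohorts at n = 500 with
  n_perm = 200 and θ = 1.5 — at n = 105 the diagnosis arm of the test is
  underpowered for any effect size a single gene plausibly has on a
  binary trait, so the causal/non-causal contrast is demonstrated at a
  cohort size where the marginal L–T logistic test has ~90% power.
* **End-to-end recovery**: 50 runs at n = 800 with common variants
  (MAF 0.3–0.5), n_perm = 300, CIT n_perm = 500. The binding constraint
  is the trans-call rule P < 1e-4 ∧ empP < 0.005: with a marginal
  trans slope of 0.48 SD per allele the noncentrality at n = 105 is ≈ 3,
  giving ~15% power, so a desk-scale *joint* demonstration of all six
  stages needs the deeper cohort; at n = 800 every stage clears 95%
  power and the full path is recovered with no decoys in ≈ 90–95% of
  runs.

The acceptance script reports these same quantities from fresh seeded
cohorts; nothing in it is stored or looked up.

## 8. Known limitations

* All mediation logic is linear; treatment–mediator interactions and
  sensitivity analysis for sequential ignorability are out of scope, so
  "passes MPT" means consistency with linear mediation, not proof of it.
* Covariate adjustment happens once, upstream; CIT consumes residualized
  expression but raw diagnosis (no covariates inside the logistic
  models).
* The independent-SNP selection needs individual-level genotypes; there
  is no summary-statistic mode with an external LD reference.
* The trans scan is restricted to declared circQTL (and control) SNPs,
  not genome-wide.
* Storey's π₀ smoother is evaluated at the largest λ of the grid; with
  heavy signal fractions (>50% non-null) π₀ is conservative.
* The miRNA screen's pass rule rewards *absence* of evidence and should
  only be compared across analyses at a fixed sample size.
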