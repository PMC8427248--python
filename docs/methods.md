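# Methods

## Scope and data model

The package analyses balanced multi-environment variety trials in
randomized complete block designs.  The canonical container is a long-form
plot table keyed by (genotype, environment, block, trait); a wide per-plot
CSV dialect is accepted on read and melted internally, because field books
are normally kept wide while the analysis code wants one observation per
row.  Labels are opaque strings and keep input order everywhere, so output
tables reproduce the row order of the source data.  Missing cells are
carried explicitly as NaN, never dropped: any ANOVA on an unbalanced trait
refuses to run unless `allow_unbalanced=True`, because the
expected-mean-square identities behind the variance components assume a
full layout.  The unbalanced fallback is plot deletion with reduced
degrees of freedom, computed as a sequential (type-I) OLS decomposition
with blocks and environments fitted before genotypes; its variance
components are no longer method-of-moments clean and should be treated as
descriptive.

## ANOVA

For the balanced paths the sums of squares are computed directly from
marginal means (the textbook decomposition), not via a regression fit:
this is exact, keeps a single 17×3×3 analysis in the tens of microseconds
(which matters for the 10⁴-replicate Monte-Carlo checks), and is verified
in the test suite against an independent OLS sequential ANOVA.  Blocks are
nested within environments because blocks are re-randomized each year; the
pooled error degrees of freedom are therefore e(g−1)(r−1), which is what
makes the df column add to N−1.

F denominators: all effects are tested against the pooled error mean
square by default, matching how combined variety-trial tables usually
print separate F values for genotype, environment and G×E.  When
environments are viewed as random, the genotype test against pooled error
is anti-conservative, so `genotype_denominator="gxe"` switches the
genotype F to the G×E mean square.  A zero error mean square makes F
undefined; it is reported as NaN (and p as NaN, not 1) and never as
infinity.

## Variance components and genetic parameters

σ̂g² = (MSG − MSE)/r_eff is the method-of-moments estimator; r_eff is the
number of plots behind each genotype mean.  In a combined analysis over e
environments with r blocks that is e·r — using r would overstate σ̂g² by a
factor of e, and only e·r makes the reference table's magnitudes coherent.
`r_policy="per_env"` exposes the single-environment convention.  A
negative moment estimate is truncated to zero in the reported summary
(standard practice), with the raw value and a flag preserved for
diagnosis; heritability is clamped to [0, 100] against ulp overshoot when
σ̂e² = 0.

GA uses h² as a proportion internally while all I/O is on the 0–100
percent scale, matching how these tables are printed.  The selection
intensity default 2.06 corresponds to selecting the top 5 %.  The optional
low/moderate/high annotation uses the common literature cutoffs (10/20 for
CV-type quantities and GAM, 30/60 for h²); these are conventions, not
results, and are labelled as such.

Reproduction of the bundled reference summary: recomputing the chain from
the published (σg², σe², μ) matches the published σp², h², GCV and PCV to
±0.01 for almost every trait, but the published GA and GAM columns were
evidently computed from unrounded intermediates — recomputation from the
rounded printed inputs deviates by up to ≈0.1 on the printed scale (worst:
NPP GAM 60.41 vs 60.51).  The package always computes from unrounded
intermediates; the residual discrepancies against the printed figures are
expected and are left visible in the acceptance tests rather than papered
over.

## LSD, CV and letter display

LSD(α) = t(1−α/2, df_error)·√(2·MSE/n) with n = r_eff plots per mean;
CV% = 100·√MSE/μ.  The compact letter display exploits that LSD
comparisons on sorted means have interval structure: the maximal
descending runs whose range is within the LSD each get one letter, which
makes "share a letter ⇔ differ by at most LSD" exact (a property test
asserts the equivalence on random mean sets).  Ties are broken by input
order for determinism.  The reference table's own printed LSD rows are not
exactly recoverable from its printed error variances under any standard
df/replication convention, so the package documents its convention (above)
and does not chase those footer values; the printed LSDs are retained in
`datasets` for qualitative checks such as the top letter group of grain
yield.

## Multivariate suite

All three analyses take the genotype-mean table (n = genotypes), because
published per-genotype PCA scores indicate means, not plots, are the
multivariate unit.  Correlation p-values use the t transform on n−2 df,
two-tailed, with no multiplicity correction (none is conventional in these
reports).  PCA is an eigendecomposition of the trait correlation matrix —
forced by the fact that reference eigenvalues sum to the trait count —
with each eigenvector flipped so its largest-magnitude loading is
positive; eigenvector signs are arbitrary, so comparisons with published
loadings must allow a global per-component flip.  The |loading| > 0.3
importance rule uses a strict inequality.  Clustering is scipy average
linkage on Euclidean distances over standardized means; standardization is
the default because traits mix days, centimetres and t/ha, and raw
Euclidean distance would be dominated by plant height.  `standardize=False`
is available.  On the bundled reference means the k = 3 cut isolates the
genotype the source trial also singled out (SARI-3-11-100); full
three-cluster membership is a diagnostic only, since the original
analysis' scaling convention is unstated.  The dendrogram exports as a
rooted Newick string with ultrametric branch lengths (leaf depth = half
the final merge height).

## Synthetic trials

The generator draws every effect in y = μ + G + E + GE + B(j) + ε as an
independent zero-mean Gaussian — the distributional assumption of the
ANOVA framework, and the choice that makes recovery distributions
analyzable.  One integer seed feeds a SeedSequence whose spawned children
drive each effect (and each trait), so a draw is reproducible and
component-wise stable.  Multi-trait simulation draws genotype effects
jointly from N(0, D^{1/2} R D^{1/2}) with R the genetic correlation matrix
(validated symmetric, unit-diagonal, PSD — rejection reports the smallest
eigenvalue) using the SVD method, which is well defined for the singular
covariances that arise from |r| = 1 or zero-variance traits.

`cowpea_like_spec()` is the default test condition: per-trait genotypic
and residual variances and grand means equal to the reference trial's
published estimates, with the genotype-effect correlation set to the
empirical correlation of the reference genotype means.  What it emulates:
realistic signal/noise per trait and realistic trait inter-correlation at
the reference design size (17 × 3 × 3).  What it does not: non-Gaussian
effects, year-specific environment structure (var_e_env, var_ge and
var_block default to 0 because the reference table does not report them),
missing plots, or spatial field trends — so passing recovery tests show
estimator correctness under the stated model, not robustness to real-world
messiness.

## Monte-Carlo checks and problem sizes

Two stochastic suites run at sizes chosen to keep the whole test run in a
few minutes while leaving negligible Monte-Carlo error: variance-component
recovery uses 2000 replicates of the 17×3×3 design at the reference DFF
components (mean σ̂g² within 2 MC standard errors of truth; the empirical
h² distribution covers the published 77.72 %), and the genotype-F type-I
error uses 10 000 null replicates judged against the 99 % binomial band
around 0.05.  The law-of-large-numbers check on the generator itself uses
10⁵ genotype draws at 1 % relative tolerance.

## Pipeline and reproducibility

`run_pipeline` writes CSV tables shaped like a variety-trial report
(sources × df/SS/MS/F/p; means ± SD with letters and grand-mean/LSD/CV
footer; the per-trait genetic-parameter table; correlation r and p;
loadings with eigenvalue/variability/cumulative footer; scores; cluster
membership) plus a Newick dendrogram and a JSON manifest recording seed,
config hash and library versions — no timestamps or hardware details, so
reruns under the same config and seed are byte-identical.  Floats are
written at 10 significant digits in report tables; the plot-data CSV
round-trips bit-exactly (values are re-parsed with correctly-rounded
`float()`, since pandas' fast parser can be off by an ulp at 17
significant digits).

## Known limitations

No REML or mixed models, narrow-sense heritability, heritability standard
errors, multiple-comparison procedures beyond LSD, lattice/alpha designs,
spatial modelling or outlier handling.  The unbalanced path is a
convenience, not a recommendation.  Heritability here is broad-sense on a
genotype-mean basis via the r_eff convention; with nonzero G×E variance in
the generator the moment estimator from the combined analysis absorbs
G×E/r into σ̂g², which is a property of the estimator, not a bug — the
recovery tests therefore simulate with the interaction components the
estimator assumes absent.
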