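# Methods

## The count model

Tag counts for gene *g* in sample *s* are modelled as Poisson with rate
proportional to the sample's sequencing depth:

    y_gs ~ Poisson(mu_gs),   log mu_gs = log N_s + x_s' beta_g

`N_s` is the per-sample total tag count ("library size"), supplied as a model
offset.  This normalises by total reads per sample without touching the
counts themselves; `N_s` may exceed the count-matrix column sum, since not
every mappable tag falls in an annotated gene.  When a design table carries
no `total_tags` column, column sums are used as a fallback and a warning is
logged.

Three mean structures are fitted per gene:

* `~ stage + source` (FULL_MAIN) vs `~ source` (REDUCED_NO_STAGE) for the
  cleavage-stage contrast (df = 1, residual df = 3 in the six-sample design);
* a free cell-means model `~ stage * source` (FULL_INTERACTION, residual
  df = 2) vs the same model with one stage's source split collapsed, for the
  in vitro vs in vivo contrast within that stage.

Fitting is iteratively reweighted least squares, vectorised over genes (one
shared design matrix, per-gene weight matrices, batched normal-equation
solves).  Convergence is declared when the relative deviance change falls
below 1e-10 (50 iterations maximum); because Newton steps converge
quadratically, converged log-likelihoods are accurate to ~1e-10, which the
oracle-equivalence tests rely on (closed-form two-group deviance to 1e-8).

**Boundary fits.**  A gene with a structurally empty factor level (e.g. zero
tags in every 4-cell sample) has its MLE at the boundary; the linear
predictor is clamped (eta >= -45, fitted means floored at 1e-8) and the fit
is flagged `boundary`.  The clamped log-likelihood equals the boundary limit
to machine precision, so LRT statistics remain meaningful, but such genes are
interpreted through categorisation (presence/absence), not through their
asymptotic p-value alone.  Their reported coefficient-based fold change is
accompanied by a descriptive log2 ratio of mean CPM with a 0.5 pseudocount.

## Overdispersion

Low-input embryo pools show clear extra-Poisson variability.  The
quasi-likelihood treatment estimates a per-gene Pearson dispersion under the
full model,

    phi = max(1, X^2 / df_residual),   X^2 = sum_s (y_gs - mu_gs)^2 / mu_gs,

and scales the LRT by it.  The floor at 1 means underdispersion never
sharpens inference — the overdispersed analysis can only be more conservative
than the standard one, and its significant set is provably a subset of the
standard set (tested on 50 random matrices).

**Reference distribution.**  With three residual degrees of freedom, `phi` is
itself very noisy, and referring `LRT/phi` to chi-square(1) ignores that
noise: a direct Monte-Carlo check (negative-binomial null, phi = 3, the
six-sample design) puts the null `p < 0.05` rate near 10% and inflates the
far tail roughly six-fold — enough to destroy BH-FDR control.  The stage and
source analyses therefore refer `LRT/(phi*df)` to `F(df, df_residual)`, the
standard quasi-likelihood small-sample reference, which the same check shows
to be slightly conservative (~3% at nominal 5%).  The plain scaled
chi-square form remains available (`overdispersion_reference="chisq"`, and it
is the default of the low-level `overdispersed_test` operation, whose scaling
identity `p(phi=1) = p_standard` is part of the API contract).  The practical
cost of the F reference is power: with only 3 denominator df, even a gene
with an infinite true fold change cannot reach p-values much below ~1e-3 at
moderate counts, so at realistic tag depths the overdispersed analysis is
deliberately hard to convince.  That trade-off — calibration over power at
n = 6 — is the package's central design choice.

## Retention filter, multiple testing, categorisation

Genes with full-model expected counts >= 5 in at least two samples are
retained before testing; BH runs over retained genes only, at alpha = 0.05.
For the source analysis BH is applied within each stage separately (the
per-stage reporting is the quantity of interest; a joint correction is a
one-line change).

Significant genes are categorised by a structural-zero rule: zero raw tags
summed across all samples of a stage means "absent" at that stage (2-cell
only / 4-cell only); otherwise the sign of the stage coefficient decides
2-cell vs 4-cell enriched.  An `absence_threshold` parameter relaxes strict
zero to "< t tags" if desired; the default is 0 because it is exactly
testable and matches the structural-zero generator.

## Synthetic data

The generator emulates the downstream structure of the study design, not
reads: six samples (2-cell: 1 in vivo + 2 in vitro; 4-cell: 2 in vivo + 1 in
vitro), library sizes (1.56M–12.8M) matching the study's mappable-tag totals,
and five gene classes in proportions 1/4/4/1/90 (%) — ten percent of genes
truly stage-affected, dominated by the enriched classes, with a small rim of
structural-zero "only" genes.  Baseline per-tag rates are lognormal,
`ln lambda ~ N(-11.5, 1)`, giving a typical gene a few dozen tags per sample
at these depths, comparable to a moderately expressed transcript in the
tags-matching-CDS totals of a low-input pool.  Stage effects are uniform on
1–2 log2 units; in vitro source effects (off by default, fraction
configurable) are applied at the 2-cell stage only, mirroring
culture-condition effects concentrated before genome activation.  The
dispersion default is phi = 3; the study gives no estimate of its own
dispersion, so this is a free parameter chosen to be clearly, but not
extremely, super-Poisson.

Counts are gamma–Poisson: `lambda ~ Gamma(m/(phi-1), phi-1)`, `y ~
Poisson(lambda)`, giving mean m and variance phi*m exactly — the
mean–variance relation the quasi-Poisson fit assumes (plain Poisson at
phi = 1).  Each gene draws from its own `SeedSequence((seed, gene_index))`
sub-stream, so matrices are bit-reproducible and independent of iteration
order; class labels are apportioned by largest remainder (counts sum exactly
to n) and shuffled with a separate sub-stream.

What the generator does **not** emulate: read-level artefacts (mapping bias,
color-space errors), gene length effects, correlated genes, transcript
degradation during library preparation, or the maternal-transcript
destabilisation that makes pre-EGA qPCR/RNA-seq comparisons discordant in
real embryos.  Passing recovery tests therefore show the statistics behave as
designed under their own assumptions — not that those assumptions hold for
any particular sequencing run.

The qPCR emulator writes Ct values whose target-minus-reference differences
reproduce the true log2 fold changes (one cycle per doubling) plus Gaussian
technical noise, with a constant-Ct spiked reference; zero-noise plates
invert exactly through the ddCt formula, which the tests exploit.  GV-oocyte
and blastocyst groups are synthetic flanking points (GV tracks the 2-cell
maternal pool; blastocyst sits 4-fold below it for maternal transcripts) —
plumbing for calibrator choices, not a model of oocyte biology.

## qPCR validation

Standard curves are least-squares lines of Ct on log10 dilution; efficiency
is `E = 10^(-1/slope) - 1`, undefined (and flagged) for non-negative slopes.
A curve is acceptable when |r| >= 0.98 and E lies in 85–100% (with 0.1%
numerical slack at the window edges, since slopes are quoted rounded).
Relative expression uses ddCt with perfect-doubling base 2 by default;
passing an efficiency switches to `(1+E)^(-ddCt)`.  Replicates are aggregated
as the arithmetic mean of dCt before differencing, with per-replicate ddCt
spread reported as a standard deviation.  Concordance between qPCR and
RNA-seq folds reports the Pearson correlation of log2 folds plus a
per-gene direction flag: concordant when both platforms agree in sign beyond
0.5 log2 units or both are flat within it.

## Clustering and enrichment

Expression for display is log2(CPM + 0.5); the pseudocount keeps structural
zeros finite without dominating low counts.  Ordering uses complete-linkage
agglomerative clustering on Euclidean distances (scipy), which is monotone in
merge heights and deterministic given the input order (distance ties resolve
by input order); the merge tree exports to Newick.  Replicate QC reports
Pearson r between same-condition replicate pairs on the log2 scale; under a
shared-signal model with signal variance a^2 and noise variance b^2 the
expected r is a^2/(a^2+b^2), which the tests verify at a 4:1 ratio (r = 0.8).

Term enrichment is a plain one-sided hypergeometric test with BH adjustment
and fold enrichment `(k/n)/(K/N)` — a minimal, exactly testable stand-in for
annotation services, without GO-graph propagation or jackknifed counts.
Term-set overlap is `100 * |A ∩ B| / |denominator|` with the query set as the
default denominator (configurable to the other set or the union).

## Problem sizes and numerical conventions

The acceptance script simulates 20 replicates of 2000 genes (the generator
defaults) for the false-discovery check — enough replication for the mean
false-discovery proportion to be stable to a couple of percentage points —
and the test suite uses matrices of 400–2000 genes per property.  Percentages
for display round half-up to the nearest integer; full precision is kept
internally.  All randomness flows from integer seeds through
`numpy.random.SeedSequence`; reruns are byte-identical.

## Known limitations

* No shrinkage or empirical-Bayes moderation of dispersions: each gene's phi
  uses 2–3 residual df on its own, which is exactly why the F reference (and
  its conservatism) is needed.  Sharing information across genes would buy
  power at the cost of the simple per-gene quasi-likelihood contract.
* No exact/conditional Poisson tests; boundary genes get no finite-sample
  p-value treatment beyond flagging.
* BH assumes the usual positive-dependence conditions; per-gene tests on the
  same six samples are treated as independent enough.
* The categorisation "absent = zero tags" is a sequencing-depth-dependent
  statement; at very low depth a present transcript can draw zero tags.
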