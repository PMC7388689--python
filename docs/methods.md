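# Methods

This note documents the models implemented in `pleiokit`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
study conditions can and cannot establish about real data.

## Summary-statistics model and harmonization

A trait's table carries, per SNP: effect allele `a1`, other allele `a2`,
per-allele effect `beta`, its standard error `se > 0`, p-value in (0, 1],
sample size and effect-allele frequency. Validation drops rows violating
these invariants; p-values of exactly 0 are clamped to the smallest positive
float rather than dropped, so extreme hits survive downstream ranking.

Two tables are joined on rsID (not chrom:pos — the id is the stable key when
merging meta-analysis files from different builds of the same panel). If
trait 2 records the same SNP with alleles swapped, its effect sign is flipped
and its frequency complemented; strand-complement matches are treated the
same way. A/T and C/G palindromic SNPs are removed rather than
frequency-resolved: with no strand annotation their orientation cannot be
decided reliably, and removal is the conservative standard. Irreconcilable
allele pairs are dropped and counted. All of these events are recorded in an
audit dictionary so a run can report exactly what the join did.

## Synthetic data generator

The generator emulates the *inputs* of a two-trait pleiotropy analysis; it
is a first-class, tested module, not a fixture.

**Panel.** Haplotype alleles are thresholded latent Gaussians. Within an LD
block the latents follow an AR(1) chain with parameter `rho_ld` (default
0.8); across blocks they are independent. Allele frequencies are
Uniform(0.05, 0.5). Haplotype pairs form diploid dosages. This gives
controllable block-diagonal LD that is sufficient for exercising pruning,
LD scores and regional colocalization; it does not reproduce the long-range
and admixture structure of real reference panels.

Blocks are placed with inter-block gaps larger than the LD-score window
(default gap 1.1 Mb vs window 1 Mb). Real genomes have no such gaps; here
they keep the estimated LD score of a SNP free of contributions from blocks
that are, by construction, unlinked. Without the gap, the few hundred null
cross-block pairs inside each window add zero-mean but high-variance noise
to the estimated scores, and regressing on a noisy regressor attenuates the
heritability slope (a ~30% bias at the default panel size in our checks).
The gap removes the attenuation at its source instead of post-hoc
correcting the estimator.

**Effects.** Each SNP is assigned to one of four components — null,
trait-1-only, trait-2-only, shared — with probabilities `pi` (default
0.85/0.05/0.05/0.05). Standardized effects `b` (per-allele
`beta = b/sqrt(2f(1-f))`) are zero-mean Gaussian on the causal set, with
shared-component pairs bivariate with correlation `rg_shared` (default
0.5), and each trait's vector is rescaled so the realized heritability
`sum(b^2)` equals the target exactly (default 0.3 per trait). Each block's
true colocalization label follows from its members: a shared SNP makes it a
shared-causal region; both trait-specific kinds present make it a
two-distinct-causals region.

**Observed statistics.** Observed z-scores are
`z = sqrt(N) * (R b) + Normal(0, 1)` with `R` the within-block panel
correlation, i.e. marginal associations are LD-smeared exactly as a GWAS
sees them; reported standard errors use the quantitative-trait
approximation `se = 1/sqrt(2 N f (1-f))`. Case-control liability modelling,
imputation noise and population stratification are not simulated, so the
expected chi-squared follows the LD-score relation with intercept 1 — the
estimated intercepts being near 1 is a property of the generator, not
evidence that the estimator would de-confound real data.

**Outcome.** The outcome trait's standardized effects are
`gamma_causal * b1_marginal` (default 0.5), optionally plus direct
pleiotropic effects, so every SNP's Wald ratio against the trait-1 marginal
effect is centered on `gamma_causal` and MR recovery is well-defined.

**Regional generator.** For colocalization calibration a lighter generator
draws independent regions directly: each realizes one of the five regional
models (default mixture 0.70/0.10/0.10/0.08/0.02), causal |z| Normal(6, 1)
with random sign (median 6), unlinked SNPs. LD within regions is omitted
deliberately: the calibration question is about the five-model posterior
arithmetic and prior estimation, not about fine-mapping resolution under
LD, which this package does not claim.

All generators are pure functions of (config, seed), with separate named
substreams per output so any artifact can be regenerated independently.

## LD utilities

Pairwise r² is the squared Pearson correlation of dosages (monomorphic SNPs
are defined as unlinked, with a warning). Pruning slides a 50-SNP window in
steps of 5; within a window, pairs are scanned in position order and the
lower-MAF member of any pair with r² > 0.2 is removed; ties remove the
later SNP (the tie rule is unspecified in common implementations and is
fixed here for determinism). The scan repeats until no window contains a
violating pair, making the result a fixed point; bit-compatibility with any
particular external pruner is not promised. SNPs absent from the panel pass
through with a warning.

LD scores sum the small-sample-adjusted `r2_adj = r2 - (1-r2)/(n-2)` over
all SNPs within 1 Mb, including the self term (exactly 1). Because adjusted
terms can be negative, a finite-sample score can dip below the self term,
which is impossible in the population; scores are floored at 1.

Block partitions are ordered disjoint half-open intervals, 1-based to match
VCF positions; BED input (0-based starts) is shifted on read. A SNP at
position p belongs to the block with start ≤ p < end.

## Conditional and conjunction FDR

The empirical dominance-count estimator is used:
`cFDR_i = min(1, p1_i * #{p2_j <= p2_i} / #{p1_j <= p1_i and p2_j <= p2_i})`,
counts inclusive of SNP i itself (denominator ≥ 1). The inclusive-≤
convention matters — off-by-one changes every value — and is frozen by an
O(N²) brute-force oracle that the fast path (Fenwick-tree dominance
counting, O(N log N), exact under ties) must match exactly in the test
suite. No kernel smoothing is applied: the raw estimator is what the
enrichment framework needs and keeps every number exactly reproducible.

The conjunction FDR is the maximum of the two directional cFDRs. The
significance cutoff per direction is the largest cFDR among SNPs already
genome-wide significant (p < 5e-8) in the principal trait; if no SNP
qualifies the model refuses and asks for a manual cutoff. For the
conjunction flag the default cutoff is the larger of the two directional
cutoffs, with "1g2"/"2g1"/float overrides, since reasonable analyses differ
on which direction's cutoff to carry over.

cFDR is computed on the LD-pruned SNP set by default: the dominance counts
assume approximately exchangeable SNPs, which dense LD violates.

Diagnostics: stratified QQ curves plot the ECDF of principal -log10 p
within conditional strata p2 ≤ t for t in {1, 0.1, 0.01, 0.001, 0.0001};
fold enrichment is the tail ratio
`[#{p1<=10^-x, p2<=t}/#{p2<=t}] / [#{p1<=10^-x}/N]`, identically 1 in the
t = 1 stratum; the conjunction Manhattan table lays chromosomes end to end
with the threshold line at -log10 of the conjunction cutoff.

## Regional colocalization

Per SNP and trait, the Wakefield approximate Bayes factor under a Gaussian
effect prior with variance W: with V = se², z = beta/se, r = W/(V+W),
`ABF = sqrt(1-r) * exp(r z^2 / 2)`, averaged over W in {0.01, 0.1, 0.5}
(documented defaults for continuous traits in this model family; exposed in
`AbfConfig`). All arithmetic is on the log scale and remains finite for
|z| up to 50 and beyond.

Regional Bayes factors assume at most one causal SNP per trait per region
and a uniform prior over causal configurations:

* RBF1 = mean_i ABF1_i, RBF2 = mean_i ABF2_i (one causal, one trait),
* RBF3 = mean_i ABF1_i·ABF2_i (one shared causal SNP),
* RBF4 = mean_{i≠j} ABF1_i·ABF2_j (two distinct causal SNPs; each ordered
  pair equally likely).

RBF4 is computed by the stable subtraction
`(sum_i)(sum_j) - sum_diag` on the log scale, falling back to an explicit
off-diagonal log-sum-exp when the subtraction nearly cancels. Single-SNP
regions cannot host two distinct causals; their log-RBF4 is -inf and they
are excluded from prior estimation (but still reported).

Genome-wide model weights maximize `sum_r log(sum_m pi_m RBF_mr)` (RBF0 = 1)
over the 5-simplex by EM, with a symmetric Dirichlet(1.1) penalty keeping
weights off the boundary; the penalized objective is nondecreasing per
iteration and convergence is declared at a gain below 1e-8 (cap 1,000
iterations, warn on non-convergence). Fixed priors can be supplied instead
for reproducible toy examples. Per-region posteriors are
`PP_m ∝ pi_m RBF_m`; a region is *classified* as model m only if PP_m
strictly exceeds the cutoff (default 0.9, matching the operating point at
which the shared-causal call list is expected to keep FDR below 0.1 — a
correspondence the acceptance script measures rather than assumes).

The putative causal SNP under models 1/2/3 is the argmax of the within-region
posterior weights (ABF1, ABF2, or their product, normalized); ties take the
first SNP in position order. Model-4 regions report one top SNP per trait.
Sample overlap between the two GWAS is not corrected for; with heavily
shared samples the trait-specific hypotheses can be conflated, which is
flagged here rather than modelled. Colocalization uses the unpruned
harmonized SNP set by default (the regional model wants the dense signal;
pruning first can delete the causal variant), switchable by flag.

## LD score regression

Single trait: weighted regression of chi² on ℓ under
`E[chi2_j] = 1 + N h2 ell_j / M + intercept excess`, h² = slope·M/N.
Weights follow the standard two-step form
`1/(max(ell,1) * (intercept + N h2 ell/M)^2)` (overcounting ×
heteroskedasticity), iterated twice from an initial 1/ell fit; an
unweighted mode exists for exact tiny examples. SNPs with chi² > 80 are
excluded (configurable); at desk scale the per-SNP non-centrality is far
larger than in a real GWAS, so this cap costs a little true signal
(~0.006 of h² at the default conditions) — the default is kept because it
is the field's standard guard against outliers, and the recovery tests pass
with it in place.

Cross-trait: regression of z1·z2 on ℓ with a free cross-intercept (sample
overlap is estimated, not assumed absent);
genetic covariance = slope·M/sqrt(N1 N2), and
r_g = gencov/sqrt(h2_1 h2_2), refusing when either h² estimate is
nonpositive. Standard errors come from a delete-one block jackknife over
200 contiguous SNP blocks; the r_g jackknife recombines all three
regressions' per-block replicates so the heritability uncertainty
propagates. Because the cross fit's weights differ from the single-trait
weights, feeding the same trait twice returns r_g ≈ 1 to regression noise,
not machine precision. Estimates outside [0, 1] are reported and flagged,
not truncated. Stratified/partitioned heritability is out of scope.

## Mendelian randomization

Instruments are exposure SNPs with p < 5e-8, LD-pruned with the same
windowed rule as the main analysis, then harmonized against the outcome.
The IVW estimate is `sum(bx by / sey^2) / sum(bx^2 / sey^2)` — the
fixed-effect pool of per-SNP Wald ratios, reducing to by/bx for a single
instrument — with the standard error inflated by sqrt(Q/(n-1)) when
Cochran's Q exceeds its degrees of freedom. MR-Egger (weighted regression
of by on bx with a free intercept, weights 1/sey²) is the directional
pleiotropy sensitivity check; constraining its intercept to zero recovers
IVW exactly. The estimators are the field-standard reconstruction for this
two-sample design; no claim is made of matching any particular published
protocol's unstated choices. Significance-selected instruments carry
winner's-curse attenuation (visible as a few percent downward bias in the
demo); the recovery tests use strongly powered instruments where the effect
is within the stated tolerance.

## Pipeline

`run_pipeline` executes harmonize → prune → cFDR → enrichment →
colocalization → LD score regression → MR from one `PipelineConfig`
(YAML-loadable). Every stage writes TSVs; `manifest.json` captures the full
configuration, seed, per-stage counts and computed thresholds — enough to
re-create every output number. The manifest deliberately omits the output
directory path so identical runs are byte-identical wherever they land.
Stage failures raise a named `StageError` (CLI exit code 3; config errors
exit 2) and earlier artifacts are retained. Figures (stratified QQ,
fold-enrichment, conjunction Manhattan with its threshold line) render from
the TSVs alone.

## Problem sizes used in the tests

The default study conditions are 20,000 SNPs in 50-SNP blocks, panel of 200
diploid individuals, N = 50,000 per trait, h² = 0.3 per trait, 5% shared
SNPs with effect correlation 0.5, causal outcome effect 0.5. Recovery and
calibration tests average 20–50 replicates at these conditions;
colocalization calibration uses 2,000 regions × 50 SNPs per seed over 5
seeds; MR recovery uses a concentrated configuration (100 strong causal
SNPs, N = 200,000) so instrument strength, not winner's curse, dominates.
These sizes were chosen as the smallest at which the asymptotic properties
under test are expected to hold cleanly.

## Known limitations

* The generator's LD is block-diagonal with inter-block gaps; conclusions
  about pruning and LD scores transfer to real panels only qualitatively.
* cFDR p-value exchangeability after pruning is approximate; residual LD
  inflates dominance counts slightly.
* Colocalization assumes at most one causal SNP per trait per region and
  ignores GWAS sample overlap.
* LDSC here is unstratified; annotation-partitioned heritability is not
  implemented.
* MR implements IVW and Egger only; weighted-median/mode estimators,
  Steiger filtering and bidirectional analyses are out of scope.
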