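# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Summary-statistics model

The pipeline never touches individual-level genotypes. A study contributes,
per SNP, an effect β on the log-odds/liability scale with standard error se,
effect-allele frequency f, p-value, and an effective-sample-size weight
N_eff = 4/(1/cases + 1/controls). Studies distributed as Z-scores are
converted with the sample-size-scheme inversion

    se = 1 / sqrt(2 f (1 − f) (N + Z²)),    β = se · Z,

which guarantees β/se round-trips Z exactly. The frequency (not the
p-value) enters the 2·f·(1−f) term; any other reading is dimensionally
incoherent. Allele harmonization flips β and replaces f by 1−f for
swapped-allele records, rescues strand flips only for non-palindromic
pairs, and excludes the rest. SNPs whose effect-allele frequency ranges
more than 0.2 across studies (strictly greater) are excluded before
pooling; the boundary case 0.2 is kept.

## Meta-analysis

Fixed effects use inverse-variance weights w_i = 1/se_i²:
β̂ = Σw_iβ_i/Σw_i, se = 1/√Σw_i. Heterogeneity is quantified by Cochran's
Q = Σw_i(β_i − β̂)² on k−1 df and I² = max(0, (Q−(k−1))/Q)·100. When the
Q-test p < 0.1 **and** I² > 50% — both strict, jointly — the SNP is
re-pooled with DerSimonian–Laird random effects:
τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)), w*_i = 1/(se_i² + τ²). Under a
homogeneous truth with k = 4 this joint trigger fires at the χ²₃ tail rate
of max(Q_{p=0.1}, 2(k−1)) ≈ 10% of SNPs; because the selected SNPs get
wider DL intervals, the *marginal* CI coverage of the pipeline output is
slightly conservative (~95.5% at τ² = 0). Coverage of the CI machinery
itself is therefore validated on the fixed-effects estimator, where the
independence of the pooled mean and Q makes 95% exact. SNPs present in a
subset of studies are pooled over the available ones (k reported); no
minimum-k filter is applied by default. Two-sided normal p-values are
computed in log-space and floored at the smallest positive double; a
`mlog10p` column carries the magnitude past underflow.

## Locus definitions

Greedy clumping walks SNPs by ascending p (ties broken by id for
determinism) and removes a candidate only when an already-accepted SNP on
the same chromosome is simultaneously within the window **and** correlated
at r² ≥ the threshold; pure-distance clumping is obtained with
r2_threshold = 0. The known-locus database is the union over studies of
per-study index variants at the suggestive level p < 5×10⁻⁶ (r² < 0.001,
10,000-kb window). A meta-analysis hit at p < 5×10⁻⁸ is novel iff its
distance to the nearest known index on its chromosome is ≥ 500,000 bp
(the boundary itself counts as novel) or its chromosome is absent. LD is
consumed from a precomputed pairwise r² table; absent pairs mean r² = 0.

## Annotation

Gene windows use the gene body (1-based inclusive; BED input converted
from 0-based half-open) intersected with ±500 kb around the SNP. Distance
is 0 inside the body, else the nearer edge. The PoPS assignment keeps the
maximum-score gene among scored window genes; negative scores are
legitimate maxima; score ties break by proximity, then symbol.

## Enrichment

For a query of m SNPs against a context of r SNPs in a background of m+n,
the upper tail P(X ≥ k) of the hypergeometric distribution is computed via
log-space survival functions (stable to backgrounds of 10⁷). The
enrichment factor is observed/expected overlap k/(rm/(m+n)). BH step-up
adjustment (delegated to statsmodels) is applied within each analysis
family — brain regions and cell types separately. The genome background is
a configuration value; results that depend on its absolute size should be
read as rankings, not calibrated probabilities.

## SMR

For each probe, the top cis SNP is the minimum-p eQTL association passing
p ≤ 5×10⁻⁸ (ties by |z|, then position). With z_G = b_G/se_G and
z_E = b_E/se_E,

    b_SMR = b_G/b_E,  T_SMR = z_G²z_E²/(z_G²+z_E²) ~ χ²(1),
    se_SMR = |b_SMR|·sqrt(1/z_G² + 1/z_E²)   (first-order delta method).

T_SMR ≤ min(z_G², z_E²), so p_SMR can never beat the weaker of the two
inputs. Probes are de-duplicated by id before BH over the scan. The HEIDI
linkage test is deliberately out of scope — upstream LD pruning is the
pleiotropy guard — as is multi-SNP SMR and binary BESD input.

## Two-sample MR

Instrument selection is asymmetric by design: forward (exposure panel →
disorder) uses p < 1×10⁻⁵ with r² = 0.1 in 500 kb; reverse (disorder →
traits) uses p < 5×10⁻⁶ with r² < 0.001 in 10,000 kb, and removes every
SNP already used forward so the two instrument sets are disjoint by
construction. Both require strength F = (β/se)² > 10, strictly.
Harmonization aligns outcome effects to the exposure's effect allele and
drops palindromic SNPs whose frequency lies in [0.42, 0.58] on either side
(a conventional ambiguity window; the underlying studies name none).

Per-instrument Wald ratios β_j = β_out/β_exp carry the first-order SE
se_out/|β_exp| (second-order term omitted — with F > 10 it contributes
< 10%). IVW is the inverse-variance-weighted mean; its SE is inflated by
√(Q/(n−1)) when Q exceeds its df (multiplicative random effects), which
leaves the point estimate untouched. MR-Egger regresses β_out on β_exp
with a free intercept, weights 1/se_out², after orienting all β_exp ≥ 0;
SEs carry the free WLS residual scale RSS/(n−2) and p-values use t on n−2
df, making the intercept test exact under a Gaussian null with homogeneous
weights. The weighted median interpolates the 50% point of the
weight-CDF over sorted ratios, with a seeded parametric-bootstrap SE
(1,000 draws). Simple and weighted mode estimators (kernel-density modes
of the ratio distribution) are provided as clearly presumptive extras and
are off by default in reports. The MR-PRESSO global test simulates the
null distribution of the leave-one-out residual sum of squares
RSS = Σ_j w_j(β_out,j − β̂_{−j}β_exp,j)², w_j = 1/se_out,j², by redrawing
β_out,j ~ N(β̂_{−j}β_exp,j, se_out,j) n_sim = 1,000 times;
p = (1 + #{sim ≥ obs})/(n_sim + 1). Outlier-correction and distortion
stages are not implemented. Leave-one-out "passes" when every
leave-one-out CI overlaps the sign of the full-sample estimate.
Significance across a trait panel is BH-adjusted IVW p < 0.05 per
direction. All stochastic steps are bit-reproducible under a fixed seed.

## Integration

The joint report counts, per SNP: novel-locus membership, forward and
reverse instrument membership (post-harmonization sets), each QTL panel
version in which the SNP is a significant top SNP (FDR_BH < 0.05 within
that version's scan), and presence in ≥1 significantly enriched region and
cell context. Ordering is count-descending then id — deterministic and
input-order independent.

## Synthetic-data generator: what it emulates

The generator is the package's study design, not a test fixture. Defaults
follow the motivating study's stated conditions where they exist — four
case-control GWAS of sizes (18,382/27,969), (18,235/36,741), (888/362,304),
(22,916/32,504); a microbiota-exposure panel of n = 5,959; 13 brain-region
and 8 brain-cell contexts — and a desk-scale genome elsewhere: 50,000 SNPs
in 10-SNP LD blocks (within-block r² = 0.8, blocks ≥ 1 Mb apart so the
500-kb and 10,000-kb windows behave distinctly), MAF uniform on
[0.05, 0.5], 1% polygenic causal SNPs with effect SD 0.05, between-study
τ² = 0.

Summary statistics are simulated directly: observed β = true β + study
shift (SD τ) + N(0, se²) with se from the frequency/sample-size formula.
LD enters only through the r² table — exactly what clumping consumes.
Planted structure with recorded truth: five SNPs with divergent
cross-study frequencies (exercising the eAF filter); 20 mediated
expression probes whose top-SNP GWAS effect equals 0.5 × the eQTL effect
(so b_SMR = 0.5 is the planted ratio, identical truth re-noised across two
eQTL versions and one mQTL version); per-trait instruments in reserved LD
blocks with |β_exp| in [0.1, 0.2] (F ≈ 25–100 at n = 5,959); two forward-
and two reverse-causal traits at |β| = 0.15; and two hub SNPs (β = 0.04)
that drive mediated probes in every QTL version, sit in every enrichment
context and enter the reverse-MR instrument set. Allele pairs are drawn
non-palindromic so no simulated signal is lost to strand ambiguity;
palindromic handling is covered by unit tests on hand-built records.

What it does **not** emulate: realistic LD decay (block r² is constant),
population stratification, sample overlap between exposure and outcome,
compositional microbiome structure, winner's-curse in the published
exposure effects, and genotype-level missingness. Passing tests therefore
demonstrate correctness of the statistical machinery under its stated
assumptions, not robustness to those real-data pathologies.

## Numerical choices and degenerate inputs

p-values floored at the smallest positive double; hypergeometric and
normal tails in log space; clumping ties broken by (p, id); single-study
SNPs report Q as missing, not 1.0; k = 1 pooling is the identity; b_eQTL =
0 raises rather than silently yielding an infinite ratio; instruments with
β_exp = 0 are excluded from ratio-based estimators with a count;
zero-instrument traits are skipped with a recorded reason and never abort
the panel.

## Problem sizes

The default test suite and the acceptance script use 4,000–10,000-SNP
worlds for recovery measurements (e.g. CI coverage at ~10,000 SNPs, 500
replicates for type-I-error checks, 18 mediated probe measurements pooled
over three QTL versions) and one full 50,000-SNP end-to-end run — sizes
chosen so every stochastic check retains a ≥ 2-MC-SE resolution while the
whole suite completes in well under a minute of compute per component.

## Known limitations

The enrichment background size is arbitrary by necessity; only rankings
and planted-overlap recovery are asserted. The mode-based MR estimators
are presumptive extras without literature-exact bandwidth choices. The
random-effects fallback makes marginal CI coverage mildly conservative
under homogeneity (see above). Genome-build liftover, BESD parsing, live
annotation queries, PoPS training and the HEIDI test are out of scope.
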