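# Methods

This note documents the statistical machinery, the synthetic-data
model behind every test, and the numerical and design choices that
were genuinely open.

## Maternal animal model and REML

The phenotypic model is

    y = Xb + Zu + Wm + S p_m + e,
    u ~ N(0, A σ²_u),  m ~ N(0, A σ²_m),  p_m ~ N(0, I σ²_pm),
    e ~ N(0, I σ²_e),

with `u` indexed by the recorded animal and `m`, `p_m` by its dam. The
direct–maternal genetic covariance σ_um is supported but **off by
default**: the printed model treats u and m as independent, and σ_um
is weakly identified at desk scale. A fit with `include_cov_um=True`
adds the cross-term `cov(Zu, Wm) = σ_um (Z A W' + W A Z')`.

The engine (`fit_reml`) works on the marginal covariance
`V = Σ_j θ_j B_j`, where each random term contributes a fixed n×n
matrix `B_j` (e.g. `Z A_sub Z'`) scaled by its parameter. One
iteration evaluates the restricted log-likelihood, the score, and the
average-information matrix; the update is an AI (quasi-Newton) step
with:

* **step halving** until the restricted logL does not decrease, so
  accepted iterations are monotone by construction;
* an **active set**: a variance pinned at its floor with an outward
  gradient is frozen for that iteration (prevents boundary creep);
* an **EM-style fixed point** `θ_j ← θ_j · (y'P B_j P y)/tr(P B_j)`
  as fallback when no damped AI step improves;
* variance floors at `1e-6 · var(y)`; convergence at |ΔlogL| < 1e-8
  and relative parameter change < 1e-6; maximum 200 iterations.

Standard errors come from the inverse AI matrix at convergence;
heritabilities and their SEs use the delta method on component ratios.
REML maxima at the boundary (σ̂²_e → floor, ĥ² → 1) are legitimate
outcomes in small designs — the restricted likelihood genuinely peaks
there for some samples — and are reported as such rather than
suppressed.

**Family blocks.** The combined nonzero pattern of the `B_j` is split
into connected components and each block is factorized independently.
Under half-sib structure with a pedigree kernel the records decompose
into per-sire-family blocks, which turns an O(n³) iteration into a sum
of much smaller factorizations. This is exact, not an approximation.

**Single-kernel fast path.** GREML and the association null models
have one kernel, so `fit_single_kernel_reml` eigendecomposes K once
and profiles the total variance out of the restricted likelihood,
leaving a 1-D bounded optimization of the heritability ratio — O(n)
per evaluation, no convergence-path concerns. The bivariate GREML
shares the same rotation; its 2×2 genetic and residual covariance
blocks are parameterized by Cholesky factors (PSD by construction),
optimized by Nelder–Mead from an empirical-covariance split, with
delta-method SEs for the genetic correlation.

**Pedigree matrices.** `A` comes from the tabular method, vectorized
one generation at a time (founders non-inbred; inbreeding accumulates
via `1 + a(s,d)/2`). `A⁻¹` uses Henderson's sparse rules with
inbreeding-adjusted Mendelian-sampling variances and is exact with
respect to the tabular `A` (asserted in tests).

## BLUP, reliabilities, deregression

The mixed-model equations are assembled over **all** pedigree animals
for both `u` and `m` (animal models produce proofs for non-phenotyped
relatives; in particular dams acquire maternal proofs through their
offspring, so more animals carry a maternal proof than a direct one).
Reliabilities are `r² = 1 − PEV/σ²` with PEV from the inverse
coefficient-matrix diagonal, computed by direct inversion — exact and
adequate at desk scale; approximation algorithms for national-scale
pedigrees are out of scope.

Deregression is defined as the exact inverse of a two-source blending
model. The EBV is viewed as the posterior mean combining (i) the
parent-average prior, PA = (EBV_s + EBV_d)/2 with reliability
r²_PA = (r²_s + r²_d)/4 (a missing parent contributes zero), and (ii)
own information worth z effective records, λ_g = (1 − h²)/h². With
q = 1/(1 − r²):

    z/λ_g  = q_i − q_PA
    DRP    = (q_i·EBV − q_PA·PA) / (q_i − q_PA)
    r²_DRP = (q_i − q_PA) / (q_i − q_PA + 1)
    w      = (1 − h²) / ((c + (1 − r²_DRP)/r²_DRP) · h²)

Re-blending DRP with the parent average reproduces (EBV, r²) exactly;
that identity is the module's correctness criterion and is asserted to
1e-8 on random cases. Animals whose reliability does not exceed their
parent-average reliability carry no own information and are dropped.
`c`, the fraction of genetic variance assumed uncaptured by markers,
defaults to 0.5 and is configurable. The DRP reliability (not the EBV
reliability) enters the weight formula. Scans keep records with
w > 0.2, strictly.

## Association scans

Variance components are estimated **once per null model**, never per
SNP; each SNP is then a generalized-least-squares fixed effect at the
null variance ratio (the standard MLMA shortcut). After rotation to
the kernel eigenbasis the per-SNP cost is a weighted regression, so a
scan is a few matrix products. For LOCO-type corrections there is one
null fit per chromosome or segment, and a SNP is always tested under
the fit whose exclusion contains it; a segment boundary SNP belongs to
exactly the segment holding it. DRP weights enter the residual
covariance as `diag(1/w)·σ²_e`; a flag disables weighting. With
`correction="none"` the scan is per-SNP ordinary least squares with
the exact t-test (residual variance re-estimated per SNP) — this is
the naive scan whose inflation the corrections are judged against.

PC covariates: `LOCO+PC20` adds the first 20 PCs of the full G to
every fit; `LOCO+CHR_PCk` adds the first k PCs of the *target
chromosome's* G only when testing that chromosome. PCA scores are
eigenvectors scaled by √λ, negative eigenvalues floored at zero, sign
fixed so each component's largest-magnitude loading is positive.

λ uses the χ²₁ median computed from the distribution (0.454936…,
printed as 0.4549) as denominator, on the Wald statistics directly.
Multiple testing: Bonferroni threshold 0.05/N and Benjamini–Hochberg
adjusted p (via statsmodels) at FDR 0.05. Per-SNP variance explained
is `2p(1−p)ĝ²/var(dependent)`.

Relationship matrices share one set of allele frequencies, computed on
the full post-QC SNP set and reused for every subset (LOCO, segment,
chromosome), so differences between full-G and LOCO-G reflect SNP
removal only; frequencies are not recentred per subset. Missing
dosages are mean-imputed at 2p, consistent with the centring. The
pruned-SNP LOCO scenario is its own analysis set and uses frequencies
from the pruned set.

## Quality control

* BW0 plausibility window [20, 60] kg, bounds retained ("above/below"
  read strictly).
* Outlier screen for the older-age weights: externally studentized
  residuals from the fixed-effects OLS fit, two-sided t p-values with
  n − p − 1 df, Bonferroni-multiplied by n and capped at 1; removal at
  adjusted p < 0.05. The literal printed rule also removes records
  with adjusted p > 0.95 — but a capped Bonferroni p equals 1 for
  essentially every unremarkable record, so the literal rule removes
  nearly everything. It is available behind `upper_cutoff=True` (with
  a warning) and off by default.
* SNP filters, all strict: call rate > 0.95, MAF > 0.01, HWE p > 0.001
  by the 1-df chi-square test (agrees with the exact test in
  accept/reject at these sample sizes; asserted ≥ 99% on random
  tables). Duplicate animals: pairwise identity over shared non-missing
  calls > 0.95 removes the lower-call-rate member, greedily.
* LD pruning follows the indep-pairwise idiom (window 50 SNPs, step 5,
  r² > 0.25; the window/step are conventions, not printed values):
  within each window the worse (lower-MAF) member of the worst pair is
  removed until no pair exceeds the threshold.

## Segment schemes

`SEG40`: chromosomes with more than 1500 SNPs are split at the
midpoint SNP into two segments; the rest stay whole. `SEG441` /
`SEG864`: per chromosome, `round(n/band-midpoint)` contiguous, as even
as possible segments aiming at 90–100 / 47–50 SNPs (only the totals,
not the algorithm, are prescribed; this reconstruction reproduces
them on maps of the published density). Chromosomes below the band
minimum become one segment with a warning.

## The synthetic population

The generator emulates the features of a Holstein-style genotyped cow
population that drive every result under test, and nothing more:

* **Skewed paternal half-sib families** — `daughters_per_sire` allows
  one family to dominate (the published population had an 855-daughter
  sire); this is the source of stratification, of naive-scan
  inflation, and of the PCA/k-means cluster structure.
* **Maternal pedigree depth** — dams come in half-sib groups under
  maternal grandsires, nested within each paternal family, with ~2
  offspring per dam by default. These links are what identify σ²_m
  against σ²_pm and σ²_e; without them the maternal components are
  confounded (the fitter warns in that design).
* **Genotypes** — founder allele frequencies uniform on `maf_range`;
  haplotypes are first-order Markov chains (a latent AR(1) Gaussian
  with lag correlation `adjacent_ld_rho`, thresholded at each allele
  frequency), giving decaying LD along the chromosome sufficient for
  pruning and LOCO to be meaningful. Gametes transmit whole
  chromosomes (no within-meiosis recombination): family covariance,
  not fine-scale linkage, is the structure under study.
* **Phenotypes** — exactly the maternal animal model: herd/year/month
  effects, a covariate slope (gestation length averaging 279.4 days
  within 265–295 for BW0; age in days otherwise), plus u + m_dam +
  pe_dam + e. (u, m) are drawn jointly either infinitesimally through
  the pedigree (parent-average + Mendelian sampling) or from causal
  SNPs rescaled to hit the target variances exactly (QTL mode,
  optionally restricted to chosen chromosomes for planted-signal
  tests). Default variances are birth-weight-like: phenotypic variance
  25 kg² split 46% direct, 14% maternal genetic, 5% maternal permanent
  environment, 35% residual.
* **Genotyping status** — daughters are genotyped, a configurable
  fraction of dams is, male ancestors are not (how dams were genotyped
  is not documented for the real population; the fraction is a flag).

What it does **not** emulate: realistic cattle LD maps or
recombination, selection and assortative mating, genotyping error,
multi-breed admixture. Passing tests therefore demonstrate the
correctness and calibration of the machinery under half-sib structure,
not the field accuracy of any particular real-data estimate.

Problem sizes in the test-suite were chosen for desk-scale runs: the
recovery study uses 50 replicates of 3,000 daughters in about 50
paternal families (asymptotic standard errors need that many
independent families to be trustworthy); calibration scans use 1,000 daughters ×
5,000 SNPs, averaging the inflation factor over replicate simulations
because a median over correlated SNPs in a three-family design is
itself noisy; the chromosome-partition study uses 500 daughters × 4
chromosomes over 20 replicates; the full-G-versus-LOCO comparison uses
many small families (40 × 8), where the attenuation from excluding one
chromosome dominates chromosome-specific sampling noise, as it does at
a real chip's SNP density. At these sizes variance-component SEs
are honest but wide — individual fits can sit at a boundary (ĥ² near
0 or 1) while 2-SE coverage of the truth holds at the nominal rate.

## Known limitations

* Dense linear algebra throughout: pedigrees and genotype sets beyond
  a few thousand animals need sparse/iterative methods that are out of
  scope.
* The gene test assumes independent SNP p-values; under LD it is
  anti-conservative (measured and asserted directionally in the
  tests). This reproduces the published procedure; no eigenvalue
  adjustment is applied.
* The multi-trait analysis is univariate + pairwise bivariate; a
  simultaneous trivariate fit is not implemented.
* "Total" heritability as printed in the source material has no stated
  formula and is not reported; direct, maternal and genomic
  heritabilities are.
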