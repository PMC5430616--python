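# Methods

`admixscan` reconstructs, as a reusable and fully tested library, the
statistical pipeline used to dissect tri-continental admixture in a large
genotyped cohort and to scan the genome for loci that are unusually
differentiated along one ancestry's branch: supervised/unsupervised
admixture decomposition with proxy ancestral panels, Hudson-Fst based
locus-specific branch lengths (LSBL), locus-bootstrap confidence intervals,
and outlier-SNP/region ranking.  This note documents the models, the
numerical choices, and what the synthetic-data tests do and do not show.

## The admixture model

Genotypes are diploid biallelic dosages counting the A1 (reference) allele.
With K ancestry components, individual ancestry proportions Q (samples x K,
rows on the simplex) and component allele frequencies P (K x SNPs), the
model is independent binomial sampling

    g_ij ~ Binomial(2, m_ij),    m_ij = sum_k q_ik p_kj,

and the log-likelihood (dropping the genotype-only binomial coefficient) is
`sum g ln m + (2-g) ln(1-m)` over non-missing cells.  Fitting is by plain
EM on the allele-copy complete data.  The supervised mode pins the Q rows
of designated proxy samples to pure indicator vectors for the duration of
the optimization; everything else is free.

Numerical choices:

- **Frequency clamp** `EPS = 1e-6` keeps `ln(0)` out of the likelihood;
  clamped frequencies print as 0.000 / 1.000 at table precision.
- **Convergence** is declared when the *relative* log-likelihood change per
  iteration drops below `tol`.  The default is `1e-7`.  Plain EM takes much
  smaller steps than the quasi-Newton block relaxation used by the standard
  admixture software, so a loose tolerance (e.g. relative `1e-4`, which
  stops after a few dozen iterations on cohort-scale data) leaves the
  ancestry proportions visibly short of the optimum (mean absolute error
  ~0.10 instead of ~0.02-0.03 on synthetic truth).  `1e-7` converges in a
  few hundred iterations at desk scale and is the default everywhere except
  inside bootstrap replicates (see below).
- **Restarts**: 3 random initializations by default (Dirichlet(1) rows for
  Q, observed frequencies plus noise for P), best log-likelihood kept; the
  seed is recorded in the fit object.
- **Label alignment**: unsupervised components are ordered by descending
  mean ancestry proportion; supervised components carry the proxy panel
  labels.  `match_components` performs best-permutation matching against a
  truth matrix for recovery experiments.
- EM monotonicity is asserted in tests on the stored per-iteration
  log-likelihood trace, and the EM optimum is cross-checked on a tiny
  instance against an independent multistart quasi-Newton search
  (L-BFGS-B on logit-transformed parameters, 160 random starts).  A literal
  dense grid at resolution 0.02 over the joint (Q, P) space of even a
  4-sample x 3-SNP, K=2 instance has ~51^10 points and is not computable;
  the multistart direct search plays the same role of an optimizer
  independent of the EM path.

**Component frequencies on unpruned SNPs.**  Model fits use LD-thinned
SNPs, but the scan scores every post-QC SNP.  `component_freqs_given_Q`
extends P to arbitrary loci by per-SNP maximization of the binomial
likelihood with Q held fixed (loci are independent given Q).  This is an
explicit reconstruction: published workflows rarely document how component
frequencies are extended to the unpruned SNP set, and fixed-Q per-SNP
maximum likelihood is the natural completion.

**Model order.**  `cross_validate` masks random genotype *cells* (not whole
samples) in k folds (default 10), refits, predicts masked cells as
`2 * m_ij`, and scores mean squared error.  Squared error stands in for the
reference software's undocumented deviance variant; the argmin over K is
what matters and is insensitive to this choice in our simulations.

## PCA with defining samples and projection

Axes are computed from a designated defining set only (the admixed cohort),
and other samples are projected onto them, so components rank variation
*within* the cohort.  Standardization is Patterson-style: per-SNP centering
at `2 p_hat` and scaling by `sqrt(2 p_hat (1 - p_hat))`, with `p_hat` from
the defining samples; SNPs monomorphic in the defining set are excluded and
missing dosages impute to the center.  Projection applies the stored
means/scales and loadings; it is refused below 80% SNP overlap, and no
shrinkage correction is applied to out-of-sample scores (a deliberate
choice; projected reference samples sit slightly closer to the origin than
they would in a joint PCA).  Loading signs are fixed by making
each column's largest-magnitude element positive.

## Proxy panels

Reference samples act as stand-ins for unobserved ancestral sources.  Each
ancestry is assigned a pole (a PC index and direction); candidates are
ranked most-extreme-first (ties broken lexicographically by id), panels are
filled to a common size N, and a sample claimed by two poles goes to the
one where its rank is more extreme.  Panel size is chosen by
`proxy_size_curve`: for each candidate N it reruns the supervised fit on B
locus-resampling bootstrap replicates and records the standard deviation of
the cohort-mean ancestry vector, summarized as the mean over components.
Loci (not samples) are the resampling unit, consistent with the
locus-bootstrap used for the genome-wide Fst confidence intervals, and the
EM tolerance is relaxed to 1e-3 inside replicates for speed.  The SE of the
*cohort-mean* ancestry is used (rather than averaging per-individual SEs);
the per-component values are also reported.

## Differentiation statistics

Pairwise Hudson Fst in two forms:

- parameter form `F = (p1-p2)^2 / [p1(1-p2) + p2(1-p1)]`, with the 0/0
  case (both frequencies 0, or both 1) defined as 0 — this convention is
  forced by table rows in which two components are both fixed and the
  branch statistic equals the remaining pairwise value;
- sample-corrected (Bhatia-style) form with numerator
  `(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)` over haploid counts n;
  per-locus values may be negative and are never truncated.

Genome-wide values aggregate as a **ratio of averages** `sum N / sum D`
over loci with positive denominators, never as a mean of per-locus ratios.
Confidence intervals are percentile bootstrap over loci (default B=10,000,
alpha=0.05, seeded and bit-reproducible).

The **LSBL** of a focal population 2 against 1 and 3 is
`(F12 + F23 - F13)/2`; it estimates the branch of 2 back to a hypothetical
common ancestral population and can be negative when 2 lies between the
others.  The **PBS** applies the same construction after the divergence
time transform `T = -log(1 - Fst)` and is undefined at a fixed difference.
The two statistics rank loci essentially identically when all pairwise Fst
are below ~0.9 (Spearman > 0.99 in simulation), which is why the scan uses
the simpler LSBL.

When a tabled comparison is between two sets of *frequencies* (component
vs component, or component vs reference panel at printed precision) the
parameter form is used — it is what reproduces the published per-SNP
values.  The sample-corrected form is used when raw genotype panels with
real counts are supplied; for an admixture *component* the effective
haploid count is taken as `2 N q_bar` (the haploid genomes attributable to
the component), which also reproduces the published small negative
component-vs-panel entry.  The mode is always explicit, never silent.

**Ranking and regions.**  Scans rank SNPs by descending statistic with
ties broken by (chromosome, position).  The top-k SNPs are grouped into
regions by single-linkage merging of same-chromosome positions within 1 Mb
— a merge radius chosen because it reproduces both published top-ten
groupings (5 regions for the branch scan, 8 for the pairwise scan); it is
configurable.  The scan is a ranking exercise and assigns no per-SNP
p-values.

**Group mean-ancestry tests** use the classical two-sample Hotelling T^2 on
two of the three ancestry proportions (the third is fixed by the simplex
and would make the covariance singular), with a Bonferroni threshold of
0.05 divided by the number of group pairs.

**TREEMIX export.**  Component allele counts are reconstructed as
`H = round(2 N q_bar)` haploid genomes with `A1 = round(H p)`.  A literal
`2 q_bar p` variant that omits the sample count (and so caps counts at 2)
is available behind `literal=True`.

## Synthetic cohorts

The generator is the inference model's generative complement plus drift:

- per-locus ancestral frequency `p_anc ~ Uniform(0.05, 0.95)`;
- Balding-Nichols drift per ancestry,
  `p_kj ~ Beta(p_anc (1-F_k)/F_k, (1-p_anc)(1-F_k)/F_k)` (mean `p_anc`,
  variance `F_k p_anc (1-p_anc)`);
- individual ancestries `q_i ~ Dirichlet(alpha)`;
- binomial genotypes; optional uniform missingness.

Defaults emulate the study design: K=3 with Dirichlet mean 0.57/0.20/0.23
(the reported cohort mean European/Amerindian/African ancestry) and
concentration 8, which reproduces the broad reported per-individual ranges;
drift F=0.15 per ancestry, a continental-scale value consistent with the
observed inter-continental differentiation.  Proxy-pool individuals are
pure single-ancestry, optionally contaminated by mixing in a fraction c of
a Dirichlet draw.  Outlier loci are created by *overwriting* one ancestry's
frequency with a target value (unambiguous truth for recovery tests); to
mimic the published outlier pattern — focal frequency near 0.9 while the
other two ancestries are near 0 — recovery experiments inject at loci
whose non-focal frequencies are below 0.1.  Without that placement an
injected locus whose background frequency is already high is not an
outlier at all, and a recovery test would measure the placement lottery
rather than the scan.

All randomness flows from the single spec seed through spawned numpy
`SeedSequence` children (frequencies, cohort ancestries, proxy ancestries,
cohort genotypes, pool genotypes, missingness), so an identical spec
reproduces an identical study bit for bit.

What the generator does *not* emulate: linkage disequilibrium (loci are
exchangeable and independent, so LD pruning is exercised only structurally),
realistic site-frequency spectra, migration or post-admixture drift, and
genotyping artifacts.  Passing recovery tests therefore demonstrate
correctness of the estimators under the model they assume, not robustness
to the ways real array data violate it.

## Problem sizes used in tests and the acceptance script

Simulation checks run at desk scale, chosen to give each check clear
statistical power while keeping the whole suite fast: supervised recovery
at 500 admixed samples x 3,000 SNPs (single fit; MAE threshold 0.05) and
paired supervised-vs-unsupervised comparisons over 10 replicates at
250 x 1,200; outlier recovery with 20 injections among 5,000 SNPs; model
order selection over 10 replicates of 180 x 400 at drift 0.25 with a flat
Dirichlet (strongly drifted, distinctly admixed individuals make K cleanly
identifiable); bootstrap calibration over 200 datasets of 400 loci with
B=500; and the optimizer cross-check on a 4 x 3 instance.  The bootstrap
default B=10,000 is retained for production use.

## Known limitations

- Plain EM is slower to converge than quasi-Newton alternatives; at
  hundreds of thousands of SNPs a production fit would want acceleration.
- Unsupervised fits on cohorts with no near-pure individuals are weakly
  identified (the usual admixture-model caveat); supervised fits with
  labeled panels are the intended mode, as in the study design.
- The LD pruning window/step (50/5) is conventional, not derived.
- Strand-ambiguous A/T and C/G SNPs are always dropped on panel merging;
  no frequency-based strand inference is attempted.
- PCA projection shrinkage is uncorrected by design (see above).
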