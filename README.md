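# admixscan

Admixture deconvolution and genetic-differentiation scans for cohorts with
recent ancestry from several continents — the analysis design used for
populations such as North-Eastern Brazilians, whose genomes mix European,
Amerindian and African ancestry.  The package is aimed at statistical
geneticists who need to (1) estimate per-individual ancestry proportions Q
and per-component allele frequencies P from SNP-array dosages, with
present-day reference samples standing in as proxies for the unobserved
ancestral sources, and (2) rank SNPs by how strongly one ancestry's branch
has differentiated, as candidates for loci under selection.

## The model and statistics

Genotypes are diploid A1-allele dosages modeled as
`g_ij ~ Binomial(2, Σ_k q_ik p_kj)` over independent loci.  Fitting is by
EM, unsupervised or supervised (proxy samples' Q rows pinned to pure
indicator vectors); model order K is chosen by masked-cell cross-validation.
Proxy panels are selected by extremity on principal-component axes defined
solely by the admixed cohort (references are projected onto those axes),
with panel size chosen to minimize the bootstrap SE of the cohort-mean
ancestry.

Differentiation uses Hudson's Fst.  Parameter form
`F = (p1−p2)² / [p1(1−p2) + p2(1−p1)]` (0/0 → 0), or the sample-corrected
form whose numerator subtracts `p(1−p)/(n−1)` terms and may be negative per
locus.  Genome-wide values are ratios of averages `ΣN/ΣD` with percentile
locus-bootstrap CIs.  The per-SNP scan statistic is the locus-specific
branch length of a focal component (e.g. Amerindian) against the other two,

    LSBL = (F12 + F23 − F13) / 2        (focal population 2),

monotonically related to the population branch statistic obtained by first
transforming each Fst to `T = −log(1−Fst)`.  Top-ranked SNPs are grouped
into genome regions by 1-Mb single linkage.  `docs/methods.md` has the full
account, including the synthetic-cohort generator (Balding–Nichols drift +
Dirichlet ancestries) that makes every stage testable without external data.

## Worked example

```python
import numpy as np
from admixscan import (CohortSpec, make_study, fit_supervised,
                       scan_lsbl, top_regions)

# synthetic tri-ancestry cohort with known truth: 300 admixed samples,
# 2,000 SNPs, drift 0.15, 30 pure proxies per ancestry
spec = CohortSpec(n_snps=2000, n_admixed=300, n_proxy_pool=30, seed=7)
study = make_study(spec)
comb = study.combined()
assign = {s: lab for lab, pool in study.proxy_pools.items()
          for s in pool.samples}

fit = fit_supervised(comb, assign, seed=0, n_restarts=1)
print("mean ancestry:", dict(zip(fit.components,
      np.round(fit.Q[:300].mean(axis=0), 3))))
print("Q error vs truth:",
      round(float(np.abs(fit.Q[:300] - study.truth.Q[:300]).mean()), 4))

table = scan_lsbl(fit.P, comb.snps, focal=fit.components.index("amr"))
print("scan mean/median:", round(table.summary["mean"], 3),
      round(table.summary["median"], 3))
print("regions in top 10:", len(top_regions(table, k=10)))
```

Output:

```
mean ancestry: {'eur': np.float64(0.538), 'amr': np.float64(0.223), 'afr': np.float64(0.239)}
Q error vs truth: 0.0275
scan mean/median: 0.063 0.022
regions in top 10: 8
```

The recovered cohort-mean ancestry sits close to the generating Dirichlet
mean (0.57/0.20/0.23 — at 300 samples the realized cohort mean itself
wobbles by a few percent) and per-individual proportions are recovered to
~0.03 mean absolute error; with no injected outliers the top-10 scan hits
are just the tail of the background drift distribution and scatter across
the genome.

There is also a config-driven CLI over the same library —
`admixscan run --config config.yaml` executes qc → prune → pca → proxies →
admix → freqs → scan → report with a replayable manifest, and
`admixscan simulate` writes synthetic studies to disk.

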