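"""Synthetic admixed cohorts with known truth.

The generative model matches the inference model: per-locus ancestral
frequencies p_anc are drawn uniformly, each of K ancestral populations
drifts away from the shared ancestor under the Balding-Nichols model

    p_kj ~ Beta(p_anc (1 - F_k) / F_k, (1 - p_anc)(1 - F_k) / F_k),

which has mean p_anc and variance F_k p_anc (1 - p_anc); individual
ancestry vectors are Dirichlet; and genotypes are independent binomial
draws g_ij ~ Binomial(2, q_i . p_j).  Proxy-pool individuals are pure
single-ancestry by default, optionally contaminated with a Dirichlet
admixture fraction.  A handful of loci can be overwritten with a target
frequency in one ancestry to mimic strongly differentiated outliers.

Defaults emulate a tri-continentally admixed cohort whose mean ancestry is
57% European / 20% Amerindian / 23% African with broad individual ranges
(Dirichlet concentration 8), and continental-scale drift F = 0.15 per
ancestry.  All randomness flows from the single spec seed through spawned
``numpy`` SeedSequence children, so an identical spec reproduces an
identical study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotypes import GenotypeMatrix, SnpRecord

__all__ = [
    "CohortSpec",
    "SyntheticTruth",
    "StudyData",
    "sample_ancestral_freqs",
    "inject_differentiation",
    "sample_admixed_genotypes",
    "make_study",
    "sample_population_pair",
]

_DEFAULT_LABELS = ("eur", "amr", "afr")


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters of a synthetic admixed study."""

    K: int = 3
    n_snps: int = 1000
    drift: tuple[float, ...] = (0.15, 0.15, 0.15)
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    n_admixed: int = 500
    dirichlet_alpha: tuple[float, ...] = (8 * 0.57, 8 * 0.20, 8 * 0.23)
    n_proxy_pool: int = 50
    proxy_contamination: float = 0.0
    outliers: tuple[tuple[int, int, float], ...] = ()  # (locus, ancestry, target freq)
    missing_rate: float = 0.0
    labels: tuple[str, ...] = _DEFAULT_LABELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_snps < 1 or self.n_proxy_pool < 1:
            raise ValueError("counts must be >= 1")
        if len(self.drift) != self.K or len(self.dirichlet_alpha) != self.K:
            raise ValueError("drift and dirichlet_alpha must have length K")
        if len(self.labels) != self.K:
            raise ValueError("labels must have length K")
        if not all(0.0 < f < 1.0 for f in self.drift):
            raise ValueError("drift parameters must lie in (0, 1)")
        if not all(a > 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be positive")
        if not 0.0 <= self.proxy_contamination <= 0.5:
            raise ValueError("proxy_contamination must be in [0, 0.5]")


@dataclass(frozen=True)
class SyntheticTruth:
    Q: np.ndarray  # all samples (cohort then pools) x K
    P: np.ndarray  # K x n_snps, post-injection
    outliers: tuple[tuple[int, int, float], ...]
    spec: CohortSpec


@dataclass(frozen=True)
class StudyData:
    cohort: GenotypeMatrix
    proxy_pools: dict[str, GenotypeMatrix]
    truth: SyntheticTruth

    def combined(self) -> GenotypeMatrix:
        """Cohort plus all proxy-pool samples in one matrix."""
        mats = [self.cohort] + list(self.proxy_pools.values())
        samples = [s for m in mats for s in m.samples]
        dosage = np.vstack([m.dosage for m in mats])
        return GenotypeMatrix(samples, list(self.cohort.snps), dosage)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def sample_ancestral_freqs(spec: CohortSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Balding-Nichols component frequencies, K x n_snps."""
    if rng is None:
        rng = _rngs(spec.seed, 6)[0]
    low, high = spec.ancestral_freq_range
    p_anc = rng.uniform(low, high, size=spec.n_snps)
    P = np.empty((spec.K, spec.n_snps))
    for k, F in enumerate(spec.drift):
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        P[k] = rng.beta(a, b)
    return P


def inject_differentiation(
    P: np.ndarray, outliers: Sequence[tuple[int, int, float]]
) -> np.ndarray:
    """Overwrite one ancestry's frequency at chosen loci; returns a copy."""
    loci = [o[0] for o in outliers]
    if len(set(loci)) != len(loci):
        raise ValueError("duplicate locus in outlier list")
    P2 = np.array(P, copy=True)
    for locus, ancestry, target in outliers:
        if not 0 <= locus < P.shape[1]:
            raise ValueError(f"outlier locus {locus} out of range")
        P2[ancestry, locus] = target
    return P2


def sample_admixed_genotypes(
    P: np.ndarray,
    Q: np.ndarray,
    seed: int | np.random.Generator = 0,
    missing_rate: float = 0.0,
    sample_ids: Sequence[str] | None = None,
    snps: Sequence[SnpRecord] | None = None,
) -> GenotypeMatrix:
    """Binomial genotype draws g_ij ~ Bin(2, q_i . p_j)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    M = np.clip(Q @ P, 0.0, 1.0)
    dosage = rng.binomial(2, M).astype(float)
    if missing_rate > 0.0:
        dosage[rng.random(dosage.shape) < missing_rate] = np.nan
    n, m = dosage.shape
    if sample_ids is None:
        sample_ids = [f"s{i:05d}" for i in range(n)]
    if snps is None:
        snps = default_snp_map(m)
    return GenotypeMatrix(list(sample_ids), list(snps), dosage)


def default_snp_map(n_snps: int, n_chroms: int = 22, spacing_bp: int = 10_000) -> list[SnpRecord]:
    """Evenly spread synthetic SNPs over autosomes with fixed spacing."""
    snps = []
    per_chrom = -(-n_snps // n_chroms)  # ceil
    for j in range(n_snps):
        chrom = str(1 + j // per_chrom)
        offset = j % per_chrom
        snps.append(
            SnpRecord(
                id=f"snp{j:06d}",
                chromosome=chrom,
                position_bp=1 + offset * spacing_bp,
                allele_a1="A",
                allele_a2="G",
            )
        )
    return snps


def make_study(spec: CohortSpec) -> StudyData:
    """Draw a full study: admixed cohort, per-ancestry proxy pools, truth."""
    rng_p, rng_q, rng_proxy, rng_geno, rng_pool, rng_miss = _rngs(spec.seed, 6)

    P = sample_ancestral_freqs(spec, rng_p)
    P = inject_differentiation(P, spec.outliers)
    snps = default_snp_map(spec.n_snps)

    Q_cohort = (
        rng_q.dirichlet(spec.dirichlet_alpha, size=spec.n_admixed)
        if spec.n_admixed
        else np.zeros((0, spec.K))
    )
    cohort_ids = [f"BRZ{i:05d}" for i in range(spec.n_admixed)]
    cohort = sample_admixed_genotypes(
        P, Q_cohort, rng_geno, spec.missing_rate, cohort_ids, snps
    )

    pools: dict[str, GenotypeMatrix] = {}
    Q_pools = []
    c = spec.proxy_contamination
    for k, label in enumerate(spec.labels):
        indicator = np.zeros(spec.K)
        indicator[k] = 1.0
        Qp = (1.0 - c) * indicator + c * rng_proxy.dirichlet(
            spec.dirichlet_alpha, size=spec.n_proxy_pool
        )
        ids = [f"{label.upper()}{i:04d}" for i in range(spec.n_proxy_pool)]
        pools[label] = sample_admixed_genotypes(
            P, Qp, rng_pool, spec.missing_rate, ids, snps
        )
        Q_pools.append(Qp)
    Q_all = np.vstack([Q_cohort] + Q_pools)
    truth = SyntheticTruth(Q_all, P, spec.outliers, spec)
    return StudyData(cohort, pools, truth)


def sample_population_pair(
    F: float,
    n_snps: int,
    n_per_pop: int,
    seed: int = 0,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two pure populations drifted F from a shared ancestor.

    Returns ``(p1, p2, d1, d2)``: true per-locus frequencies and diploid
    dosage matrices (n_per_pop x n_snps) for each population.  Convenience
    for differentiation-estimator checks.
    """
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(*freq_range, size=n_snps)
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    p1 = rng.beta(a, b)
    p2 = rng.beta(a, b)
    d1 = rng.binomial(2, p1, size=(n_per_pop, n_snps)).astype(float)
    d2 = rng.binomial(2, p2, size=(n_per_pop, n_snps)).astype(float)
    return p1, p2, d1, d2
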