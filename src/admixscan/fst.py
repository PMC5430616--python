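"""Hudson Fst estimators, genome-wide aggregation, bootstrap CIs, LSBL and PBS.

Two forms of the pairwise statistic are provided.  The parameter form

    F = (p1 - p2)^2 / [p1 (1 - p2) + p2 (1 - p1)]

treats the two allele frequencies as known population parameters (with the
0/0 -> 0 convention when both frequencies are 0 or both are 1).  The
sample-corrected form subtracts the finite-sample variance of each frequency
estimate from the numerator,

    N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    D = p1 (1 - p2) + p2 (1 - p1),

with n the haploid sample counts; the per-locus ratio N/D may be negative
and is never truncated.  Genome-wide values aggregate as a ratio of averages,
sum(N)/sum(D), never as a mean of per-locus ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FstPairs",
    "BootstrapCi",
    "fst_param",
    "fst_sample",
    "fst_genomewide",
    "fst_bootstrap_ci",
    "lsbl",
    "pbs",
]


@dataclass(frozen=True)
class FstPairs:
    """Per-locus Hudson Fst numerators and denominators."""

    num: np.ndarray
    den: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "num", np.atleast_1d(np.asarray(self.num, float)))
        object.__setattr__(self, "den", np.atleast_1d(np.asarray(self.den, float)))
        if self.num.shape != self.den.shape:
            raise ValueError("numerator and denominator must have equal length")
        if np.any(self.den < 0):
            raise ValueError("denominators must be non-negative")

    @property
    def ratio(self) -> np.ndarray:
        """Per-locus N/D; NaN where D == 0.  May be negative."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.den > 0, self.num / np.where(self.den > 0, self.den, 1.0), np.nan)

    def __len__(self) -> int:
        return self.num.size


@dataclass(frozen=True)
class BootstrapCi:
    point: float
    lower: float
    upper: float
    alpha: float
    B: int
    seed: int

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("bootstrap CI has lower > upper")


def fst_param(p1, p2):
    """Parameter-form Hudson Fst between two allele frequencies.

    Vectorized; the denominator-zero case (both 0 or both 1) returns 0.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    num = (p1 - p2) ** 2
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def fst_sample(p1, n1, p2, n2) -> FstPairs:
    """Sample-corrected Hudson Fst components from frequencies and haploid counts."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("haploid sample counts must be >= 2")
    num = (
        (p1 - p2) ** 2
        - p1 * (1.0 - p1) / (n1 - 1.0)
        - p2 * (1.0 - p2) / (n2 - 1.0)
    )
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return FstPairs(num, den)


def fst_genomewide(pairs: FstPairs) -> float:
    """Ratio-of-averages genome-wide Fst: sum(N) / sum(D) over loci with D > 0."""
    ok = pairs.den > 0
    if not ok.any():
        raise ValueError("genome-wide Fst undefined: all denominators are zero")
    return float(pairs.num[ok].sum() / pairs.den[ok].sum())


def fst_bootstrap_ci(
    pairs: FstPairs,
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BootstrapCi:
    """Percentile bootstrap CI for the genome-wide Fst, resampling loci."""
    L = len(pairs)
    if L < 2:
        raise ValueError("bootstrap requires at least 2 loci")
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    chunk = max(1, min(B, 8_000_000 // max(L, 1)))
    for start in range(0, B, chunk):
        nb = min(chunk, B - start)
        idx = rng.integers(0, L, size=(nb, L))
        num = pairs.num[idx]
        den = pairs.den[idx]
        den_sum = np.where(den > 0, den, 0.0).sum(axis=1)
        num_sum = np.where(den > 0, num, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            reps[start : start + nb] = np.where(den_sum > 0, num_sum / np.maximum(den_sum, 1e-300), np.nan)
    reps = reps[~np.isnan(reps)]
    lower, upper = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapCi(fst_genomewide(pairs), float(lower), float(upper), alpha, B, seed)


def lsbl(f12, f23, f13):
    """Locus-specific branch length of population 2 against 1 and 3.

    (F12 + F23 - F13) / 2; may be negative when population 2 sits between
    the other two.
    """
    f12 = np.asarray(f12, dtype=float)
    f23 = np.asarray(f23, dtype=float)
    f13 = np.asarray(f13, dtype=float)
    out = (f12 + f23 - f13) / 2.0
    return float(out) if out.ndim == 0 else out


def pbs(f12, f23, f13):
    """Population branch statistic: the LSBL construction on the divergence
    time scale T = -log(1 - Fst)."""
    f12 = np.asarray(f12, dtype=float)
    f23 = np.asarray(f23, dtype=float)
    f13 = np.asarray(f13, dtype=float)
    if np.any(f12 >= 1) or np.any(f23 >= 1) or np.any(f13 >= 1):
        raise ValueError("PBS undefined for pairwise Fst >= 1 (infinite divergence)")
    t = lambda f: -np.log1p(-f)
    out = (t(f12) + t(f23) - t(f13)) / 2.0
    return float(out) if out.ndim == 0 else out
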