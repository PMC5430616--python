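"""Genotype data model, QC filters, allele frequencies, LD pruning and panel merging.

Dosages count copies of the A1 (first / reference) allele, matching the
``f(A1)`` convention of the differentiation tables produced by
:mod:`admixscan.scan`.  Missing genotypes are encoded as NaN and every
statistic uses complete-case (or pairwise-complete) handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SnpRecord",
    "GenotypeMatrix",
    "QcThresholds",
    "QcReport",
    "allele_freq",
    "filter_snps",
    "ld_r2",
    "ld_prune",
    "intersect_snps",
]

#: Strand-ambiguous allele pairs (indistinguishable after a strand flip).
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with 1-based physical coordinates.

    ``allele_a1`` is the counted (reference) allele; dosage d counts A1
    copies, so the A2 dosage is ``2 - d``.
    """

    id: str
    chromosome: str
    position_bp: int
    allele_a1: str
    allele_a2: str
    genetic_pos_cm: float | None = None

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"SNP {self.id}: position_bp must be >= 1")
        if self.allele_a1 == self.allele_a2:
            raise ValueError(f"SNP {self.id}: alleles A1 and A2 must differ")

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset((self.allele_a1.upper(), self.allele_a2.upper()))

    @property
    def is_strand_ambiguous(self) -> bool:
        return self.allele_set in _AMBIGUOUS_PAIRS


@dataclass
class GenotypeMatrix:
    """Samples x SNPs diploid A1-allele dosage matrix.

    dosage entries are in {0, 1, 2} or NaN (missing), stored as float64.
    """

    samples: list[str]
    snps: list[SnpRecord]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("SNP ids must be unique within a matrix")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique within a matrix")

    # ------------------------------------------------------------------ views
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def sample_indices(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def snp_indices(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s.id: i for i, s in enumerate(self.snps)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from None

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(ids)
        return GenotypeMatrix(list(ids), list(self.snps), self.dosage[idx, :].copy())

    def subset_snps(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.snp_indices(ids)
        return GenotypeMatrix(
            list(self.samples), [self.snps[i] for i in idx], self.dosage[:, idx].copy()
        )


@dataclass(frozen=True)
class QcThresholds:
    """SNP QC thresholds; defaults match call rate >= 99% and MAF >= 5%."""

    call_rate_min: float = 0.99
    maf_min: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.call_rate_min <= 1.0:
            raise ValueError("call_rate_min must be in [0, 1]")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")


@dataclass(frozen=True)
class QcReport:
    n_retained: int
    n_dropped: int
    dropped_ids: tuple[str, ...] = field(default=(), repr=False)


def allele_freq(
    gm: GenotypeMatrix, sample_subset: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP A1 allele frequency and haploid count over a sample subset.

    Returns ``(freq, n)`` where ``freq[j] = sum(dosage) / (2 * #non-missing)``
    and ``n[j] = 2 * #non-missing``.  SNPs with no non-missing genotype in
    the subset get ``freq = NaN`` and ``n = 0``.
    """
    if sample_subset is None:
        d = gm.dosage
    else:
        if len(list(sample_subset)) == 0:
            raise ValueError("sample subset must be non-empty")
        d = gm.dosage[gm.sample_indices(sample_subset), :]
    obs = ~np.isnan(d)
    n = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, np.nansum(d, axis=0) / np.maximum(n, 1), np.nan)
    return freq, n.astype(int)


def call_rate(gm: GenotypeMatrix) -> np.ndarray:
    """Fraction of samples with a non-missing genotype, per SNP."""
    return (~np.isnan(gm.dosage)).mean(axis=0)


def minor_allele_freq(gm: GenotypeMatrix) -> np.ndarray:
    freq, _ = allele_freq(gm)
    return np.minimum(freq, 1.0 - freq)


def filter_snps(
    gm: GenotypeMatrix, thr: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, QcReport]:
    """Retain SNPs passing both the call-rate and MAF filters."""
    cr = call_rate(gm)
    maf = minor_allele_freq(gm)
    # an all-missing SNP has undefined MAF; it can only survive a zero threshold
    maf_ok = np.where(np.isnan(maf), thr.maf_min == 0.0, maf >= thr.maf_min)
    keep = (cr >= thr.call_rate_min) & maf_ok
    kept_ids = [s.id for s, k in zip(gm.snps, keep) if k]
    dropped = tuple(s.id for s, k in zip(gm.snps, keep) if not k)
    out = GenotypeMatrix(
        list(gm.samples), [gm.snps[i] for i in np.flatnonzero(keep)], gm.dosage[:, keep].copy()
    )
    return out, QcReport(len(kept_ids), len(dropped), dropped)


def ld_r2(gm: GenotypeMatrix, snp_i: str, snp_j: str) -> float:
    """Squared Pearson correlation of dosages (composite LD, phase unknown).

    Computed over pairwise-complete samples; NaN when fewer than two complete
    pairs or either SNP has zero variance.
    """
    i, j = gm.snp_indices([snp_i, snp_j])
    return _r2_from_vectors(gm.dosage[:, i], gm.dosage[:, j])


def _r2_from_vectors(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    c = np.cov(xs, ys, ddof=0)[0, 1]
    return float(c * c / (vx * vy))


def ld_prune(
    gm: GenotypeMatrix,
    r2_max: float = 0.3,
    window_snps: int = 50,
    step_snps: int = 5,
) -> list[str]:
    """Greedy sliding-window LD thinning; returns retained SNP ids in map order.

    Within each window the pair of retained SNPs with the highest r-squared
    above ``r2_max`` is found and the lower-MAF member dropped (ties: the SNP
    later in map order is dropped), until no retained within-window pair
    exceeds the threshold.  SNPs must be sorted by (chromosome, position).
    """
    order = [(s.chromosome, s.position_bp) for s in gm.snps]
    by_chrom: dict[str, list[int]] = {}
    for idx, s in enumerate(gm.snps):
        by_chrom.setdefault(s.chromosome, []).append(idx)
    for chrom, idxs in by_chrom.items():
        pos = [order[i][1] for i in idxs]
        if pos != sorted(pos):
            raise ValueError(f"SNPs on chromosome {chrom} are not position-sorted")

    maf = minor_allele_freq(gm)
    removed = np.zeros(gm.n_snps, dtype=bool)
    for idxs in by_chrom.values():
        idxs = np.asarray(idxs)
        start = 0
        while start < len(idxs):
            window = idxs[start : start + window_snps]
            _prune_window(gm.dosage, window, removed, maf, r2_max)
            if start + window_snps >= len(idxs):
                break
            start += step_snps
    return [s.id for s, r in zip(gm.snps, removed) if not r]


def _prune_window(
    dosage: np.ndarray,
    window: np.ndarray,
    removed: np.ndarray,
    maf: np.ndarray,
    r2_max: float,
) -> None:
    while True:
        live = window[~removed[window]]
        if live.size < 2:
            return
        worst: tuple[float, int, int] | None = None
        for a_pos in range(live.size - 1):
            for b_pos in range(a_pos + 1, live.size):
                a, b = int(live[a_pos]), int(live[b_pos])
                r2 = _r2_from_vectors(dosage[:, a], dosage[:, b])
                if np.isnan(r2) or r2 <= r2_max:
                    continue
                if worst is None or r2 > worst[0]:
                    worst = (r2, a, b)
        if worst is None:
            return
        _, a, b = worst
        if maf[a] < maf[b]:
            removed[a] = True
        elif maf[b] < maf[a]:
            removed[b] = True
        else:  # equal MAF: drop the later one in map order
            removed[max(a, b)] = True


def intersect_snps(
    gm_a: GenotypeMatrix, gm_b: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict two matrices to shared SNPs with a reconciled allele orientation.

    SNPs are matched on id plus allele pair (order-insensitive).  When A1/A2
    are swapped between the two panels, the second panel's dosages are flipped
    (d -> 2 - d) so both outputs count the same allele.  Strand-ambiguous A/T
    and C/G SNPs are dropped, as are SNPs with irreconcilable allele pairs
    (with a warning).
    """
    b_lookup = {s.id: i for i, s in enumerate(gm_b.snps)}
    keep_a: list[int] = []
    keep_b: list[int] = []
    flip: list[bool] = []
    for ia, rec_a in enumerate(gm_a.snps):
        ib = b_lookup.get(rec_a.id)
        if ib is None:
            continue
        rec_b = gm_b.snps[ib]
        if rec_a.is_strand_ambiguous or rec_b.is_strand_ambiguous:
            continue
        if rec_a.allele_set != rec_b.allele_set:
            warnings.warn(
                f"SNP {rec_a.id}: irreconcilable allele pairs "
                f"({rec_a.allele_a1}/{rec_a.allele_a2} vs "
                f"{rec_b.allele_a1}/{rec_b.allele_a2}); dropped"
            )
            continue
        keep_a.append(ia)
        keep_b.append(ib)
        flip.append(rec_a.allele_a1.upper() != rec_b.allele_a1.upper())

    snps = [gm_a.snps[i] for i in keep_a]
    da = gm_a.dosage[:, keep_a].copy()
    db = gm_b.dosage[:, keep_b].copy()
    flip_arr = np.asarray(flip, dtype=bool)
    if flip_arr.any():
        db[:, flip_arr] = 2.0 - db[:, flip_arr]
    out_a = GenotypeMatrix(list(gm_a.samples), snps, da)
    out_b = GenotypeMatrix(list(gm_b.samples), list(snps), db)
    return out_a, out_b
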