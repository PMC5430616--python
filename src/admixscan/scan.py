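"""Genome scans for differentiated loci: LSBL and pairwise Fst ranking,
region grouping, Hotelling ancestry-mean tests and TREEMIX count export.

The locus-specific branch length (LSBL) scan scores each SNP by the branch
length of a focal ancestry component against the other two, i.e. the
differentiation of that component from a hypothetical common ancestral
population of all three.  The pairwise scan scores direct Fst between a
focal component and a comparison population.  Both are ranking exercises:
SNPs are ordered by the statistic and the top hits grouped into genome
regions by single-linkage merging of nearby positions.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fst import fst_param, fst_sample, lsbl
from .genotypes import SnpRecord

__all__ = [
    "DifferentiationTable",
    "Region",
    "scan_lsbl",
    "scan_pairwise",
    "top_regions",
    "hotelling_two_sample",
    "HotellingResult",
    "treemix_counts",
    "write_treemix",
]


@dataclass
class DifferentiationTable:
    """Per-SNP differentiation statistics with ranks, plus scan summaries."""

    table: pd.DataFrame  # columns: id chrom pos a1 a2 f_* fst_* stat rank
    statistic: str  # "lsbl" | "fst"
    summary: dict[str, float]  # mean / median / p75 of the statistic

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Region:
    region_id: int
    chromosome: str
    start_bp: int
    end_bp: int
    snp_ids: tuple[str, ...]
    max_stat: float


def _snp_columns(snps: Sequence[SnpRecord]) -> dict[str, list]:
    return {
        "id": [s.id for s in snps],
        "chrom": [s.chromosome for s in snps],
        "pos": [s.position_bp for s in snps],
        "a1": [s.allele_a1 for s in snps],
        "a2": [s.allele_a2 for s in snps],
    }


def _rank_and_summarize(df: pd.DataFrame, statistic: str) -> DifferentiationTable:
    # descending statistic; ties broken by (chromosome, position)
    order = df.sort_values(
        ["stat", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    ).index
    ranks = pd.Series(np.arange(1, len(df) + 1), index=order)
    df = df.assign(rank=ranks)
    stat = df["stat"].to_numpy()
    summary = {
        "mean": float(np.nanmean(stat)),
        "median": float(np.nanmedian(stat)),
        "p75": float(np.nanpercentile(stat, 75)),
    }
    return DifferentiationTable(df, statistic, summary)


def scan_lsbl(
    P: np.ndarray,
    snps: Sequence[SnpRecord],
    focal: int = 1,
    component_names: Sequence[str] = ("eur", "amr", "afr"),
) -> DifferentiationTable:
    """LSBL scan over component allele frequencies.

    ``P`` is components x SNPs (three rows); ``focal`` indexes the branch
    of interest.  Per SNP the three parameter-form pairwise Fst values are
    computed and combined as (F(f,a) + F(f,b) - F(a,b)) / 2 for focal f.
    """
    P = np.asarray(P, float)
    if P.shape[0] != 3:
        raise ValueError("LSBL scan needs exactly three components")
    others = [k for k in range(3) if k != focal]
    a, b = others
    f_fa = fst_param(P[focal], P[a])
    f_fb = fst_param(P[focal], P[b])
    f_ab = fst_param(P[a], P[b])
    stat = lsbl(f_fa, f_fb, f_ab)
    cols = _snp_columns(snps)
    for k, name in enumerate(component_names):
        cols[f"f_{name}"] = P[k]
    df = pd.DataFrame(cols)
    df[f"fst_{component_names[focal]}_{component_names[a]}"] = f_fa
    df[f"fst_{component_names[focal]}_{component_names[b]}"] = f_fb
    df[f"fst_{component_names[a]}_{component_names[b]}"] = f_ab
    df["stat"] = stat
    return _rank_and_summarize(df, "lsbl")


def scan_pairwise(
    p_focal: np.ndarray,
    p_comp: np.ndarray,
    snps: Sequence[SnpRecord],
    mode: str = "param",
    n_focal: np.ndarray | None = None,
    n_comp: np.ndarray | None = None,
    focal_name: str = "amr",
    comp_name: str = "comp",
) -> DifferentiationTable:
    """Direct pairwise Fst scan of a focal component against a population.

    ``mode='param'`` uses the parameter form; ``mode='sample'`` uses the
    finite-sample-corrected form and requires haploid counts for both sides
    (per-locus values may then be negative).
    """
    p_focal = np.asarray(p_focal, float)
    p_comp = np.asarray(p_comp, float)
    if mode == "param":
        stat = fst_param(p_focal, p_comp)
    elif mode == "sample":
        if n_focal is None or n_comp is None:
            raise ValueError("mode='sample' requires haploid counts for both sides")
        stat = fst_sample(p_focal, n_focal, p_comp, n_comp).ratio
    else:
        raise ValueError("mode must be 'param' or 'sample'")
    cols = _snp_columns(snps)
    cols[f"f_{focal_name}"] = p_focal
    cols[f"f_{comp_name}"] = p_comp
    df = pd.DataFrame(cols)
    df["stat"] = stat
    return _rank_and_summarize(df, "fst")


def top_regions(
    table: DifferentiationTable, k: int = 10, merge_bp: int = 1_000_000
) -> list[Region]:
    """Group the top-k ranked SNPs into genome regions.

    SNPs on the same chromosome merge into one region when within
    ``merge_bp`` of the group's nearest member (single linkage).  Regions
    are numbered by their best SNP's rank.
    """
    top = table.table.nsmallest(k, "rank").sort_values(["chrom", "pos"])
    groups: list[list[pd.Series]] = []
    for _, row in top.iterrows():
        placed = False
        for grp in groups:
            if grp[0]["chrom"] != row["chrom"]:
                continue
            if min(abs(row["pos"] - m["pos"]) for m in grp) <= merge_bp:
                grp.append(row)
                placed = True
                break
        if not placed:
            groups.append([row])
    groups.sort(key=lambda grp: min(m["rank"] for m in grp))
    return [
        Region(
            region_id=i + 1,
            chromosome=str(grp[0]["chrom"]),
            start_bp=int(min(m["pos"] for m in grp)),
            end_bp=int(max(m["pos"] for m in grp)),
            snp_ids=tuple(m["id"] for m in sorted(grp, key=lambda m: m["pos"])),
            max_stat=float(max(m["stat"] for m in grp)),
        )
        for i, grp in enumerate(groups)
    ]


def regions_to_bed(regions: Sequence[Region]) -> pd.DataFrame:
    """0-based half-open BED intervals for a region list."""
    return pd.DataFrame(
        {
            "chrom": [r.chromosome for r in regions],
            "start": [r.start_bp - 1 for r in regions],
            "end": [r.end_bp for r in regions],
            "name": [f"region_{r.region_id}" for r in regions],
            "score": [r.max_stat for r in regions],
        }
    )


# ----------------------------------------------------------------- Hotelling


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float


def hotelling_two_sample(
    Q_a: np.ndarray, Q_b: np.ndarray, components: tuple[int, int] = (0, 1)
) -> HotellingResult:
    """Two-sample Hotelling T-squared on two ancestry components.

    Only two of the three components are compared: the third is determined
    by the simplex constraint and would make the covariance singular.
    """
    Xa = np.asarray(Q_a, float)[:, list(components)]
    Xb = np.asarray(Q_b, float)[:, list(components)]
    n1, n2 = len(Xa), len(Xb)
    if n1 < 3 or n2 < 3:
        raise ValueError("each group needs at least 3 samples")
    p = 2
    diff = Xa.mean(axis=0) - Xb.mean(axis=0)
    S = ((n1 - 1) * np.cov(Xa, rowvar=False) + (n2 - 1) * np.cov(Xb, rowvar=False)) / (
        n1 + n2 - 2
    )
    try:
        solve = np.linalg.solve(S, diff)
    except np.linalg.LinAlgError:
        raise ValueError(
            "pooled covariance is singular; choose a different component pair"
        ) from None
    t2 = float(n1 * n2 / (n1 + n2) * diff @ solve)
    f_stat = t2 * (n1 + n2 - p - 1) / ((n1 + n2 - 2) * p)
    df = (p, n1 + n2 - p - 1)
    p_value = float(stats.f.sf(f_stat, *df))
    return HotellingResult(t2, f_stat, df, p_value)


# ------------------------------------------------------------------- TREEMIX


def treemix_counts(
    q_bar: float,
    p: np.ndarray,
    n_samples: int,
    literal: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer (A1, A2) allele counts for an admixture component.

    The effective haploid total is H = round(2 * n_samples * q_bar) — the
    number of haploid genomes attributable to the component — and A1 counts
    are round(H * p).  ``literal=True`` instead uses the bare product
    2 * q_bar * p without the sample count (which caps counts at 2).
    """
    if not 0.0 < q_bar <= 1.0:
        raise ValueError("q_bar must be in (0, 1]")
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")

    def _round_half_up(x):
        return np.floor(np.asarray(x) + 0.5).astype(int)

    if literal:
        a1 = _round_half_up(2.0 * q_bar * p)
        a2 = _round_half_up(2.0 * q_bar * (1.0 - p))
        return a1, a2
    H = int(np.floor(2.0 * n_samples * q_bar + 0.5))
    a1 = _round_half_up(H * p)
    return a1, H - a1


def write_treemix(path: str | Path, counts: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> None:
    """Write the gzipped TREEMIX count format: pop header, per-SNP 'a,b' pairs."""
    pops = list(counts)
    lengths = {len(counts[p][0]) for p in pops} | {len(counts[p][1]) for p in pops}
    if len(lengths) != 1:
        raise ValueError("all populations must have counts for the same SNPs")
    (n_snps,) = lengths
    with gzip.open(path, "wt") as fh:
        fh.write(" ".join(pops) + "\n")
        for j in range(n_snps):
            fh.write(
                " ".join(f"{int(counts[p][0][j])},{int(counts[p][1][j])}" for p in pops)
                + "\n"
            )
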