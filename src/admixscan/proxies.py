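"""Supervising proxy panels chosen by extremity on projected PCA axes.

Reference samples standing in for an unobserved ancestral source are ranked
by their coordinate on a principal-component axis (most extreme first) and
the top N(proxy) form the panel, with equal panel sizes across ancestries.
The panel size is chosen by the bootstrap standard error of the cohort-mean
ancestry proportions: panels grow until adding less-extreme (more admixed)
samples stops reducing, and eventually inflates, the SE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .admixture import _em, _init_qp
from .genotypes import GenotypeMatrix

__all__ = ["ProxyPanel", "ProxySizeCurve", "rank_by_pc", "select_proxies", "proxy_size_curve"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProxyPanel:
    ancestry: str
    sample_ids: tuple[str, ...]  # most extreme first
    pc_index: int
    direction: str  # "min" | "max"

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"panel {self.ancestry}: duplicate sample ids")

    @property
    def n_selected(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class ProxySizeCurve:
    n_values: list[int]
    se_mean: list[float]  # mean over per-component SEs
    se_components: np.ndarray  # len(n_values) x K
    B: int
    seed: int

    @property
    def argmin_n(self) -> int:
        return self.n_values[int(np.argmin(self.se_mean))]


def rank_by_pc(
    scores: pd.DataFrame, pc_index: int, direction: str = "min"
) -> list[str]:
    """Sample ids ordered by signed PC coordinate, most extreme first.

    ``pc_index`` is 1-based (PC1, PC2, ...).  Ties break by lexicographic
    sample id for determinism.
    """
    col = f"PC{pc_index}"
    if col not in scores.columns:
        raise KeyError(f"scores have no component {col}")
    if direction not in {"min", "max"}:
        raise ValueError("direction must be 'min' or 'max'")
    sign = 1.0 if direction == "min" else -1.0
    order = sorted(scores.index, key=lambda s: (sign * scores.at[s, col], s))
    return list(order)


def select_proxies(
    rankings: Mapping[str, Sequence[str]], n_proxy: int,
    pc_info: Mapping[str, tuple[int, str]] | None = None,
) -> list[ProxyPanel]:
    """Equal-size panels from per-ancestry rankings, one panel per ancestry.

    A sample appearing in several rankings is claimed by the pole where its
    rank is more extreme (smaller rank index wins; ties go to the ancestry
    listed first).  Raises if any ancestry cannot fill its panel.
    """
    labels = list(rankings)
    claimed: set[str] = set()
    panels: dict[str, list[str]] = {lab: [] for lab in labels}
    cursors = {lab: 0 for lab in labels}
    progressed = True
    while progressed and any(len(panels[lab]) < n_proxy for lab in labels):
        progressed = False
        for lab in labels:  # round-robin by rank index: extreme ranks claim first
            if len(panels[lab]) >= n_proxy:
                continue
            ranking = rankings[lab]
            while cursors[lab] < len(ranking) and len(panels[lab]) < n_proxy:
                candidate = ranking[cursors[lab]]
                cursors[lab] += 1
                progressed = True
                if candidate not in claimed:
                    claimed.add(candidate)
                    panels[lab].append(candidate)
                    break
    for lab in labels:
        if len(panels[lab]) < n_proxy:
            raise ValueError(
                f"ancestry {lab!r}: only {len(panels[lab])} of {n_proxy} "
                "proxy candidates available"
            )
    out = []
    for lab in labels:
        pc, direction = (pc_info or {}).get(lab, (0, "min"))
        out.append(ProxyPanel(lab, tuple(panels[lab]), pc, direction))
    return out


def proxy_size_curve(
    gm: GenotypeMatrix,
    rankings: Mapping[str, Sequence[str]],
    n_candidates: Sequence[int],
    B: int = 100,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 500,
) -> ProxySizeCurve:
    """Bootstrap SE of cohort-mean ancestry as a function of panel size.

    For each candidate size n, panels are selected, then B locus-resampling
    bootstrap replicates of the supervised fit are run and the per-component
    standard deviation of the cohort-mean ancestry vector recorded.  The EM
    tolerance is relaxed inside replicates for speed.  Replicates whose fit
    fails to converge are dropped (error if more than 10% drop).
    """
    if B < 50:
        raise ValueError("B must be >= 50 for a stable SE estimate")
    labels = list(rankings)
    K = len(labels)
    ref_samples = {s for r in rankings.values() for s in r}
    cohort_idx = np.array([i for i, s in enumerate(gm.samples) if s not in ref_samples])
    if cohort_idx.size == 0:
        raise ValueError("no cohort samples left after excluding proxy candidates")

    ss = np.random.SeedSequence(seed)
    se_mean: list[float] = []
    se_comp_rows: list[np.ndarray] = []
    for n, child in zip(n_candidates, ss.spawn(len(n_candidates))):
        panels = select_proxies(rankings, n)
        proxy_ids = [s for p in panels for s in p.sample_ids]
        proxy_anc = {s: p.ancestry for p in panels for s in p.sample_ids}
        used = [gm.samples[i] for i in cohort_idx] + proxy_ids
        sub = gm.subset_samples(used)
        G = sub.dosage
        fixed_rows = sub.sample_indices(proxy_ids)
        fixed_Q = np.zeros((len(proxy_ids), K))
        for r, sid in enumerate(proxy_ids):
            fixed_Q[r, labels.index(proxy_anc[sid])] = 1.0
        coh = sub.sample_indices([gm.samples[i] for i in cohort_idx])

        rng = np.random.default_rng(child)
        means = []
        dropped = 0
        for _ in range(B):
            loci = rng.integers(0, G.shape[1], size=G.shape[1])
            Gb = G[:, loci]
            Q0, P0 = _init_qp(Gb, K, rng, fixed_rows, fixed_Q)
            Q, _, _, _, converged, _ = _em(
                Gb, Q0, P0, fixed_rows, fixed_Q, tol, max_iter
            )
            if not converged:
                dropped += 1
                logger.warning("proxy_size_curve: dropping non-convergent replicate")
                continue
            means.append(Q[coh].mean(axis=0))
        if dropped > 0.1 * B:
            raise ValueError(f"n={n}: {dropped}/{B} bootstrap replicates failed to converge")
        arr = np.asarray(means)
        se_k = arr.std(axis=0, ddof=1)
        se_comp_rows.append(se_k)
        se_mean.append(float(se_k.mean()))
    return ProxySizeCurve(list(n_candidates), se_mean, np.asarray(se_comp_rows), B, seed)
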