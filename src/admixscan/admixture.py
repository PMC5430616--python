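"""Maximum-likelihood admixture decomposition under the binomial model.

Genotypes are modeled as g_ij ~ Binomial(2, m_ij) with mixture frequency
m_ij = sum_k q_ik p_kj, where Q holds per-individual ancestry proportions
over K components and P the per-component A1 allele frequencies.  The
log-likelihood (dropping the genotype-independent binomial coefficient) is

    l(Q, P) = sum_ij [ g_ij ln m_ij + (2 - g_ij) ln(1 - m_ij) ]

over non-missing genotypes.  Fitting is by plain EM on the allele-copy
complete data; the supervised mode fixes the Q rows of designated proxy
samples to pure single-ancestry indicator vectors throughout optimization.
Model order K is chosen by masked-cell cross-validation: held-out genotype
cells are predicted as 2 * m_ij and scored by squared error.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = [
    "AdmixtureFit",
    "CvResult",
    "loglik",
    "fit_unsupervised",
    "fit_supervised",
    "component_freqs_given_Q",
    "cross_validate",
    "match_components",
]

#: Boundary clamp on component frequencies; keeps ln(1 - m) and ln(m) finite.
EPS = 1e-6


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # samples x K, rows on the simplex
    P: np.ndarray  # K x SNPs, entries in [EPS, 1 - EPS]
    loglik: float
    n_iter: int
    converged: bool
    mode: str  # "supervised" | "unsupervised"
    seed: int
    samples: list[str]
    components: list[str]
    loglik_trace: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))

    def q_frame(self):
        import pandas as pd

        return pd.DataFrame(self.Q, index=self.samples, columns=self.components)


@dataclass(frozen=True)
class CvResult:
    K_values: list[int]
    cv_error: list[float]
    folds: int
    seed: int

    @property
    def best_K(self) -> int:
        return self.K_values[int(np.argmin(self.cv_error))]


# ----------------------------------------------------------------- likelihood


def _as_arrays(gm: GenotypeMatrix | np.ndarray) -> np.ndarray:
    return gm.dosage if isinstance(gm, GenotypeMatrix) else np.asarray(gm, float)


def loglik(gm: GenotypeMatrix | np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    """Binomial log-likelihood of (Q, P); missing genotypes contribute zero."""
    G = _as_arrays(gm)
    Q = np.asarray(Q, float)
    P = np.asarray(P, float)
    if Q.shape[0] != G.shape[0] or P.shape[1] != G.shape[1] or Q.shape[1] != P.shape[0]:
        raise ValueError("dimension mismatch among genotypes, Q and P")
    W = ~np.isnan(G)
    Gf = np.where(W, G, 0.0)
    M = np.clip(Q @ P, EPS, 1.0 - EPS)
    return float(np.sum(Gf * np.log(M) + np.where(W, 2.0 - Gf, 0.0) * np.log1p(-M)))


# ------------------------------------------------------------------------ EM


def _em(
    G: np.ndarray,
    Q: np.ndarray,
    P: np.ndarray,
    fixed_rows: np.ndarray | None,
    fixed_Q: np.ndarray | None,
    tol: float,
    max_iter: int,
    update_q: bool = True,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, np.ndarray]:
    W = ~np.isnan(G)
    Gf = np.where(W, G, 0.0)
    G2f = np.where(W, 2.0 - G, 0.0)
    trace = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M = np.clip(Q @ P, EPS, 1.0 - EPS)
        A = Gf / M  # g / m, zero where missing
        B = G2f / (1.0 - M)  # (2 - g) / (1 - m), zero where missing
        ll = float(np.sum(Gf * np.log(M) + G2f * np.log1p(-M)))
        trace.append(ll)
        if it > 1 and abs(ll - ll_prev) < tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll
        if update_q:
            Qn = Q * (A @ P.T + B @ (1.0 - P).T)
            denom = Qn.sum(axis=1, keepdims=True)
            Qn = np.where(denom > 0, Qn / np.maximum(denom, 1e-300), 1.0 / Q.shape[1])
            if fixed_rows is not None:
                Qn[fixed_rows] = fixed_Q
        else:
            Qn = Q
        a = P * (Q.T @ A)
        b = (1.0 - P) * (Q.T @ B)
        with np.errstate(invalid="ignore", divide="ignore"):
            Pn = np.where(a + b > 0, a / np.maximum(a + b, 1e-300), P)
        Q = Qn
        P = np.clip(Pn, EPS, 1.0 - EPS)
    return Q, P, trace[-1], it, converged, np.asarray(trace)


def _init_qp(
    G: np.ndarray,
    K: int,
    rng: np.random.Generator,
    fixed_rows: np.ndarray | None,
    fixed_Q: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    n, m = G.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    if fixed_rows is not None:
        Q[fixed_rows] = fixed_Q
    obs = ~np.isnan(G)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(G, axis=0) / np.maximum(2 * obs.sum(axis=0), 1)
    p = np.where(obs.any(axis=0), p, 0.5)
    P = np.clip(p + rng.normal(0.0, 0.05, size=(K, m)), EPS, 1.0 - EPS)
    return Q, P


def fit_unsupervised(
    gm: GenotypeMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 2000,
    n_restarts: int = 3,
    sample_ids: Sequence[str] | None = None,
) -> AdmixtureFit:
    """EM fit with free Q and P; best of ``n_restarts`` random starts.

    Components are relabeled by descending mean ancestry proportion.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    G = _as_arrays(gm)
    if np.isnan(G).all(axis=0).any():
        raise ValueError("input contains an all-missing SNP")
    samples = (
        list(gm.samples) if isinstance(gm, GenotypeMatrix)
        else list(sample_ids) if sample_ids is not None
        else [f"s{i}" for i in range(G.shape[0])]
    )
    best = None
    for child_seed in np.random.SeedSequence(seed).generate_state(n_restarts):
        rng = np.random.default_rng(child_seed)
        Q0, P0 = _init_qp(G, K, rng, None, None)
        result = _em(G, Q0, P0, None, None, tol, max_iter)
        if best is None or result[2] > best[2]:
            best = result
    Q, P, ll, n_iter, converged, trace = best
    if not converged:
        warnings.warn("admixture EM did not converge within max_iter")
    order = np.argsort(-Q.mean(axis=0), kind="stable")
    Q = Q[:, order]
    P = P[order, :]
    return AdmixtureFit(
        K=K, Q=Q, P=P, loglik=ll, n_iter=n_iter, converged=converged,
        mode="unsupervised", seed=seed, samples=samples,
        components=[f"K{i+1}" for i in range(K)], loglik_trace=trace,
    )


def fit_supervised(
    gm: GenotypeMatrix,
    proxy_assignment: Mapping[str, str],
    K: int | None = None,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 2000,
    n_restarts: int = 3,
) -> AdmixtureFit:
    """EM fit with proxy samples' Q rows pinned to their ancestry indicators.

    ``proxy_assignment`` maps sample id -> ancestry label; the component
    order follows first appearance of the labels.  Unequal panel sizes are
    tolerated with a warning (they bias the likelihood weighting).
    """
    labels = list(dict.fromkeys(proxy_assignment.values()))
    if K is None:
        K = len(labels)
    if K != len(labels):
        raise ValueError(f"K={K} but proxy assignment names {len(labels)} ancestries")
    counts = {lab: sum(1 for v in proxy_assignment.values() if v == lab) for lab in labels}
    if any(c == 0 for c in counts.values()):
        raise ValueError("every ancestry needs at least one proxy sample")
    if len(set(counts.values())) > 1:
        warnings.warn(f"unequal proxy panel sizes {counts}; estimates may be biased")
    missing = [s for s in proxy_assignment if s not in set(gm.samples)]
    if missing:
        raise ValueError(f"proxy samples absent from matrix: {missing[:5]}")

    G = gm.dosage
    fixed_rows = gm.sample_indices(list(proxy_assignment))
    fixed_Q = np.zeros((len(fixed_rows), K))
    for r, sid in enumerate(proxy_assignment):
        fixed_Q[r, labels.index(proxy_assignment[sid])] = 1.0

    best = None
    for child_seed in np.random.SeedSequence(seed).generate_state(n_restarts):
        rng = np.random.default_rng(child_seed)
        Q0, P0 = _init_qp(G, K, rng, fixed_rows, fixed_Q)
        result = _em(G, Q0, P0, fixed_rows, fixed_Q, tol, max_iter)
        if best is None or result[2] > best[2]:
            best = result
    Q, P, ll, n_iter, converged, trace = best
    if not converged:
        warnings.warn("admixture EM did not converge within max_iter")
    return AdmixtureFit(
        K=K, Q=Q, P=P, loglik=ll, n_iter=n_iter, converged=converged,
        mode="supervised", seed=seed, samples=list(gm.samples),
        components=labels, loglik_trace=trace,
    )


def component_freqs_given_Q(
    gm: GenotypeMatrix | np.ndarray,
    Q: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> np.ndarray:
    """Per-SNP ML component frequencies with the ancestry matrix held fixed.

    Loci are independent given Q, so this extends a fit's P to SNPs that were
    not used during fitting (e.g. the full pre-pruning panel).  SNPs with all
    genotypes missing return NaN for every component.
    """
    G = _as_arrays(gm)
    Q = np.asarray(Q, float)
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-6) or (Q < -1e-9).any():
        raise ValueError("Q rows must be ancestry proportions on the simplex")
    K, m = Q.shape[1], G.shape[1]
    W = ~np.isnan(G)
    Gf = np.where(W, G, 0.0)
    G2f = np.where(W, 2.0 - G, 0.0)
    P = np.full((K, m), 0.5)
    for _ in range(max_iter):
        M = np.clip(Q @ P, EPS, 1.0 - EPS)
        a = P * (Q.T @ (Gf / M))
        b = (1.0 - P) * (Q.T @ (G2f / (1.0 - M)))
        with np.errstate(invalid="ignore", divide="ignore"):
            Pn = np.where(a + b > 0, a / np.maximum(a + b, 1e-300), P)
        Pn = np.clip(Pn, EPS, 1.0 - EPS)
        delta = np.max(np.abs(Pn - P))
        P = Pn
        if delta < tol:
            break
    all_missing = np.isnan(G).all(axis=0)
    P[:, all_missing] = np.nan
    return P


def cross_validate(
    gm: GenotypeMatrix | np.ndarray,
    K_values: Sequence[int],
    folds: int = 10,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 2000,
    n_restarts: int = 1,
) -> CvResult:
    """Masked-cell cross-validation error per K.

    Non-missing genotype cells are partitioned into ``folds`` folds; each
    fold is masked in turn, the model refit, and the masked cells predicted
    as 2 * m_ij; the error is the mean squared difference pooled over folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    G = _as_arrays(gm).copy()
    cells = np.argwhere(~np.isnan(G))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cells))
    fold_of = np.empty(len(cells), dtype=int)
    fold_of[perm] = np.arange(len(cells)) % folds
    errors = []
    for K in K_values:
        sq_sum = 0.0
        n_cells = 0
        for f in range(folds):
            mask = cells[fold_of == f]
            Gm = G.copy()
            Gm[mask[:, 0], mask[:, 1]] = np.nan
            # guard: a fully masked SNP column cannot be fit
            dead = np.isnan(Gm).all(axis=0)
            if dead.any():
                keep_cells = ~dead[mask[:, 1]]
                Gm[:, dead] = G[:, dead]
                mask = mask[keep_cells]
            fit = fit_unsupervised(
                Gm, K, seed=int(rng.integers(2**31 - 1)), tol=tol,
                max_iter=max_iter, n_restarts=n_restarts,
            )
            pred = 2.0 * np.einsum("ik,ki->i", fit.Q[mask[:, 0]], fit.P[:, mask[:, 1]])
            sq_sum += float(((G[mask[:, 0], mask[:, 1]] - pred) ** 2).sum())
            n_cells += len(mask)
        errors.append(sq_sum / n_cells)
    return CvResult(list(K_values), errors, folds, seed)


def match_components(
    Q_est: np.ndarray, Q_true: np.ndarray
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Permute estimated components to best match a truth matrix (min MAE)."""
    K = Q_true.shape[1]
    best_perm = None
    best_err = np.inf
    for perm in itertools.permutations(range(K)):
        err = float(np.abs(Q_est[:, perm] - Q_true).mean())
        if err < best_err:
            best_err = err
            best_perm = perm
    return Q_est[:, best_perm], best_perm
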