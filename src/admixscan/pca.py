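"""PCA whose axes are defined by a chosen sample subset, with projection.

The axes of variation are computed from a designated set of defining samples
only (e.g. the admixed study cohort); reference samples are then *projected*
onto those axes.  This keeps the components ranked by variation within the
cohort rather than by variation among the references.  Standardization is
Patterson-style: per-SNP centering at the mean dosage 2p of the defining set
and scaling by sqrt(2p(1-p)).  Out-of-sample projections are not corrected
for shrinkage toward zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["PcaModel", "standardize", "pca_fit", "pca_project"]


@dataclass
class PcaModel:
    snp_ids: list[str]
    snp_means: np.ndarray  # 2 * p-hat of defining samples
    snp_scales: np.ndarray  # sqrt(2 p (1 - p))
    loadings: np.ndarray  # SNPs x n_components, orthonormal columns
    eigenvalues: np.ndarray  # per-component variance, non-increasing

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def save(self, path: str | Path) -> None:
        """JSON metadata plus a .npy binary loadings sidecar."""
        path = Path(path)
        sidecar = path.with_suffix(".loadings.npy")
        np.save(sidecar, self.loadings)
        meta = {
            "snp_ids": self.snp_ids,
            "snp_means": self.snp_means.tolist(),
            "snp_scales": self.snp_scales.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "loadings_file": sidecar.name,
        }
        path.write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "PcaModel":
        path = Path(path)
        meta = json.loads(path.read_text())
        loadings = np.load(path.parent / meta["loadings_file"])
        return cls(
            snp_ids=list(meta["snp_ids"]),
            snp_means=np.asarray(meta["snp_means"]),
            snp_scales=np.asarray(meta["snp_scales"]),
            loadings=loadings,
            eigenvalues=np.asarray(meta["eigenvalues"]),
        )


def standardize(
    gm: GenotypeMatrix, defining_samples: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Center/scale dosages by the defining-sample allele frequencies.

    Returns ``(X, means, scales, kept_snp_ids)`` for the defining samples;
    SNPs monomorphic (or all-missing) in the defining set are excluded and
    missing dosages impute to 0 after centering.
    """
    if len(defining_samples) < 2:
        raise ValueError("standardization requires at least 2 defining samples")
    idx = gm.sample_indices(defining_samples)
    d = gm.dosage[idx, :]
    obs = ~np.isnan(d)
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(d, axis=0) / np.maximum(2 * n, 1)
    keep = (n > 0) & (p > 0.0) & (p < 1.0)
    p = p[keep]
    means = 2.0 * p
    scales = np.sqrt(2.0 * p * (1.0 - p))
    X = (d[:, keep] - means) / scales
    X[np.isnan(X)] = 0.0
    kept_ids = [s.id for s, k in zip(gm.snps, keep) if k]
    return X, means, scales, kept_ids


def pca_fit(
    gm: GenotypeMatrix,
    defining_samples: Sequence[str],
    n_components: int,
) -> tuple[PcaModel, pd.DataFrame]:
    """Fit axes from the defining samples; returns the model and their scores."""
    X, means, scales, kept_ids = standardize(gm, defining_samples)
    n = X.shape[0]
    if n_components > min(n - 1, X.shape[1]):
        raise ValueError(
            f"n_components={n_components} exceeds min(#defining-1, #SNPs)="
            f"{min(n - 1, X.shape[1])}"
        )
    # columns of X are exactly zero-mean: observed entries sum to zero around
    # 2*p-hat and missing entries impute to zero, so no recentering is needed
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum()) if s.size else 0
    k = n_components
    if rank < n_components:
        warnings.warn(
            f"rank {rank} below requested {n_components} components; truncating"
        )
        k = rank
    loadings = Vt[:k].T
    scores = U[:, :k] * s[:k]
    # sign convention: largest-magnitude element of each loading column positive
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0
    eigenvalues = s[:k] ** 2 / (n - 1)
    model = PcaModel(kept_ids, means, scales, loadings, eigenvalues)
    scores_df = pd.DataFrame(
        scores, index=list(defining_samples), columns=[f"PC{i+1}" for i in range(k)]
    )
    scores_df.index.name = "sample_id"
    return model, scores_df


def pca_project(model: PcaModel, gm_other: GenotypeMatrix) -> pd.DataFrame:
    """Project samples onto a fitted model's axes using its means and scales.

    SNPs absent from ``gm_other`` contribute zero (mean imputation); if fewer
    than 80% of the model's SNPs are present the projection is refused.
    """
    present = {s.id: i for i, s in enumerate(gm_other.snps)}
    hits = [(k, present[sid]) for k, sid in enumerate(model.snp_ids) if sid in present]
    if len(hits) < 0.8 * len(model.snp_ids):
        raise ValueError(
            f"only {len(hits)}/{len(model.snp_ids)} model SNPs present; "
            "projection unreliable below 80% overlap"
        )
    model_idx = np.array([h[0] for h in hits])
    other_idx = np.array([h[1] for h in hits])
    X = (gm_other.dosage[:, other_idx] - model.snp_means[model_idx]) / model.snp_scales[model_idx]
    X[np.isnan(X)] = 0.0
    scores = X @ model.loadings[model_idx, :]
    out = pd.DataFrame(
        scores, index=list(gm_other.samples),
        columns=[f"PC{i+1}" for i in range(model.n_components)],
    )
    out.index.name = "sample_id"
    return out
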