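"""Genotype principal-component analysis with Patterson normalization.

Each locus is centred by twice its observed allele frequency and scaled
by sqrt(p*(1-p)); missing calls are imputed at the centred mean (zero).
Eigendecomposition of the sample x sample covariance of the normalized
matrix gives the components; per-component sign is fixed by forcing the
largest-magnitude coordinate positive so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from snpdiv.genotype_io import MISSING, GenotypeMatrix, PathOrStream, _as_writer

_EIG_TOL = 1e-9


@dataclass
class PcaResult:
    coordinates: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray  # descending, length k
    percent_variance: np.ndarray
    loci_used: int
    sample_ids: list[str]
    populations: list[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def coords_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates, columns=[f"PC{i + 1}" for i in range(self.k)]
        )
        df.insert(0, "population", self.populations)
        df.insert(0, "sample", self.sample_ids)
        return df

    def eigen_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(self.k)],
                "eigenvalue": self.eigenvalues,
                "percent_variance": self.percent_variance,
            }
        )


def _normalized_matrix(gm: GenotypeMatrix, patterson: bool) -> tuple[np.ndarray, int]:
    calls = gm.calls.astype(float)
    obs = gm.calls != MISSING
    calls[~obs] = np.nan
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(calls, axis=0) / (2.0 * np.maximum(n_obs, 1))
    poly = (n_obs > 0) & (p > 0.0) & (p < 1.0)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic loci")
    calls = calls[:, poly]
    p = p[poly]
    x = calls - 2.0 * p
    if patterson:
        x /= np.sqrt(p * (1.0 - p))
    x[np.isnan(x)] = 0.0  # mean imputation after centring
    return x, int(poly.sum())


def run_pca(gm: GenotypeMatrix, k: int = 10, patterson: bool = True) -> PcaResult:
    """Compute the leading ``k`` principal components of the genotypes.

    ``k`` is truncated to the matrix rank (with a warning record) if it
    exceeds it.  Coordinates are eigenvectors scaled by the square root
    of their eigenvalue; percent variance is relative to the sum of all
    positive eigenvalues.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if k < 1:
        raise ValueError("k must be >= 1")
    x, loci_used = _normalized_matrix(gm, patterson)
    cov = x @ x.T / loci_used
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.where(np.abs(eigval) < _EIG_TOL, 0.0, eigval)

    rank = int((eigval > 0.0).sum())
    notes: list[str] = []
    if k > rank:
        notes.append(f"requested k={k} exceeds rank {rank}; truncated")
        k = rank
    total = eigval[eigval > 0.0].sum()
    eigval_k = eigval[:k]
    coords = eigvec[:, :k] * np.sqrt(eigval_k)
    for c in range(k):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return PcaResult(
        coordinates=coords,
        eigenvalues=eigval_k,
        percent_variance=100.0 * eigval_k / total,
        loci_used=loci_used,
        sample_ids=list(gm.sample_ids),
        populations=list(gm.population_labels),
        warnings=notes,
    )
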