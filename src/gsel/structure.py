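"""Genomic relationship matrix and population-structure PCA.

The GRM follows the observed-frequency construction
``G = Z Z' / (2 * sum p_j (1 - p_j))`` with ``Z`` the column-centered
dosage matrix. Principal components come from the eigendecomposition of
``G``; each component is screened with a Tracy-Widom statistic using the
moment-matched effective marker number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .types import GenotypeMatrix

__all__ = ["GRM", "StructureResult", "grm_vanraden", "pca_structure"]

# Upper-tail critical values of the Tracy-Widom (beta=1) distribution,
# from published percentile tables (Tracy & Widom / Patterson usage).
TW1_CRITICAL = {0.05: 0.9793, 0.01: 2.0234, 0.001: 3.2724}


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with its scaling metadata."""

    matrix: np.ndarray
    denominator: float
    allele_freqs: np.ndarray
    ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def with_ridge(self, ridge: float = 1e-6) -> "GRM":
        """Copy with ``ridge`` added to the diagonal (guarantees PD)."""
        m = self.matrix.copy()
        m[np.diag_indices_from(m)] += ridge
        return GRM(m, self.denominator, self.allele_freqs, self.ids)

    def min_eigenvalue_ratio(self) -> float:
        w = np.linalg.eigvalsh(self.matrix)
        return float(w[0] / max(w[-1], np.finfo(float).tiny))

    def to_frame(self) -> pd.DataFrame:
        ids = self.ids if self.ids is not None else np.arange(self.n)
        return pd.DataFrame(self.matrix, index=ids, columns=ids)


@dataclass
class StructureResult:
    scores: np.ndarray  # n x k, eigenvectors scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # descending, length k
    tracy_widom_stats: np.ndarray  # per component, nan if undefined
    significant: np.ndarray  # bool per component
    n_significant: int  # leading run of significant components
    alpha: float

    def scores_frame(self, ids=None) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        df = pd.DataFrame(self.scores, columns=cols)
        if ids is not None:
            df.insert(0, "id", ids)
        return df


def grm_vanraden(
    genotypes: GenotypeMatrix, allele_freqs: Optional[np.ndarray] = None
) -> GRM:
    """VanRaden (method 1) genomic relationship matrix.

    Frequencies default to the in-sample estimates; pass ``allele_freqs``
    to use external/base-population values.
    """
    M = genotypes.dosages
    if np.isnan(M).any():
        raise ValueError("GRM requires a complete (imputed) genotype matrix")
    p = M.mean(axis=0) / 2.0 if allele_freqs is None else np.asarray(allele_freqs, float)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("zero GRM denominator: all SNPs monomorphic")
    Z = M - 2.0 * p
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0  # enforce exact symmetry against fp drift
    return GRM(matrix=G, denominator=denom, allele_freqs=p, ids=genotypes.ids)


def _tw_stat(eigenvalues: np.ndarray, i: int) -> float:
    """Tracy-Widom statistic for the i-th component (0-based) using the
    moment-matching estimate of the effective number of markers."""
    lam = eigenvalues[i:]
    mm = len(lam)
    if mm < 2:
        return np.nan
    s1, s2 = float(lam.sum()), float((lam**2).sum())
    denom = (mm - 1) * s2 - s1**2
    if denom <= 0:  # eigenvalues (near-)equal: no excess structure
        return np.nan
    n_eff = (mm + 1) * s1**2 / denom
    if n_eff <= 1:
        return np.nan
    ell = mm * lam[0] / s1
    sq_n = np.sqrt(n_eff - 1)
    sq_m = np.sqrt(mm)
    mu = (sq_n + sq_m) ** 2 / n_eff
    sigma = (sq_n + sq_m) / n_eff * (1.0 / sq_n + 1.0 / sq_m) ** (1.0 / 3.0)
    return (ell - mu) / sigma


def pca_structure(grm: GRM, k: int = 10, alpha: float = 0.05) -> StructureResult:
    """Eigendecomposition of the GRM with Tracy-Widom screening.

    Scores are eigenvectors scaled by the square root of their eigenvalue.
    ``n_significant`` counts the leading components whose TW statistic
    exceeds the critical value at ``alpha``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if alpha not in TW1_CRITICAL:
        raise ValueError(f"alpha must be one of {sorted(TW1_CRITICAL)}")
    w, v = np.linalg.eigh(grm.matrix)
    w, v = w[::-1], v[:, ::-1]  # descending
    rank = int(np.sum(w > 1e-10 * max(w[0], 1.0)))
    if k > rank:
        warnings.warn(f"k={k} exceeds GRM rank {rank}; truncating", stacklevel=2)
        k = max(rank, 1)
    k = min(k, grm.n - 1) if grm.n > 1 else 1

    w_clip = np.clip(w, 0.0, None)
    scores = v[:, :k] * np.sqrt(w_clip[:k])
    pos = w_clip[w_clip > 1e-12 * max(w_clip[0], 1.0)]
    tw = np.array([_tw_stat(pos, i) if i < len(pos) else np.nan for i in range(k)])
    crit = TW1_CRITICAL[alpha]
    sig = np.where(np.isnan(tw), False, tw > crit)
    n_sig = 0
    for flag in sig:
        if not flag:
            break
        n_sig += 1
    return StructureResult(
        scores=scores,
        eigenvalues=w[:k],
        tracy_widom_stats=tw,
        significant=sig,
        n_significant=n_sig,
        alpha=alpha,
    )
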