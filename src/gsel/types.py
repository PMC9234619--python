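"""Core data containers shared across the pipeline stages.

Dosages are stored as ``float64`` with ``np.nan`` marking missing calls so
that vectorised masking works everywhere; complete matrices after imputation
may carry fractional dosages (mean imputation fills ``2p``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpMap",
    "GenotypeMatrix",
    "PhenotypeTable",
]

SNP_MAP_COLUMNS = ["chrom", "pos", "ref", "alt"]


def _as_snp_map(snp_map: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SNP_MAP_COLUMNS if c not in snp_map.columns]
    if missing:
        raise ValueError(f"snp_map missing columns: {missing}")
    return snp_map.reset_index(drop=True)


#: alias kept for readability in signatures
SnpMap = pd.DataFrame


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with a marker map.

    Attributes
    ----------
    dosages:
        ``(n, m)`` array of alt-allele dosages in ``{0, 1, 2}`` with ``nan``
        for missing calls (fractional values allowed after mean imputation).
    snp_map:
        DataFrame with columns ``chrom, pos, ref, alt`` (one row per SNP).
    ids:
        Individual identifiers, length ``n``.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        self.snp_map = _as_snp_map(self.snp_map)
        if len(self.snp_map) != self.dosages.shape[1]:
            raise ValueError(
                f"snp_map has {len(self.snp_map)} rows but dosages has "
                f"{self.dosages.shape[1]} columns"
            )
        if self.ids is None:
            self.ids = np.array([f"ind{i}" for i in range(self.dosages.shape[0])])
        else:
            self.ids = np.asarray(self.ids)
            if self.ids.shape[0] != self.dosages.shape[0]:
                raise ValueError("ids length does not match number of individuals")
        valid = np.isnan(self.dosages) | ((self.dosages >= 0) & (self.dosages <= 2))
        if not valid.all():
            raise ValueError("dosages must lie in [0, 2] or be nan")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def missing_rate(self) -> float:
        return float(np.isnan(self.dosages).mean())

    def is_complete(self) -> bool:
        return not np.isnan(self.dosages).any()

    def subset(
        self,
        individuals: Optional[Sequence[int]] = None,
        snps: Optional[Sequence[int]] = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given row/column indices."""
        dos = self.dosages
        ids = self.ids
        smap = self.snp_map
        if individuals is not None:
            individuals = np.asarray(individuals)
            dos = dos[individuals, :]
            ids = ids[individuals]
        if snps is not None:
            snps = np.asarray(snps)
            dos = dos[:, snps]
            smap = smap.iloc[snps]
        return GenotypeMatrix(dosages=dos.copy(), snp_map=smap.copy(), ids=ids.copy())

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            dosages=self.dosages.copy(),
            snp_map=self.snp_map.copy(),
            ids=self.ids.copy(),
        )


@dataclass
class PhenotypeTable:
    """Per-individual trait records.

    ``value`` is the recorded trait (attachment duration in hours for the
    heat-challenge design), ``batch`` an integer batch label used as a fixed
    effect, and ``true_bv`` the simulated breeding value when known.
    """

    ids: np.ndarray
    value: np.ndarray
    batch: np.ndarray
    true_bv: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.value = np.asarray(self.value, dtype=np.float64)
        self.batch = np.asarray(self.batch)
        n = len(self.ids)
        if len(self.value) != n or len(self.batch) != n:
            raise ValueError("ids, value and batch must have equal length")
        if self.true_bv is not None:
            self.true_bv = np.asarray(self.true_bv, dtype=np.float64)
            if len(self.true_bv) != n:
                raise ValueError("true_bv length mismatch")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        data = {"id": self.ids, "batch": self.batch, "duration_h": self.value}
        if self.true_bv is not None:
            data["true_bv"] = self.true_bv
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhenotypeTable":
        true_bv = df["true_bv"].to_numpy() if "true_bv" in df.columns else None
        return cls(
            ids=df["id"].to_numpy(),
            value=df["duration_h"].to_numpy(),
            batch=df["batch"].to_numpy(),
            true_bv=true_bv,
        )


def batch_design(batch: np.ndarray, add_intercept: bool = True) -> np.ndarray:
    """Fixed-effect design matrix for a batch factor.

    Intercept plus treatment-coded batch dummies (first level as reference),
    mirroring the "intercept and different batches" fixed-effect structure.
    """
    batch = np.asarray(batch)
    levels = np.unique(batch)
    cols = []
    if add_intercept:
        cols.append(np.ones(len(batch)))
        dummy_levels = levels[1:]
    else:
        dummy_levels = levels
    for lv in dummy_levels:
        cols.append((batch == lv).astype(np.float64))
    return np.column_stack(cols) if cols else np.empty((len(batch), 0))
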