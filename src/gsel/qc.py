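"""Genotype quality control and naive imputation.

Filter order is fixed and documented: (1) individuals by call rate, then
(2) SNPs by call rate, then (3) SNPs by MAF, with MAF recomputed after the
first two steps. Thresholds are strict (a SNP with MAF exactly at the
minimum is removed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .types import GenotypeMatrix

__all__ = ["QCThresholds", "QCReport", "QCError", "compute_maf", "apply_qc", "impute_naive"]


class QCError(ValueError):
    """Raised when a filter removes every individual or every SNP."""

    def __init__(self, message: str, report: "QCReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class QCThresholds:
    maf_min: float = 0.05
    snp_call_min: float = 0.95
    ind_call_min: float = 0.80

    def __post_init__(self) -> None:
        for name in ("maf_min", "snp_call_min", "ind_call_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    n_ind_in: int
    n_ind_out: int
    n_snps_in: int
    n_snps_out: int
    n_ind_removed_call_rate: int
    n_snps_removed_call_rate: int
    n_snps_removed_maf: int
    mean_missing_rate_after: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    def log_lines(self) -> list[str]:
        return [
            f"QC in: {self.n_ind_in} individuals x {self.n_snps_in} SNPs",
            f"removed {self.n_ind_removed_call_rate} individuals (call rate)",
            f"removed {self.n_snps_removed_call_rate} SNPs (call rate)",
            f"removed {self.n_snps_removed_maf} SNPs (MAF)",
            f"QC out: {self.n_ind_out} individuals x {self.n_snps_out} SNPs, "
            f"mean missing rate {self.mean_missing_rate_after:.4%}",
        ]


def compute_maf(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency from non-missing calls.

    ``MAF = min(p, 1 - p)`` with ``p = sum(dosages) / (2 * n_called)``.
    All-missing SNPs get ``nan`` as an undefined sentinel.
    """
    dos = genotypes.dosages
    n_called = np.sum(~np.isnan(dos), axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(dos, axis=0) / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    maf[n_called == 0] = np.nan
    return maf


def apply_qc(
    genotypes: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the three QC filters in the documented order."""
    if genotypes.n_individuals == 0 or genotypes.n_snps == 0:
        raise QCError("empty genotype matrix")
    n_ind_in, n_snps_in = genotypes.n_individuals, genotypes.n_snps
    called = ~np.isnan(genotypes.dosages)

    ind_call = called.mean(axis=1)
    keep_ind = ind_call > thresholds.ind_call_min
    n_ind_removed = int((~keep_ind).sum())

    snp_call = called[keep_ind, :].mean(axis=0) if keep_ind.any() else np.zeros(n_snps_in)
    keep_snp_call = snp_call > thresholds.snp_call_min
    n_snp_call_removed = int((~keep_snp_call).sum())

    sub = genotypes.subset(
        individuals=np.flatnonzero(keep_ind), snps=np.flatnonzero(keep_snp_call)
    )
    maf = compute_maf(sub) if sub.n_snps else np.empty(0)
    # undefined MAF (all-missing) cannot pass a strict threshold
    keep_maf = np.where(np.isnan(maf), False, maf > thresholds.maf_min)
    n_maf_removed = int((~keep_maf).sum())
    out = sub.subset(snps=np.flatnonzero(keep_maf))

    report = QCReport(
        n_ind_in=n_ind_in,
        n_ind_out=out.n_individuals,
        n_snps_in=n_snps_in,
        n_snps_out=out.n_snps,
        n_ind_removed_call_rate=n_ind_removed,
        n_snps_removed_call_rate=n_snp_call_removed,
        n_snps_removed_maf=n_maf_removed,
        mean_missing_rate_after=out.missing_rate if out.n_snps else float("nan"),
    )
    if out.n_individuals == 0:
        raise QCError("QC removed all individuals", report)
    if out.n_snps == 0:
        raise QCError("QC removed all SNPs", report)
    return out, report


def impute_naive(
    genotypes: GenotypeMatrix, mode: str = "mean", seed: int = 0
) -> GenotypeMatrix:
    """Fill missing dosages from per-SNP allele frequencies.

    ``mean`` fills the expected dosage ``2p`` (preserves allele frequency
    exactly); ``sample`` draws from Hardy-Weinberg proportions at ``p``.
    """
    if mode not in ("mean", "sample"):
        raise ValueError(f"unknown imputation mode: {mode!r}")
    out = genotypes.copy()
    miss = np.isnan(out.dosages)
    if not miss.any():
        return out
    n_called = (~miss).sum(axis=0)
    if (n_called == 0).any():
        raise ValueError("cannot impute all-missing SNPs; run QC first")
    p = np.nansum(out.dosages, axis=0) / (2.0 * n_called)
    if mode == "mean":
        fill = np.broadcast_to(2.0 * p, out.dosages.shape)
        out.dosages[miss] = fill[miss]
    else:
        rng = np.random.default_rng(seed)
        rows, cols = np.nonzero(miss)
        pj = p[cols]
        u = rng.random(len(rows))
        # HWE genotype probabilities: (1-p)^2, 2p(1-p), p^2
        q2 = (1 - pj) ** 2
        q2_plus_2pq = q2 + 2 * pj * (1 - pj)
        out.dosages[rows, cols] = np.where(u < q2, 0.0, np.where(u < q2_plus_2pq, 1.0, 2.0))
    return out
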