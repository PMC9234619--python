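"""Single-marker mixed-linear-model association scan.

The null model ``y = Xb + g + e`` (``g ~ N(0, G sigma_g^2)``) is fitted
once by REML; per-marker Wald tests are then run with the variance
components held fixed (the EMMAX approximation), which reduces each test
to weighted least squares in the eigen-rotated space. Effects are reported
per copy of the minor allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .predict import RemlFit, reml_single_random
from .structure import GRM
from .types import GenotypeMatrix

__all__ = [
    "SignificanceThresholds",
    "NullModel",
    "fit_null_mlm",
    "scan_association",
    "compute_thresholds",
    "classify_snps",
    "compute_pve",
    "annotate_candidates",
    "export_manhattan_qq",
]


@dataclass(frozen=True)
class SignificanceThresholds:
    """Genome-wide (Bonferroni) and suggestive p-value cutoffs."""

    genome_wide_p: float
    suggestive_p: float
    m_tests: int
    alpha: float

    @property
    def genome_wide_neglog10(self) -> float:
        return round(-math.log10(self.genome_wide_p), 2)

    @property
    def suggestive_neglog10(self) -> float:
        return round(-math.log10(self.suggestive_p), 2)


def compute_thresholds(
    m_tests: int, alpha: float = 0.05, suggestive: float = 1e-5
) -> SignificanceThresholds:
    """Bonferroni genome-wide threshold ``alpha / m`` plus the conventional
    suggestive cutoff."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    gw = alpha / m_tests
    return SignificanceThresholds(
        genome_wide_p=gw, suggestive_p=suggestive, m_tests=m_tests, alpha=alpha
    )


@dataclass
class NullModel:
    """Null-model REML fit plus the rotation cache used by the scan."""

    fit: RemlFit
    y: np.ndarray
    X: np.ndarray
    weights: np.ndarray  # 1 / (sigma_g2 * d_i + sigma_e2) in rotated space

    @property
    def sigma_g2(self) -> float:
        return self.fit.sigma_g2

    @property
    def sigma_e2(self) -> float:
        return self.fit.sigma_e2

    @property
    def h2(self) -> float:
        return self.fit.h2


def fit_null_mlm(y: np.ndarray, covariates: np.ndarray, grm: GRM) -> NullModel:
    """REML fit of the covariates-only mixed model; caches the spectral
    rotation so every marker test afterwards is O(n)."""
    y = np.asarray(y, dtype=np.float64)
    X = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
    fit = reml_single_random(y, X, grm)
    w = 1.0 / (fit.sigma_g2 * fit.eigvals + fit.sigma_e2)
    return NullModel(fit=fit, y=y, X=X, weights=w)


def scan_association(
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray,
    null_fit: NullModel,
    var_p: Optional[float] = None,
) -> pd.DataFrame:
    """Per-SNP Wald tests with null variance components held fixed.

    Returns a Table-1-style frame: snp, chrom, pos, alleles (minor/major),
    maf, beta (per minor-allele copy), se, p_value, pve (percent).
    Monomorphic markers get ``beta=0, p=1`` and a flag.
    """
    M = genotypes.dosages
    if np.isnan(M).any():
        raise ValueError("scan requires a complete genotype matrix")
    y = np.asarray(y, dtype=np.float64)
    X = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
    n, m = M.shape
    if len(y) != n:
        raise ValueError("phenotype/genotype dimension mismatch")
    U = null_fit.fit.eigvecs
    sw = np.sqrt(null_fit.weights)

    Xw = sw[:, None] * (U.T @ X)
    yw = sw * (U.T @ y)
    Mw = sw[:, None] * (U.T @ M)

    Q, _ = np.linalg.qr(Xw)
    ry = yw - Q @ (Q.T @ yw)
    RM = Mw - Q @ (Q.T @ Mw)

    sxx = np.einsum("ij,ij->j", RM, RM)
    sxy = RM.T @ ry
    syy = float(ry @ ry)
    p_cov = X.shape[1]
    dof = n - p_cov - 1

    mono = sxx <= 1e-12 * max(float(sxx.max(initial=0.0)), 1.0)
    safe_sxx = np.where(mono, 1.0, sxx)
    beta = np.where(mono, 0.0, sxy / safe_sxx)
    rss = np.clip(syy - beta**2 * safe_sxx, 0.0, None)
    se = np.sqrt(rss / dof / safe_sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(mono | (se == 0), 0.0, beta / np.where(se == 0, 1.0, se))
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    pval = np.where(mono, 1.0, np.clip(pval, np.finfo(float).tiny, 1.0))

    # orient effects to the minor allele
    p_alt = M.mean(axis=0) / 2.0
    maf = np.minimum(p_alt, 1.0 - p_alt)
    flip = p_alt > 0.5
    beta_minor = np.where(flip, -beta, beta)
    smap = genotypes.snp_map
    minor = np.where(flip, smap["ref"], smap["alt"])
    major = np.where(flip, smap["alt"], smap["ref"])

    if var_p is None:
        var_p = float(np.var(y))
    pve = compute_pve(beta_minor, maf, var_p)

    return pd.DataFrame(
        {
            "snp": [
                f"{c}_{p}" for c, p in zip(smap["chrom"], smap["pos"])
            ],
            "chrom": smap["chrom"].to_numpy(),
            "pos": smap["pos"].to_numpy(),
            "allele": [f"{mi}/{ma}" for mi, ma in zip(minor, major)],
            "maf": maf,
            "beta": beta_minor,
            "se": se,
            "p_value": pval,
            "pve": pve,
            "monomorphic": mono,
        }
    )


def compute_pve(
    beta: np.ndarray | float, maf: np.ndarray | float, var_p: float
) -> np.ndarray | float:
    """Percent phenotypic variance explained by one SNP:
    ``100 * 2 p (1-p) beta^2 / sigma_P^2``."""
    if var_p <= 0:
        raise ValueError("var_p must be positive")
    return 100.0 * 2.0 * np.asarray(maf) * (1.0 - np.asarray(maf)) * np.asarray(beta) ** 2 / var_p


def classify_snps(
    results: pd.DataFrame, thresholds: SignificanceThresholds
) -> pd.DataFrame:
    """Label each SNP genome-wide / suggestive / none.

    Boundary convention: a p-value exactly at a threshold passes it.
    """
    out = results.copy()
    p = out["p_value"].to_numpy()
    cls = np.where(
        p <= thresholds.genome_wide_p,
        "genome-wide",
        np.where(p <= thresholds.suggestive_p, "suggestive", "none"),
    )
    out["sig_class"] = cls
    return out


def count_classes(classified: pd.DataFrame) -> dict:
    vc = classified["sig_class"].value_counts()
    return {
        "genome-wide": int(vc.get("genome-wide", 0)),
        "suggestive": int(vc.get("suggestive", 0)),
        "none": int(vc.get("none", 0)),
    }


def _read_genes_gff3(path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        rows.append((feat.seqid, int(feat.start), int(feat.end), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def annotate_candidates(
    snps: pd.DataFrame,
    annotation,
    window_bp: int = 50_000,
    classes: Sequence[str] = ("genome-wide", "suggestive"),
) -> pd.DataFrame:
    """Candidate genes on or near the significant SNPs.

    ``annotation`` is a GFF3 path (gene features, 1-based inclusive) or an
    equivalent frame with columns ``chrom, start, end, gene``. For each SNP
    in the requested significance classes, all genes overlapping the SNP or
    within ``window_bp`` of it are reported; if none, the nearest gene on
    the chromosome with its distance. SNPs inside a gene span are labeled
    ``genic`` (the toy annotation has no exon structure), otherwise
    ``intergenic``.
    """
    genes = annotation if isinstance(annotation, pd.DataFrame) else _read_genes_gff3(annotation)
    if "sig_class" in snps.columns:
        q = snps[snps["sig_class"].isin(classes)]
    else:
        q = snps
    unmatched = sorted(set(q["chrom"]) - set(genes["chrom"]))
    if unmatched:
        raise ValueError(f"chromosomes absent from annotation: {unmatched}")

    rows = []
    for _, snp in q.iterrows():
        sub = genes[genes["chrom"] == snp["chrom"]]
        pos = int(snp["pos"])
        dist = np.where(
            (sub["start"] <= pos) & (pos <= sub["end"]),
            0,
            np.minimum(np.abs(sub["start"] - pos), np.abs(sub["end"] - pos)),
        )
        if len(sub) == 0:
            rows.append((snp["snp"], snp["chrom"], pos, None, None, "intergenic", "none within window"))
            continue
        within = np.flatnonzero(dist <= window_bp)
        region = "genic" if (dist == 0).any() else "intergenic"
        if len(within) == 0:
            j = int(np.argmin(dist))
            rows.append(
                (snp["snp"], snp["chrom"], pos, sub.iloc[j]["gene"], int(dist[j]), region, "nearest")
            )
        else:
            for j in within:
                rows.append(
                    (snp["snp"], snp["chrom"], pos, sub.iloc[j]["gene"], int(dist[j]), region, "within window")
                )
    return pd.DataFrame(
        rows,
        columns=["snp", "chrom", "pos", "gene", "distance_bp", "region", "match"],
    )


def export_manhattan_qq(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables.

    Manhattan: cumulative genome coordinate (chromosome offsets stacked in
    map order) and ``-log10 p``. QQ: expected quantiles
    ``-log10((rank - 0.5) / m)`` vs observed, both descending.
    """
    res = results.reset_index(drop=True)
    offsets = {}
    cum = 0
    for chrom in pd.unique(res["chrom"]):
        offsets[chrom] = cum
        cum += int(res.loc[res["chrom"] == chrom, "pos"].max())
    x = res["pos"].to_numpy() + np.array([offsets[c] for c in res["chrom"]])
    manhattan = pd.DataFrame(
        {
            "chrom": res["chrom"],
            "pos": res["pos"],
            "x": x,
            "neglog10_p": -np.log10(res["p_value"].to_numpy()),
        }
    )
    m = len(res)
    p_sorted = np.sort(res["p_value"].to_numpy())
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    qq = pd.DataFrame(
        {"expected": expected, "observed": -np.log10(p_sorted)}
    )
    return manhattan, qq
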