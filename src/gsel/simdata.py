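"""Synthetic population generator.

Emulates a random-mating aquaculture population: founder haplotypes with
tunable allele frequencies and linkage disequilibrium, one generation of
random mating with recombination, an additive trait with batch fixed
effects and a recording ceiling, and independent genotype missingness.

The LD model is a Gaussian-copula first-order autoregression along each
chromosome: latent standard normals follow AR(1) with parameter ``ld_rho``
and are thresholded at the per-site allele frequency, so marginal
frequencies are exact and pairwise correlation decays geometrically with
marker distance. ``ld_rho = 0`` gives independent sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import GenotypeMatrix, PhenotypeTable

__all__ = [
    "FounderPool",
    "TraitArchitecture",
    "SimulatedPopulation",
    "simulate_founders",
    "random_mate",
    "simulate_phenotype",
    "inject_missingness",
    "attachment_summary",
    "AttachmentSummary",
    "simulate_dataset",
]


@dataclass
class FounderPool:
    """Phased founder haplotypes plus the marker map.

    ``haplotypes`` has shape ``(2 * n_founders, m)`` with entries in {0, 1};
    rows ``2k`` and ``2k + 1`` are the two haplotypes of founder ``k``.
    """

    haplotypes: np.ndarray
    snp_map: pd.DataFrame
    allele_freqs: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=np.float64)
        if set(np.unique(self.haplotypes)) - {0, 1}:
            raise ValueError("haplotype entries must be 0/1")
        if not ((self.allele_freqs > 0) & (self.allele_freqs < 1)).all():
            raise ValueError("allele_freqs must lie strictly in (0, 1)")
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class TraitArchitecture:
    """Additive trait specification.

    ``qtl_effects`` are phenotype units per alt-allele copy; ``h2_target``
    sets the realized narrow-sense heritability; recordings are censored at
    ``ceiling_hours`` (survivors of the full challenge are scored at the
    ceiling).
    """

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    h2_target: float
    batch_effects: np.ndarray = field(default_factory=lambda: np.zeros(4))
    intercept: float = 3.0
    ceiling_hours: float = 6.0
    null_residual_var: float = 1.0

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=np.int64)
        self.qtl_effects = np.asarray(self.qtl_effects, dtype=np.float64)
        self.batch_effects = np.asarray(self.batch_effects, dtype=np.float64)
        if len(self.qtl_indices) != len(self.qtl_effects):
            raise ValueError("qtl_indices and qtl_effects length mismatch")
        if len(np.unique(self.qtl_indices)) != len(self.qtl_indices):
            raise ValueError("qtl_indices must be unique")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must be in [0, 1]")

    @classmethod
    def sample(
        cls,
        m: int,
        n_qtl: int,
        h2_target: float,
        n_batches: int = 4,
        batch_sd: float = 0.2,
        effect_scale: float = 1.0,
        seed: int = 0,
        **kwargs,
    ) -> "TraitArchitecture":
        """Draw a sparse architecture: QTL positions uniform, effects
        double-exponential (a few loci reach percent-level variance shares)."""
        rng = np.random.default_rng(seed)
        idx = rng.choice(m, size=n_qtl, replace=False)
        effects = rng.laplace(0.0, effect_scale, size=n_qtl)
        batch_eff = rng.normal(0.0, batch_sd, size=n_batches)
        return cls(
            qtl_indices=np.sort(idx),
            qtl_effects=effects,
            h2_target=h2_target,
            batch_effects=batch_eff,
            **kwargs,
        )


@dataclass
class SimulatedPopulation:
    genotypes: GenotypeMatrix
    phenotypes: Optional[PhenotypeTable]
    true_bv: Optional[np.ndarray]
    pedigree: pd.DataFrame
    seed: int


def simulate_founders(
    n_founders: int,
    m: int,
    chrom_lengths: Sequence[int],
    maf_range: Tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.0,
    seed: int = 0,
) -> FounderPool:
    """Draw founder haplotypes with AR(1)-copula LD.

    SNPs are spread over chromosomes proportionally to ``chrom_lengths``
    with uniform random (sorted, distinct) basepair positions. Per-SNP alt
    frequencies are uniform on ``maf_range``.
    """
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if m < 1:
        raise ValueError("m must be >= 1")
    chrom_lengths = list(chrom_lengths)
    if len(chrom_lengths) == 0:
        raise ValueError("chrom_lengths must be non-empty")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must be in [0, 1)")

    rng = np.random.default_rng(seed)
    total = float(sum(chrom_lengths))
    # proportional allocation, remainder to the largest chromosomes
    raw = np.array([m * L / total for L in chrom_lengths])
    counts = np.floor(raw).astype(int)
    short = m - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1

    rows = []
    n_hap = 2 * n_founders
    freqs = rng.uniform(lo, hi, size=m)
    haplotypes = np.empty((n_hap, m), dtype=np.int8)
    col = 0
    for c, (L, k) in enumerate(zip(chrom_lengths, counts)):
        if k == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=k, replace=False))
        for p in pos:
            rows.append((f"chr{c + 1}", int(p), "A", "G"))
        # latent AR(1) per haplotype along this chromosome
        z = rng.standard_normal((n_hap, k))
        if ld_rho > 0:
            w = np.sqrt(1.0 - ld_rho**2)
            for j in range(1, k):
                z[:, j] = ld_rho * z[:, j - 1] + w * z[:, j]
        thresh = norm.ppf(freqs[col : col + k])
        haplotypes[:, col : col + k] = (z < thresh).astype(np.int8)
        col += k

    snp_map = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    # retain stated frequencies (the marginal target), not realized ones
    return FounderPool(haplotypes=haplotypes, snp_map=snp_map, allele_freqs=freqs)


def _make_gamete(
    pool: FounderPool, parent: int, chrom_slices: list, rng: np.random.Generator
) -> np.ndarray:
    """One recombined gamete: exactly one crossover per chromosome,
    uniform breakpoint, random starting haplotype."""
    h1 = pool.haplotypes[2 * parent]
    h2 = pool.haplotypes[2 * parent + 1]
    gamete = np.empty(pool.n_snps, dtype=np.int8)
    for sl, pos in chrom_slices:
        k = sl.stop - sl.start
        start_hap = rng.integers(2)
        a, b = (h1, h2) if start_hap == 0 else (h2, h1)
        # crossover between marker intervals; breakpoint index = number of
        # leading markers taken from the starting haplotype
        bp = rng.integers(0, k + 1)
        seg = np.concatenate([a[sl][:bp], b[sl][bp:]])
        gamete[sl] = seg
    return gamete


def random_mate(
    pool: FounderPool, n_offspring: int, seed: int = 0
) -> SimulatedPopulation:
    """One generation of random mating among the founders.

    Each offspring gets two distinct uniform-random parents and one
    recombined gamete from each; full- and half-sib families arise by
    chance. Dosage is the sum of the two gamete alleles.
    """
    if pool.n_founders < 2:
        raise ValueError("need at least 2 founders to mate")
    rng = np.random.default_rng(seed)

    chrom_slices = []
    smap = pool.snp_map
    for chrom in smap["chrom"].unique():
        idx = np.flatnonzero((smap["chrom"] == chrom).to_numpy())
        chrom_slices.append((slice(int(idx[0]), int(idx[-1]) + 1), None))

    dosages = np.empty((n_offspring, pool.n_snps), dtype=np.float64)
    sires = np.empty(n_offspring, dtype=np.int64)
    dams = np.empty(n_offspring, dtype=np.int64)
    for i in range(n_offspring):
        sire, dam = rng.choice(pool.n_founders, size=2, replace=False)
        sires[i], dams[i] = sire, dam
        g1 = _make_gamete(pool, sire, chrom_slices, rng)
        g2 = _make_gamete(pool, dam, chrom_slices, rng)
        dosages[i] = g1 + g2

    ids = np.array([f"ind{i}" for i in range(n_offspring)])
    genotypes = GenotypeMatrix(dosages=dosages, snp_map=smap.copy(), ids=ids)
    pedigree = pd.DataFrame({"id": ids, "sire": sires, "dam": dams})
    return SimulatedPopulation(
        genotypes=genotypes, phenotypes=None, true_bv=None, pedigree=pedigree, seed=seed
    )


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    arch: TraitArchitecture,
    n_batches: int = 4,
    seed: int = 0,
    target_var_g: Optional[float] = None,
) -> PhenotypeTable:
    """Additive phenotype with batch fixed effects and a recording ceiling.

    Genetic values are ``g = M[:, qtl] @ effects``; the residual variance is
    chosen so the realized sample satisfies
    ``Var(g) / (Var(g) + sigma_e^2) = h2_target``. Batches are assigned
    round-robin. Records are clipped to ``[0, ceiling_hours]``; the upper
    clip models censored survivors of the full challenge.

    ``target_var_g`` rescales the genetic values (and implicitly the
    effects) so that ``Var(g)`` hits a chosen value — used to keep the
    trait within a realistic duration range regardless of the QTL count.
    """
    if (arch.qtl_indices >= genotypes.n_snps).any() or (arch.qtl_indices < 0).any():
        raise ValueError("qtl_indices out of range for this genotype matrix")
    rng = np.random.default_rng(seed)
    n = genotypes.n_individuals

    if arch.h2_target == 0.0 or len(arch.qtl_indices) == 0:
        if arch.h2_target == 1.0:
            raise ValueError("h2_target=1 requires at least one QTL")
        g = np.zeros(n)
        sigma_e2 = arch.null_residual_var if arch.h2_target == 0.0 else 0.0
    else:
        M = genotypes.dosages[:, arch.qtl_indices]
        if np.isnan(M).any():
            raise ValueError("genotypes at QTLs must be complete")
        g = M @ arch.qtl_effects
        var_g = float(np.var(g))
        if var_g == 0.0:
            raise ValueError("genetic variance is zero; check QTL polymorphism")
        if target_var_g is not None:
            g = g * np.sqrt(target_var_g / var_g)
            var_g = target_var_g
        g = g - g.mean()
        if arch.h2_target == 1.0:
            sigma_e2 = 0.0
        else:
            sigma_e2 = var_g * (1.0 - arch.h2_target) / arch.h2_target

    batch = np.arange(n) % n_batches
    if len(arch.batch_effects) < n_batches:
        raise ValueError("batch_effects shorter than n_batches")
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=n) if sigma_e2 > 0 else np.zeros(n)
    y = arch.intercept + arch.batch_effects[batch] + g + e
    y = np.clip(y, 0.0, arch.ceiling_hours)
    return PhenotypeTable(ids=genotypes.ids, value=y, batch=batch, true_bv=g)


def inject_missingness(
    genotypes: GenotypeMatrix, rate: float, seed: int = 0
) -> GenotypeMatrix:
    """Mask each call independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    out = genotypes.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.dosages.shape) < rate
    out.dosages[mask] = np.nan
    return out


@dataclass
class AttachmentSummary:
    """Binned detachment summary of a censored-duration challenge."""

    bin_edges: np.ndarray
    drop_rate: np.ndarray
    cumulative_drop_rate: np.ndarray
    final_attachment_rate: float

    @property
    def peak_bin(self) -> int:
        return int(np.argmax(self.drop_rate))


def attachment_summary(
    durations: np.ndarray, bin_width: float = 1.0, total_hours: float = 6.0
) -> AttachmentSummary:
    """Per-bin drop rates, cumulative drop rate and final attachment rate.

    Individuals with duration equal to ``total_hours`` are censored
    survivors and counted in the final attachment rate, not in any bin.
    Mass conservation holds exactly:
    ``sum(drop_rate) + final_attachment_rate == 1``.
    """
    durations = np.asarray(durations, dtype=np.float64)
    if (durations < 0).any():
        raise ValueError("durations must be non-negative")
    if (durations > total_hours).any():
        raise ValueError("durations exceed total_hours")
    n = len(durations)
    if n == 0:
        raise ValueError("empty durations")
    n_bins = int(np.ceil(total_hours / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, total_hours)
    survivors = durations >= total_hours
    dropped = durations[~survivors]
    counts, _ = np.histogram(dropped, bins=edges)
    drop_rate = counts / n
    final_rate = float(survivors.mean())
    return AttachmentSummary(
        bin_edges=edges,
        drop_rate=drop_rate,
        cumulative_drop_rate=np.cumsum(drop_rate),
        final_attachment_rate=final_rate,
    )


def simulate_dataset(
    n_founders: int = 400,
    n_offspring: int = 1120,
    m: int = 2000,
    n_chrom: int = 18,
    chrom_length: int = 50_000_000,
    maf_range: Tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.5,
    n_qtl: int = 200,
    h2_target: float = 0.40,
    n_batches: int = 4,
    missing_rate: float = 0.008,
    seed: int = 0,
) -> SimulatedPopulation:
    """Convenience wrapper: founders -> offspring -> phenotype -> missingness.

    Sub-seeds are derived deterministically from ``seed`` so the whole
    dataset is reproducible byte-for-byte.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0]) for s in ss]
    pool = simulate_founders(
        n_founders,
        m,
        [chrom_length] * n_chrom,
        maf_range=maf_range,
        ld_rho=ld_rho,
        seed=sub[0],
    )
    pop = random_mate(pool, n_offspring, seed=sub[1])
    arch = TraitArchitecture.sample(
        m=m, n_qtl=min(n_qtl, m), h2_target=h2_target, n_batches=n_batches, seed=sub[2]
    )
    # pin Var(g) so sigma_P^2 ~ 2.2 h^2 regardless of QTL count
    pheno = simulate_phenotype(
        pop.genotypes,
        arch,
        n_batches=n_batches,
        seed=sub[2],
        target_var_g=2.2 * h2_target if h2_target > 0 else None,
    )
    genotypes = inject_missingness(pop.genotypes, missing_rate, seed=sub[3])
    return SimulatedPopulation(
        genotypes=genotypes,
        phenotypes=pheno,
        true_bv=pheno.true_bv,
        pedigree=pop.pedigree,
        seed=seed,
    )
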