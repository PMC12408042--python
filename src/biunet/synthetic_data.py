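"""Synthetic phased cohorts with block-LD structure and rare variants.

The generator is a Li-Stephens-style mosaic: a small panel of founder
haplotypes is drawn with a U-shaped allele-frequency spectrum (Beta(0.3,0.3)),
and every simulated haplotype copies one founder at a time, switching to a
uniformly chosen founder with a small per-SNP probability and flipping each
copied allele with a small mutation probability. Low switch rates give long
shared haplotype blocks — exactly the linkage-disequilibrium signal that
imputation exploits — while the U-shaped founder spectrum populates both the
rare (MAF <= 0.5%) and common (MAF >= 40%) ends of the frequency spectrum.

Haplotypes are paired into phased diploids, coded {1..4}, and SNPs failing
the MAF >= 0.1% quality floor are dropped (count logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeMatrix, VariantMeta, compute_maf_matrix

logger = logging.getLogger(__name__)

#: encoding of a phased allele pair (a0, a1) -> class code
_PAIR_CODE = np.array([[1, 2], [3, 4]], dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 400
    n_snps: int = 2000
    n_founders: int = 30
    switch_rate: float = 0.01      # per-SNP template-switch probability
    mutation_rate: float = 0.002   # per-site allele flip probability
    position_span: tuple = (1_000_000, 9_000_000)
    maf_floor: float = 0.001
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("switch_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_founders < 1 or self.n_samples < 1 or self.n_snps < 1:
            raise ValueError("sizes must be positive")


@dataclass
class FounderPanel:
    haplotypes: np.ndarray   # [n_founders, n_snps] in {0, 1}
    frequencies: np.ndarray  # allele frequencies the panel was drawn from


def simulate_founders(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> FounderPanel:
    """Draw founder haplotypes site-wise from a U-shaped frequency spectrum."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    freqs = rng.beta(0.3, 0.3, size=config.n_snps)
    # keep every site segregating-able in principle
    freqs = np.clip(freqs, 1e-3, 1 - 1e-3)
    haps = (rng.random((config.n_founders, config.n_snps))
            < freqs[None, :]).astype(np.uint8)
    return FounderPanel(haplotypes=haps, frequencies=freqs)


def simulate_haplotype(panel: FounderPanel, config: SimulationConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """One mosaic haplotype: copy a founder, switch templates at random SNPs,
    then apply per-site mutation flips."""
    return _simulate_haplotypes(panel, config, rng, 1)[0]


def _simulate_haplotypes(panel: FounderPanel, config: SimulationConfig,
                         rng: np.random.Generator, n: int) -> np.ndarray:
    n_founders, n_snps = panel.haplotypes.shape
    # founder index per (haplotype, SNP): switch points get fresh uniform
    # draws; forward-fill between switches
    switch = rng.random((n, n_snps)) < config.switch_rate
    switch[:, 0] = True
    draws = rng.integers(0, n_founders, size=(n, n_snps))
    pos = np.arange(n_snps)
    last_switch = np.maximum.accumulate(np.where(switch, pos, -1), axis=1)
    founder = np.take_along_axis(draws, last_switch, axis=1)
    haps = np.take_along_axis(
        np.broadcast_to(panel.haplotypes, (n, n_founders, n_snps)),
        founder[:, None, :], axis=1)[:, 0, :]
    if config.mutation_rate > 0:
        flips = rng.random((n, n_snps)) < config.mutation_rate
        haps = haps ^ flips
    return haps.astype(np.uint8)


def simulate_cohort(config: SimulationConfig) -> GenotypeMatrix:
    """Phased diploid cohort: 2*n_samples mosaic haplotypes paired in order.

    Positions are a sorted draw without replacement from ``position_span``;
    SNPs with cohort MAF below the QC floor are dropped (count logged, and a
    warning is raised if fewer SNPs survive than requested).
    """
    import warnings

    rng = np.random.default_rng(config.seed)
    panel = simulate_founders(config, rng)
    haps = _simulate_haplotypes(panel, config, rng, 2 * config.n_samples)
    codes = _PAIR_CODE[haps[0::2], haps[1::2]]  # [n_samples, n_snps]

    maf = compute_maf_matrix(codes)
    keep = maf >= config.maf_floor
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d SNP(s) below the MAF >= %g QC floor",
                    n_dropped, config.maf_floor)
    codes = codes[:, keep]
    n_kept = codes.shape[1]
    if n_kept < config.n_snps:
        warnings.warn(f"only {n_kept} of {config.n_snps} simulated SNPs "
                      "survived the MAF floor")
    if n_kept == 0:
        raise ValueError("no SNPs survived the MAF floor")

    lo, hi = config.position_span
    positions = np.sort(rng.choice(np.arange(lo, hi), size=n_kept,
                                   replace=False))
    variants = [VariantMeta(chrom=config.chrom, pos=int(p), ref_allele="A",
                            alt_allele="G", snp_id=f"snp{j}")
                for j, p in enumerate(positions)]
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    return GenotypeMatrix(codes=codes, variants=variants, sample_ids=sample_ids)
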