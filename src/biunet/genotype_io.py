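"""Phased-VCF input/output and the integer genotype encoding.

Phased diploid genotypes are represented by a 6-symbol integer code:

====  ==========  ==================================
code  GT string   meaning
====  ==========  ==================================
0     ``./.``     missing call
1     ``0|0``     homozygous reference (A|A)
2     ``0|1``     heterozygous, ref on first haplotype (A|a)
3     ``1|0``     heterozygous, alt on first haplotype (a|A)
4     ``1|1``     homozygous alternate (a|a)
5     --          padding; only ever appears inside segments
====  ==========  ==================================

Phase is information: codes 2 and 3 are distinct classes, and the model
predicts over the four non-missing classes {1, 2, 3, 4}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

# Encoding scheme constants
MISSING = 0
HOM_REF = 1
HET_REF_ALT = 2  # 0|1
HET_ALT_REF = 3  # 1|0
HOM_ALT = 4
PAD = 5

VOCABULARY_SIZE = 6
CLASS_CODES = (HOM_REF, HET_REF_ALT, HET_ALT_REF, HOM_ALT)
N_CLASSES = len(CLASS_CODES)

#: alternate-allele dosage per class code (index by code; 0 and 5 are invalid)
_DOSAGE_BY_CODE = np.array([-1, 0, 1, 1, 2, -1], dtype=np.int64)

_GT_BY_CODE = {MISSING: "./.", HOM_REF: "0|0", HET_REF_ALT: "0|1",
               HET_ALT_REF: "1|0", HOM_ALT: "1|1"}
_CODE_BY_ALLELES = {(0, 0): HOM_REF, (0, 1): HET_REF_ALT,
                    (1, 0): HET_ALT_REF, (1, 1): HOM_ALT}


@dataclass(frozen=True)
class VariantMeta:
    """Metadata for one biallelic SNP (1-based VCF coordinates)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    snp_id: str | None = None


@dataclass
class GenotypeMatrix:
    """Samples × SNPs integer-coded phased genotypes plus variant metadata."""

    codes: np.ndarray  # [n_samples, n_snps], values in {0..4}
    variants: list[VariantMeta]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D [n_samples, n_snps] array")
        n_samples, n_snps = self.codes.shape
        if len(self.variants) != n_snps:
            raise ValueError(
                f"variants length {len(self.variants)} != n_snps {n_snps}")
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"sample_ids length {len(self.sample_ids)} != n_samples {n_samples}")
        if self.codes.size and self.codes.max() > HOM_ALT:
            raise ValueError("padding code 5 must never appear in a GenotypeMatrix")
        chroms = {v.chrom for v in self.variants}
        if len(chroms) > 1:
            raise ValueError(
                f"GenotypeMatrix holds one chromosome at a time, got {sorted(chroms)}")
        pos = self.positions
        if n_snps > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("variant positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)


def encode_genotype(gt_string: str) -> int:
    """Map a VCF GT field to the integer code.

    Raises
    ------
    ValueError
        On unphased non-missing calls (``0/1``) or ploidy != 2.
    """
    gt = gt_string.strip()
    if gt in ("./.", ".|.", "."):
        return MISSING
    sep = "|" if "|" in gt else ("/" if "/" in gt else None)
    if sep is None:
        raise ValueError(f"cannot parse GT field {gt_string!r}")
    parts = gt.split(sep)
    if len(parts) != 2:
        raise ValueError(f"only diploid calls are supported, got {gt_string!r}")
    if all(p == "." for p in parts):
        return MISSING
    if sep == "/":
        raise ValueError(
            f"unphased genotype {gt_string!r}: input must be phased "
            "(phase codes 2 vs 3 cannot be assigned)")
    try:
        alleles = (int(parts[0]), int(parts[1]))
    except ValueError as exc:
        raise ValueError(f"cannot parse GT field {gt_string!r}") from exc
    if alleles not in _CODE_BY_ALLELES:
        raise ValueError(f"non-biallelic alleles in GT field {gt_string!r}")
    return _CODE_BY_ALLELES[alleles]


def decode_genotype(code: int) -> str:
    """Inverse of :func:`encode_genotype`; padding (5) is rejected."""
    code = int(code)
    if code not in _GT_BY_CODE:
        raise ValueError(f"code {code} is not a writable genotype (padding?)")
    return _GT_BY_CODE[code]


def genotype_to_dosage(code: int) -> int:
    """Alternate-allele count of a non-missing class code: {1→0, 2→1, 3→1, 4→2}."""
    code = int(code)
    if code not in CLASS_CODES:
        raise ValueError(f"dosage undefined for code {code}")
    return int(_DOSAGE_BY_CODE[code])


def dosage_of_codes(codes: np.ndarray) -> np.ndarray:
    """Vectorized dosage; raises if any code is missing (0) or padding (5)."""
    codes = np.asarray(codes)
    if codes.size and (np.any(codes < HOM_REF) or np.any(codes > HOM_ALT)):
        raise ValueError("dosage undefined for missing/padding codes")
    return _DOSAGE_BY_CODE[codes]


def compute_maf(column: np.ndarray) -> float:
    """Minor allele frequency of one SNP from class codes, ignoring missing calls."""
    column = np.asarray(column)
    nonmissing = column[column != MISSING]
    if nonmissing.size == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    if np.any(nonmissing > HOM_ALT):
        raise ValueError("padding codes are not valid in a genotype column")
    alt = int(_DOSAGE_BY_CODE[nonmissing].sum())
    f_alt = alt / (2 * nonmissing.size)
    return min(f_alt, 1.0 - f_alt)


def compute_maf_matrix(codes: np.ndarray) -> np.ndarray:
    """Per-SNP MAF over a [n_samples, n_snps] code matrix (vectorized)."""
    codes = np.asarray(codes)
    nonmiss = codes != MISSING
    n_nonmiss = nonmiss.sum(axis=0)
    if np.any(n_nonmiss == 0):
        raise ValueError("MAF undefined for all-missing SNP column(s)")
    alt = np.where(nonmiss, _DOSAGE_BY_CODE[codes], 0).sum(axis=0)
    f_alt = alt / (2.0 * n_nonmiss)
    return np.minimum(f_alt, 1.0 - f_alt)


def read_phased_vcf(path: str) -> GenotypeMatrix:
    """Load a phased VCF into a :class:`GenotypeMatrix`.

    Biallelic SNPs only; multi-allelic and non-SNP records are skipped (count
    logged). Unphased non-missing calls raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[VariantMeta] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(len(sample_ids), dtype=np.uint8)
        for i, g in enumerate(gts):
            if len(g) != 3:
                raise ValueError(
                    f"non-diploid call for sample {sample_ids[i]} at "
                    f"{rec.CHROM}:{rec.POS}")
            a0, a1, phased = g[0], g[1], g[2]
            if a0 == -1 and a1 == -1:
                col[i] = MISSING
            elif not phased:
                raise ValueError(
                    f"unphased genotype for sample {sample_ids[i]} at "
                    f"{rec.CHROM}:{rec.POS}: input must be phased")
            else:
                key = (int(a0), int(a1))
                if key not in _CODE_BY_ALLELES:
                    raise ValueError(
                        f"unexpected alleles {key} at {rec.CHROM}:{rec.POS}")
                col[i] = _CODE_BY_ALLELES[key]
        variants.append(VariantMeta(
            chrom=rec.CHROM, pos=rec.POS, ref_allele=rec.REF,
            alt_allele=rec.ALT[0], snp_id=rec.ID))
        rows.append(col)
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP record(s)", n_skipped)
    if not variants:
        raise ValueError(f"no biallelic SNPs found in {path}")
    codes = np.stack(rows, axis=1)
    order = np.argsort([v.pos for v in variants], kind="stable")
    if not np.array_equal(order, np.arange(len(variants))):
        variants = [variants[i] for i in order]
        codes = codes[:, order]
    return GenotypeMatrix(codes=codes, variants=variants, sample_ids=sample_ids)


def write_imputed_vcf(matrix: GenotypeMatrix, dosages: np.ndarray, path: str) -> None:
    """Write a completed matrix as VCF with phased GT and a DS dosage field.

    ``dosages`` is the model's expected alternate-allele dosage per site,
    shape [n_samples, n_snps]; values are clipped to [0, 2].
    """
    import pysam

    if np.any(matrix.codes == MISSING):
        raise ValueError("matrix still contains missing genotypes; impute first")
    dosages = np.clip(np.asarray(dosages, dtype=np.float64), 0.0, 2.0)
    if dosages.shape != matrix.codes.shape:
        raise ValueError("dosages shape must match the genotype matrix")

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,'
                    'Description="Expected alternate allele dosage">')
    chrom = matrix.variants[0].chrom
    header.contigs.add(chrom, length=int(matrix.variants[-1].pos) + 1)
    for s in matrix.sample_ids:
        header.add_sample(s)

    alleles_by_code = {HOM_REF: (0, 0), HET_REF_ALT: (0, 1),
                       HET_ALT_REF: (1, 0), HOM_ALT: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, v in enumerate(matrix.variants):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos,
                alleles=(v.ref_allele, v.alt_allele),
                id=v.snp_id)
            for i, s in enumerate(matrix.sample_ids):
                rec.samples[s]["GT"] = alleles_by_code[int(matrix.codes[i, j])]
                rec.samples[s].phased = True
                rec.samples[s]["DS"] = float(dosages[i, j])
            out.write(rec)
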