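import numpy as np
import pytest

from biunet import GenotypeMatrix, VariantMeta


def make_matrix(codes, positions=None, chrom="1"):
    codes = np.asarray(codes, dtype=np.uint8)
    n_samples, n_snps = codes.shape
    if positions is None:
        positions = 100 * (np.arange(n_snps) + 1)
    variants = [VariantMeta(chrom=chrom, pos=int(p), ref_allele="A",
                            alt_allele="G", snp_id=f"rs{j}")
                for j, p in enumerate(positions)]
    return GenotypeMatrix(codes=codes, variants=variants,
                          sample_ids=[f"S{i}" for i in range(n_samples)])


def random_matrix(rng, n_samples, n_snps, include_missing=False):
    lo = 0 if include_missing else 1
    codes = rng.integers(lo, 5, size=(n_samples, n_snps)).astype(np.uint8)
    pos = np.sort(rng.choice(10_000_000, size=n_snps, replace=False)) + 1
    return make_matrix(codes, positions=pos)


@pytest.fixture
def toy_vcf(tmp_path):
    """3 samples x 2 SNPs with GTs [[0|0,0|1],[1|1,./.],[1|0,0|0]]."""
    path = tmp_path / "toy.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
        "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|0\t1|1\t1|0\n"
        "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0|1\t.|.\t0|0\n")
    return path
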