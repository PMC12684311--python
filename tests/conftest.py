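"""Shared fixtures: small pooled tables and a dirty VCF with known fates."""

import numpy as np
import pandas as pd
import pytest

from gfchrono.pool_stats import PooledVariantTable

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpool
"""


def vcf_line(pos, ref, alt, depth, alt_reads, extra_ad=None):
    ad = f"{depth - alt_reads - (extra_ad or 0)},{alt_reads}"
    if extra_ad is not None:
        ad += f",{extra_ad}"
    return (f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tDP={depth}\t"
            f"DP:AD\t{depth}:{ad}\n")


@pytest.fixture
def dirty_vcf_text():
    """Twelve records with hand-enumerated filter fates.

    Survivors of the default filter (5 bp indel flanks, depth in
    [301, 599] inclusive, biallelic only, mask over position 1060):
    positions 1000, 1037, 1070, 1080, 1090.  Removals: depth 2 (1010 low,
    1020 high), indel 1 (1030), flank 2 (1025 and 1033, within 5 bp of the
    indel footprint 1030-1031), multi-allelic 1 (1050), masked 1 (1060).
    """
    recs = [
        vcf_line(1000, "A", "G", 450, 90),     # keep
        vcf_line(1010, "C", "T", 300, 60),     # depth: 300 < 301
        vcf_line(1020, "G", "A", 600, 60),     # depth: 600 > 599
        vcf_line(1030, "AT", "A", 450, 90),    # indel
        vcf_line(1033, "T", "C", 450, 90),     # indel flank (3 bp)
        vcf_line(1025, "G", "C", 450, 90),     # indel flank (exactly 5 bp)
        vcf_line(1037, "A", "T", 450, 90),     # keep (6 bp from footprint)
        vcf_line(1050, "C", "G,T", 450, 90, extra_ad=45),  # multi-allelic
        vcf_line(1060, "T", "A", 450, 90),     # masked
        vcf_line(1070, "G", "T", 301, 60),     # keep (inclusive low edge)
        vcf_line(1080, "A", "C", 599, 60),     # keep (inclusive high edge)
        vcf_line(1090, "C", "A", 450, 0),      # keep (invariant site)
    ]
    return VCF_HEADER + "".join(recs)


DIRTY_SURVIVOR_POSITIONS = [1000, 1037, 1070, 1080, 1090]
DIRTY_TALLIES = {"indel_flank": 2, "indel": 1, "depth": 2,
                 "not_biallelic": 1, "masked": 1}
DIRTY_MASK = [("chr1", 1059, 1060)]  # BED half-open over position 1060


def make_table(freqs, n=100, population_id="pop", depth=450, start_pos=1000,
               coordinates=None):
    """Build a filtered PooledVariantTable directly from frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    df = pd.DataFrame({
        "chrom": "chr1",
        "pos": start_pos + 10 * np.arange(freqs.size),
        "ref_allele": "A",
        "alt_allele": "G",
        "depth": depth,
        "alt_freq": freqs,
        "is_indel": False,
        "n_alleles": 2,
    })
    return PooledVariantTable(population_id, n, df, coordinates)
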