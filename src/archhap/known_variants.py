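"""The CYP2C8*3 / CYP2C9*2 star-allele variants the pipeline was built around.

Coordinates are hg19 (GRCh37).  ``CYP2C_REGION_HG19`` is the span of the
linked haplotype carrying both star alleles in present-day non-African
populations.
"""

from .genomic_io import Region, VariantSite

#: CYP2C9*2 defining variant (R144C)
RS1799853 = VariantSite(chrom="chr10", pos=96_702_047, ref="C", alt="T", rsid="rs1799853")

#: one of the two CYP2C8*3 defining variants (K399R)
RS10509681 = VariantSite(chrom="chr10", pos=96_798_749, ref="T", alt="C", rsid="rs10509681")

#: rsids of the three amino-acid replacements defining CYP2C8*3 (R139K,
#: K399R) and CYP2C9*2 (R144C)
DEFINING_RSIDS = ("rs11572080", "rs10509681", "rs1799853")

#: span of the linked CYP2C8*3/CYP2C9*2 haplotype, hg19
CYP2C_REGION_HG19 = Region("chr10", 96_537_863, 96_851_277)


def variant_pair_distance_bp(a: VariantSite = RS1799853, b: VariantSite = RS10509681) -> int:
    """Genomic spacing (bp) between two variants on the same chromosome."""
    if a.chrom != b.chrom:
        raise ValueError("variants lie on different chromosomes")
    return abs(b.pos - a.pos)
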