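"""Regulatory-region arithmetic: merge, intersect, TSS distance, annotation.

Builds a toy gene with exons, defines its +-50 kb regulatory space, keeps the
DHSs that fall inside it, and annotates each by genomic feature and signed
distance to the nearest TSS (negative = TSS upstream of the DHS).
"""

from acedhs.intervals import (
    GeneRecord,
    GenomicInterval,
    annotate_feature,
    define_regulatory_region,
    distance_to_tss,
    elements_of,
    merge_intervals,
)

gene = GeneRecord(
    "NPAS3-like",
    GenomicInterval("chrS", 100_000, 120_000, id="NPAS3-like"),
    "+",
    exons=[GenomicInterval("chrS", 100_000, 101_000),
           GenomicInterval("chrS", 118_000, 120_000)],
)
region = define_regulatory_region(gene, chrom_length=1_000_000)
print(f"regulatory region: {region.chrom}:{region.start}-{region.end}")

raw = [
    GenomicInterval("chrS", 95_000, 95_400, id="dhs1"),
    GenomicInterval("chrS", 95_300, 95_900, id="dhs1b"),   # overlaps dhs1
    GenomicInterval("chrS", 100_500, 100_800, id="dhs2"),  # exonic
    GenomicInterval("chrS", 110_000, 110_600, id="dhs3"),  # intronic
    GenomicInterval("chrS", 400_000, 400_500, id="far"),   # outside
]
merged = merge_intervals(raw)
print(f"{len(raw)} raw DHS records merge into {len(merged)} blocks")

inside = elements_of(raw, [region])
for dhs in inside:
    feat = annotate_feature(dhs, [gene])
    dist, gid = distance_to_tss(dhs, [gene])
    print(f"  {dhs.id}: {feat}, {dist:+d} bp from TSS of {gid}")
# 'far' is dropped; dhs2 overlaps an exon so exon precedence applies.
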