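"""Map selected SNPs to genes with 1-kb flanks from a GFF3 file.

Writes a small gene model file, maps a handful of SNPs against it and
prints the candidate-gene table.
"""

from pathlib import Path

from boostsel.annotation import candidate_table, map_snps_to_genes, read_gff
from boostsel.genotype import VariantSite

gff = Path("toy_genes.gff3")
gff.write_text(
    "##gff-version 3\n"
    "chr1\tdemo\tgene\t5000\t8000\t.\t+\t.\tID=g47234\n"
    "chr1\tdemo\tgene\t9500\t12000\t.\t-\t.\tID=g47235\n"
    "chr2\tdemo\tgene\t1000\t2000\t.\t+\t.\tID=g12346\n"
)
genes = read_gff(gff)

snps = [
    VariantSite("chr1", 6100),   # inside g47234
    VariantSite("chr1", 8900),   # in both genes' flanks
    VariantSite("chr1", 20000),  # far from everything
    VariantSite("chr2", 500),    # upstream flank of g12346
]
hits = map_snps_to_genes(snps, genes, flank=1000)
for h in hits:
    print(f"{h.site_id} -> {h.gene_id} ({h.relation}, {h.distance} bp)")

table = candidate_table(hits, model_counts={"chr1:6100": 38})
print()
print(table.to_string(index=False))
# A SNP between two genes can hit both flanks; the table aggregates hits
# per gene and carries the best replicate-model support of its SNPs.
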