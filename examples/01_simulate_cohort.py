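"""Simulate a genotype/phenotype cohort with planted causal SNPs.

Generates the default desk-scale cohort (300 accessions x 5000 biallelic
SNPs, three seed-colour classes at roughly 45:27:23 imbalance, mild
population structure, 5-site LD blocks, 8 causal SNPs) and writes it as
VCF + phenotype table + truth file.
"""

from boostsel.simulate import SimulationConfig, emit_vcf, simulate_dataset, write_truth
from boostsel.genotype import write_phenotypes

config = SimulationConfig(seed=42)
matrix, phenos, truth = simulate_dataset(config)

print(f"simulated {matrix.n_samples} samples x {matrix.n_sites} sites")
print("class counts:", phenos.class_counts())
print("causal site indices:", truth.causal_indices)

emit_vcf(matrix, "cohort.vcf")
write_phenotypes(phenos, "cohort.pheno.tsv")
write_truth(truth, matrix, config, "cohort.truth.tsv")
print("wrote cohort.vcf, cohort.pheno.tsv, cohort.truth.tsv")
# The class counts show the white > beige > orange imbalance the
# classifier must handle; the truth file records which SNPs actually
# drive the colours so downstream selections can be scored.
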