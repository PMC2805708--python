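"""Rule-based genotype calling and concordance against the planted truth.

The truth panel plays the role of an error-free array platform; the
dominant discordance class is the allele-dropout signature.
"""

import rrlsnp as r

genome = r.generate_genome(2, 100_000, site_density=5.0, seed=4)
panel = r.plant_variants(genome, n_snps=600, seed=4)
reads = r.simulate_reads(genome, panel, mean_depth=20, seed=4)
result = r.discover(r.aggregate_pileup(reads, genome), seed=4)

groups = dict(panel.samples)
labels = [groups[s] for s in reads.samples]
strict = r.genotype_matrix(result.high_quality, reads.samples, labels, rule="strict")
lenient = r.genotype_matrix(result.high_quality, reads.samples, labels, rule="lenient")
print(f"strict calls: {strict.n_called()}  lenient calls: {lenient.n_called()} "
      f"over {strict.n_sites} SNPs x {strict.n_samples} samples")

table = r.concordance(strict, r.truth_matrix(panel))
print(table.to_dataframe())
print(f"overall concordance {table.overall_percent():.2f}% "
      f"over {table.grand_total} co-called genotypes")
(row, col), count = table.dominant_discordance()
names = ["hom_ref", "het", "hom_alt"]
print(f"dominant discordance: called {names[row]}, truth {names[col]} (n={count})")
# A homozygote called where the truth is heterozygous is the fingerprint of
# restriction-site polymorphism: the allele linked to a disrupted CCGG site
# is never sequenced from that cut.
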