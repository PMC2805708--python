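"""In-silico HpaII digestion and RRL read simulation.

Builds a small synthetic genome, digests it (C^CGG), plants SNPs with a
cultivated/wild group structure and simulates size-biased 32 bp reads.
"""

import numpy as np

import rrlsnp as r

genome = r.generate_genome(n_chroms=2, chrom_length=50_000, site_density=5.0, seed=1)
frags = [f for c, s in genome.chromosomes.items() for f in r.digest(s, c)]
lengths = np.array([f.length for f in frags])
print(f"{len(frags)} fragments; median length {np.median(lengths):.0f} bp; "
      f"{np.mean((lengths >= 40) & (lengths <= 250)):.0%} inside the 40-250 bp window")

panel = r.plant_variants(genome, n_snps=300, seed=1)
by_class = {}
for v in panel.variants:
    by_class[v.klass] = by_class.get(v.klass, 0) + 1
print("planted variant classes:", by_class)
print(f"{sum(v.disrupts_site for v in panel.variants)} variants abolish a CCGG site")

reads = r.simulate_reads(genome, panel, mean_depth=20.0, seed=1)
print(f"{len(reads)} reads from 17 samples; "
      f"{reads.tag_fraction():.1%} begin with the CGG tag")
# The tag fraction is just below 1: substitution errors at offsets 1-3
# occasionally corrupt the residual recognition sequence, as in real data.
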