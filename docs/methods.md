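# Methods

`rrlsnp` re-implements, at desk scale, the analysis chain used to
characterize a high-diversity plant genus from *HpaII* reduced-representation
libraries (RRLs): in-silico digestion and coverage enrichment, heuristic SNP
discovery from per-sample read counts, rule-based genotype calling,
segregation classification, EM-based LD decay with an unlinked background,
and PCA.  Because the original raw reads are not required, a synthetic-data
generator stands in for them and carries a known truth panel, so every
downstream claim can be checked against planted ground truth.

## The simulator

**Genome.**  A random multi-chromosome sequence (default 2 x 100 kb, GC
0.45) in which CCGG recognition sites are planted explicitly at uniform,
well-separated positions (default 5 sites/kb, matching a fragment-length
scale of ~200 bp) and incidental occurrences are scrubbed.  Two
chromosomes are the minimum because the LD background is defined by
inter-chromosomal pairs.  With ~500 sites per 100 kb chromosome the
fragment-length distribution is approximately exponential: ~13% of
fragments are shorter than a read (never sequenced), ~54% fall in the
amplification window, ~29% are longer than 250 bp.

**Digestion.**  *HpaII* cleaves C^CGG.  Fragments therefore tile the
sequence exactly, every internal fragment starts with the CGG tag and ends
with C.  This convention reproduces the empirical observation that the
large majority of RRL reads begin with the residual CGG tag.

**Sampling model.**  Reads are 32 bp (the 36->32 trimming of the original
protocol is emulated by generating 32-mers directly; the discarded cycles
are never modelled).  Reads are drawn only from fragment ends that are
genuine cuts — chromosome-terminal ends have no ligatable overhang — and
only from fragments >= 32 bp.  Each end of a fragment inside the size
window (default 40-250 bp) receives sampling weight 10, ends outside
weight 1; the quantitative enrichment is not published, so the 10:1
piecewise weight is a design choice made once.  `mean_depth` (default 20)
is defined as the expected per-sample read count at an in-window fragment
end; out-of-window ends then see ~2 reads per sample, which is what makes
low-depth, error-driven candidate sites appear — the raw material of the
read-position-bias diagnostic.  Reverse-end reads carry the bottom-strand
CGG tag (CCGG is palindromic) and overlap two bases into the neighbouring
fragment, exactly as overhang fill-in does.

**Variants.**  600 bi-allelic SNPs by default, planted inside the terminal
read windows (offsets 4..32; the tag bases cannot vary) of *in-window*
fragments: that is the genome fraction the assay interrogates at
genotypable depth, and the genotypic contingency filter has no power at
the ~2 reads/sample seen elsewhere.  Class mixture defaults (44.2%
cultivated-only, 28.8% wild-only, 24.3% shared, 2.7% fixed, as exclusive
shares) mirror the segregation structure reported for the real panel of
11 cultivated + 6 wild accessions; within-class allele frequencies are
uniform on [0.1, 0.5] and genotypes are Hardy-Weinberg draws conditioned
on the class definition.  A fraction (default 5%) of variants is placed
*inside* a CCGG site with the alternative allele abolishing the cut: the
carrying haplotype is then never sequenced from that cut (allele dropout),
unless a short flanking fragment lets the merged fragment's other end
reach the site.  Haplotype-resolved digestion handles both effects
automatically, including cuts created or destroyed by any variant.

**Errors and qualities.**  The substitution rate rises linearly from 0.002
at offset 1 to 0.02 at offset 32, reproducing the concentration of errors
at read ends.  Reported Phred qualities are drawn around a separate,
gently declining profile (34 at the read start to 22 at the end, sd 3).
They are deliberately *not* −10·log10(epsilon): base callers are
systematically overconfident near read ends, and in an RRL every site is
observed at essentially one fixed offset (reads start at cut sites), so a
calibrated mapping would make the site mean-quality filter equivalent to
a hard positional cutoff and the published Q >= 20 / sensitivity trade-off
could not coexist.  The decoupling emulates the documented miscalibration
and leaves the mean-quality filter a soft, noisy guard — the heavy lifting
against read-end artifacts is done by the contingency test, as in the
original analysis.

**Block-haplotype generator.**  For LD validation a separate generator
produces genotypes directly: sites within a block (default 5 kb) ride on
one of two founder haplotypes with a small per-site flip probability
(default 0.02, emulating mutation/gene conversion and keeping columns from
being exact duplicates, which would otherwise make bin-level rank tests
anticonservative); founder choice is independent across blocks, so
inter-block r² matches the inter-chromosomal background.

## Discovery filters

Preliminary (candidate) tier, applied to every site with at least one
mismatching read base: reject if the second-most-common allele is <= 5% of
total depth, depth < 10 or > 1000, or the 3rd+4th alleles sum to >= 2% of
depth; the two most common alleles are then retained.  "Minor allele" is
read as the retained alternative (the 3rd/4th rule separately bounds the
remainder).  Ties among equally common alleles break reference-first,
then lexicographically, deterministically.

High-quality tier: mean Phred quality over all base observations at the
site >= 20 (averaging over the minor allele only is a configuration
switch) and genotypic contingency p <= 0.01.  No multiple-testing
correction is applied; the published rule is a raw threshold.

**Contingency test.**  Pearson chi-square on the 2 x k table of
(reference, alternative) read counts per sample, with zero-coverage
samples dropped.  When any expected cell is < 5 the p-value is Monte-Carlo:
alternative-allele counts are resampled with margins fixed via the
multivariate hypergeometric distribution (10^4 draws by default, seeded);
degenerate tables (one informative row or column) return p = 1.  The test
suite validates this against an independent literal permutation of allele
labels.

**Read-position diagnostic.**  The histogram of minor-allele evidence over
within-read offsets, with each SNP given unit weight spread over its
observed offsets (a raw observation count is available but is dominated by
deep true sites).  The summary slope is the least-squares slope over
offsets 4..32; offsets 1-3 are the invariant tag.  On default simulations
the candidate tier has a clearly positive slope (error-driven sites
concentrate at read ends) and the high-quality filters remove it.

## Genotype calling

Lenient (for LD): homozygous at >= 4 reads of one allele and 0 of the
other; heterozygous at >= 4 reads of each; otherwise missing.
Strict (for concordance): homozygous at >= 5 reads all of one allele;
heterozygous at >= 8 reads passing the heterozygosity test; otherwise
missing.  The heterozygosity test is concretized as a one-sided exact
binomial tail: pass iff P(Binomial(n, eps) >= k) < 0.01 with eps = 0.01 by
default, k the minor count — i.e. the minor reads exceed what sequencing
error alone would produce.  Both eps and the threshold are configuration
keys.

Concordance between two genotype matrices is tabulated over co-called
(sample, site) pairs as a 3 x 3 table with percentages against the grand
total; sites whose allele pairs disagree across platforms are dropped and
counted.  On synthetic data the truth panel plays the role of the
error-free array platform, and the dominant discordance class is a
sequence homozygote at a true heterozygote — the signature of restriction
-site allele dropout.

## Population genetics

**Segregation.**  A group is polymorphic at a SNP when it carries >= 1
read of each allele; shared means polymorphic in both groups; a fixed
difference has each allele exclusive to one group.  The module reports
both the overlapping per-group shares and the disjoint partition, which
satisfy poly_A + poly_B − shared + fixed + unclassified = 1.  Note that at
the pooled depths the default simulation produces (~340x per site), a
single error read is enough to flag a group "polymorphic", so the shared
share is inflated relative to the planted mixture; the rule is applied as
published, and the truth round-trip is verified on error-free counts.

**LD.**  Haplotype frequencies for two bi-allelic loci are maximum
likelihood via EM on unphased diploid genotypes: the double-heterozygote
count is split between cis and trans phases at their expected proportions
and the four frequencies re-estimated until the largest change is < 1e-8
(<= 1000 iterations).  The linkage-equilibrium start is a stationary point
of the EM map, so EM also starts from both coupling phases displaced
halfway to the D bounds and keeps the best likelihood (validated against a
1-D grid search over f(AB), the only free parameter once allele margins
are fixed).  r² = D²/(pA pa pB pb); D′ is not computed (unreliable at
these sample sizes).  Pairs with a monomorphic locus after pairwise
deletion are skipped and logged.

Sites entering LD analysis are restricted to the cultivated group, with
> 1 missing call or a minor-allele count < 2 (singletons, monomorphic)
excluded.  All same-chromosome pairs within 40 kb are scored, sorted by
distance and cut into sequential bins of 1000 comparisons (the trailing
partial bin is dropped unless requested).  Background LD is 20,000 r²
values from random inter-chromosomal pairs, drawn without replacement,
seeded.  Each bin is compared to the background with a one-sided
Mann-Whitney U (bin stochastically greater); one-sided because the
hypothesis is LD above background.  scipy's implementation is used: exact
on small tie-free inputs, normal approximation with tie correction
otherwise.

**PCA.**  Genotypes coded 0/1/2 alternative copies; sites called in fewer
than 14 of 17 samples or monomorphic are excluded; missing values are
imputed with the per-site mean; sites are centred (not variance-scaled,
matching a plain `prcomp` on the coded matrix) and coordinates taken from
the SVD.  Variance fractions are s²/Σs² over all components, so the
reported leading fractions sum to <= 1 and are non-increasing.

## Coverage model

The mappable genome is assembled bases minus unknown (N) bases minus
annotated repeats, supplied as masks (BED) rather than recomputed.  Mean
coverage is lambda = total mapped bases / mappable bases.  (The source
text for the study also quotes a smaller mapped-base total that is
inconsistent with its own printed lambda of 2.14; this package follows the
definition and totals that reproduce 2.14.)  The un-enriched expectation
is Poisson(lambda) scaled to the mappable size, with tail mass collapsed
into the final bin; the enrichment report gives observed/expected ratios
per depth and the smallest depth >= 1 at which observed exceeds expected.
Masked positions are excluded from both observed and expected histograms.

## Problem sizes and determinism

Default analysis scale — 2 x 100 kb genome, 17 samples, 600 planted SNPs,
~390k reads, 20,000 background LD pairs — was chosen so a full run
completes in about a minute while every phenomenon of interest (tag
fraction, coverage enrichment, read-position bias, allele dropout, LD
decay to background) is statistically resolvable.  All randomness flows
from explicit integer seeds through `numpy.random.SeedSequence`; identical
seeds give byte-identical tabular outputs, which the pipeline manifest
verifies by content hash.

## What the synthetic data do and do not show

The generator emulates fragment-size-biased sampling, fixed read starts at
cut sites, read-end error concentration, quality miscalibration, two-group
population structure and restriction-site allele dropout.  It does not
model alignment (reads are born placed; mapping ambiguity is reduced to an
optional repeat mask), PCR duplicates, indels, methylation sensitivity or
paired ends, and its coverage is bimodal rather than continuously varying
as in real libraries.  Passing tests therefore demonstrate that the
implemented rules behave as published under the stated error model — not
that the rules are optimal, nor that real-data set sizes (which depend on
the raw archive) are reproduced.

## Known limitations

* The read-level segregation rule is error-sensitive at high pooled depth
  (see above); classification shares from deep simulations overstate
  sharing.
* The contingency Monte-Carlo p-value has resolution 1/(draws+1); at the
  default 10^4 draws the p <= 0.01 decision is stable but p-values below
  1e-4 are reported as ties with the resolution floor.
* EM multi-start guards against the D = 0 stationary point but, like any
  EM, cannot certify a global optimum for n larger than the grid-validated
  range.
* The PCA path mean-imputes missing genotypes, which shrinks coordinates
  of poorly covered samples toward the origin.
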